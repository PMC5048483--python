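"""Per-individual uncertainty of the compromise configuration.

Each individual is represented by M points — its coordinates in each
projected configuration (trajectory) on the first two compromise
dimensions. Two region summaries are computed per individual: the
normal-theory 95% confidence ellipse of the M points (chi-square quantile
on the sample covariance) and their convex hull. Larger areas mean a less
certain location; individuals with no missing rows still have nonzero
regions because the imputations perturb the whole configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import chi2

from .pipeline import MiMfaResult

__all__ = ["Ellipse", "Hull", "UncertaintyRegion", "confidence_ellipse", "convex_hull",
           "uncertainty_report"]


@dataclass
class Ellipse:
    center: np.ndarray       # (2,)
    covariance: np.ndarray   # 2 x 2 sample covariance
    level: float
    area: float

    def contains(self, x: np.ndarray) -> bool:
        """Mahalanobis membership test (degenerate ellipses contain only
        their centre)."""
        if self.area == 0.0:
            return bool(np.allclose(x, self.center))
        q = chi2.ppf(self.level, df=2)
        diff = np.asarray(x, float) - self.center
        return float(diff @ np.linalg.solve(self.covariance, diff)) <= q


@dataclass
class Hull:
    vertices: np.ndarray  # ordered (counter-clockwise) vertex coordinates
    area: float


@dataclass
class UncertaintyRegion:
    individual_id: str
    points: np.ndarray  # M x 2
    ellipse: Ellipse | None
    hull: Hull
    imputed: bool  # True if this individual was a hot-deck recipient anywhere


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Normal-theory confidence ellipse of a planar point set.

    The ellipse is {x : (x-mu)^T Sigma^{-1} (x-mu) <= q} with mu the point
    mean, Sigma the sample covariance and q the ``level`` quantile of the
    chi-square distribution with 2 degrees of freedom; its area is
    pi * q * sqrt(det Sigma). A singular covariance (all points coincident
    or collinear) yields a degenerate ellipse of zero area with a warning.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    q = float(chi2.ppf(level, df=2))
    if det <= np.finfo(float).tiny:
        warnings.warn("singular covariance: degenerate ellipse with zero area",
                      RuntimeWarning, stacklevel=2)
        return Ellipse(center=center, covariance=cov, level=level, area=0.0)
    return Ellipse(center=center, covariance=cov, level=level,
                   area=float(np.pi * q * np.sqrt(det)))


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def convex_hull(points: np.ndarray) -> Hull:
    """Minimal convex polygon containing all points (area by the shoelace
    formula). Collinear or single-point inputs degenerate to a segment or a
    point with zero area."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a nonempty (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] == 1:
        return Hull(vertices=uniq, area=0.0)
    try:
        h = ConvexHull(uniq)
    except QhullError:
        # collinear: the hull is the extreme segment along the spread direction
        c = uniq - uniq.mean(axis=0)
        direction = c[np.argmax(np.linalg.norm(c, axis=1))]
        t = c @ direction
        return Hull(vertices=uniq[[int(np.argmin(t)), int(np.argmax(t))]], area=0.0)
    return Hull(vertices=uniq[h.vertices], area=_shoelace(uniq[h.vertices]))


def uncertainty_report(result: MiMfaResult, level: float = 0.95) -> list[UncertaintyRegion]:
    """One uncertainty region per individual from the M projected
    configurations (first two compromise dimensions).

    All individuals get a region, including fully observed ones. With
    M < 3 ellipses cannot be estimated and are skipped with a warning;
    hulls are always computed.
    """
    trajectories = result.compromise.trajectories
    M = len(trajectories)
    ids = result.compromise.individual_ids
    if result.d < 2:
        raise ValueError("uncertainty regions need at least 2 compromise dimensions")
    skip_ellipse = M < 3
    if skip_ellipse:
        warnings.warn(f"M={M} < 3: ellipses skipped, hulls still computed",
                      RuntimeWarning, stacklevel=2)
    recipients = {
        r for a in result.imputations.assignments for (_, r) in a.keys()
    }
    regions: list[UncertaintyRegion] = []
    for i, ind in enumerate(ids):
        pts = np.array([t[i, :2] for t in trajectories])
        if skip_ellipse:
            ell = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ell = confidence_ellipse(pts, level=level)
        regions.append(
            UncertaintyRegion(
                individual_id=ind,
                points=pts,
                ellipse=ell,
                hull=convex_hull(pts),
                imputed=ind in recipients,
            )
        )
    return regions
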