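"""MI-MFA orchestration: hot-deck completions -> per-completion MFA ->
STATIS compromise; plus the replicate-based procedure for choosing the
number of imputations M.

The stability procedure grows nested collections of completions (the
collection at one level is a strict prefix of the next, guaranteed by the
prefix-stable hot-deck draw), computes a compromise at each level, and
tracks the RV coefficient between compromises at consecutive levels across
N replicates until the successive means stabilise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import Configuration, MultiOmicsSet
from .hotdeck import ImputationSet, count_total_imputations, multiple_imputation
from .mfa import PreprocessSpec, mfa
from .statis import CompromiseResult, cross_product, rv_coefficient, statis_compromise

__all__ = ["MiMfaResult", "StabilityCurve", "run_mi_mfa", "choose_num_imputations"]

logger = logging.getLogger(__name__)

# Below this many distinct completions, exhaustive use of all of them is
# cheap and preferable to choosing M.
SMALL_M_TOTAL = 50


@dataclass
class MiMfaResult:
    compromise: CompromiseResult
    per_imputation_configs: list[Configuration]
    imputations: ImputationSet
    d: int
    parameters: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.imputations.M


@dataclass
class StabilityCurve:
    """Mean/SD of the consecutive-level RV coefficients r_n^l.

    ``mean_r[k]`` is the mean over replicates of RV between the compromises
    at ``M_levels[k+1]`` and ``M_levels[k]``; the series has one entry fewer
    than ``M_levels``. ``converged_at`` indexes ``M_levels`` at the first
    level where the difference between successive means drops below the
    tolerance (None if never). ``recommended_M`` is the level at
    convergence, or M_total when the procedure short-circuits because
    M_total is small.
    """

    M_levels: list[int]
    mean_r: list[float]
    sd_r: list[float]
    N: int
    converged_at: int | None
    recommended_M: int
    short_circuited: bool = False


def run_mi_mfa(
    dataset: MultiOmicsSet,
    M: int = 30,
    d: int = 2,
    seed: int = 0,
    spec: PreprocessSpec | None = None,
) -> MiMfaResult:
    """Run the full MI-MFA: M hot-deck completions, an MFA per completion,
    and a STATIS compromise of the M configurations.

    A complete dataset admits exactly one completion (itself), so M is
    forced to 1 and the compromise equals the plain MFA configuration.
    """
    spec = spec or PreprocessSpec()
    if M < 1:
        raise ValueError("M must be >= 1")
    if dataset.is_complete() and M > 1:
        logger.info("dataset complete: a single (trivial) completion exists; forcing M=1")
        M = 1
    imputations = multiple_imputation(dataset, M=M, seed=seed)
    configs: list[Configuration] = []
    for m, completion in enumerate(imputations.completions):
        configs.append(mfa(completion, d=d, spec=spec))
        logger.info("imputation %d/%d: MFA done", m + 1, M)
    compromise = statis_compromise(configs, d=d)
    return MiMfaResult(
        compromise=compromise,
        per_imputation_configs=configs,
        imputations=imputations,
        d=d,
        parameters={
            "M": M,
            "d": d,
            "seed": seed,
            "center": spec.center,
            "scale_unit_variance": spec.scale_unit_variance,
        },
    )


def _config_rv(a: Configuration, b: Configuration) -> float:
    return rv_coefficient(cross_product(a), cross_product(b))


def choose_num_imputations(
    dataset: MultiOmicsSet,
    M_levels: list[int] | None = None,
    N: int = 5,
    seed: int = 0,
    tol: float = 0.01,
    d: int = 2,
    spec: PreprocessSpec | None = None,
) -> StabilityCurve:
    """Choose the number of imputations M by replicate stability.

    For each of N replicates, nested completion collections are grown
    across ``M_levels``; at every level a compromise is computed and the RV
    coefficient to the previous level's compromise is recorded. The curve
    of per-level means and SDs is returned; convergence is declared at the
    first level where the difference between successive means falls below
    ``tol``.

    If the total number of distinct completions is small (M_total <= 50)
    the procedure short-circuits: every completion can simply be used, so
    the recommendation is M = M_total.
    """
    spec = spec or PreprocessSpec()
    if dataset.is_complete():
        # one trivial completion; every level yields the same configuration
        levels = list(M_levels) if M_levels else [1]
        k = len(levels) - 1
        return StabilityCurve(
            M_levels=levels,
            mean_r=[1.0] * k,
            sd_r=[0.0] * k,
            N=N,
            converged_at=0,
            recommended_M=1,
            short_circuited=True,
        )
    m_total = count_total_imputations(dataset)
    if m_total <= SMALL_M_TOTAL:
        return StabilityCurve(
            M_levels=[m_total],
            mean_r=[],
            sd_r=[],
            N=N,
            converged_at=0,
            recommended_M=m_total,
            short_circuited=True,
        )
    if M_levels is None:
        M_levels = [10, 20, 30]
    M_levels = sorted(int(m) for m in M_levels)
    if len(set(M_levels)) != len(M_levels):
        raise ValueError("M_levels must be strictly increasing")
    if N < 2:
        raise ValueError("need N >= 2 replicates")
    if M_levels[-1] > m_total:
        raise ValueError(f"max(M_levels)={M_levels[-1]} exceeds M_total={m_total}")

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(N)]

    L = len(M_levels)
    r = np.zeros((N, L - 1))
    for n in range(N):
        # one draw at the largest level; prefixes give the nested collections
        imps = multiple_imputation(dataset, M=M_levels[-1], seed=rep_seeds[n])
        configs = [mfa(c, d=d, spec=spec) for c in imps.completions]
        prev = None
        for l, Ml in enumerate(M_levels):
            comp = statis_compromise(configs[:Ml], d=d).as_configuration()
            if prev is not None:
                r[n, l - 1] = _config_rv(comp, prev)
            prev = comp
        logger.info("stability replicate %d/%d done", n + 1, N)

    mean_r = r.mean(axis=0)
    sd_r = r.std(axis=0, ddof=1)
    converged_at: int | None = None
    for k in range(1, L - 1):
        if abs(mean_r[k] - mean_r[k - 1]) < tol:
            converged_at = k + 1  # index into M_levels
            break
    recommended = M_levels[converged_at] if converged_at is not None else M_levels[-1]
    return StabilityCurve(
        M_levels=list(M_levels),
        mean_r=[float(x) for x in mean_r],
        sd_r=[float(x) for x in sd_r],
        N=N,
        converged_at=converged_at,
        recommended_M=recommended,
        short_circuited=False,
    )
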