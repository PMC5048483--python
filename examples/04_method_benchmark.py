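"""Benchmark MI-MFA against mean-variable and regularized-iterative
imputation on a known truth.

The complete liver-shaped dataset provides the true configuration; rows are
removed per scenario (1/2/3 per stratum of 8), each method reconstructs a
configuration, and the RV coefficient to the truth is averaged over
replicates (5 here; increase for smoother curves).
"""

import warnings

import mimfa as mi
from mimfa.evaluation import aggregate_reports
from mimfa.synthetic import liver_preset, liver_row_scenarios

base = liver_preset(seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    reports = mi.benchmark(base, list(liver_row_scenarios().values()),
                           replicates=5, M=30, d=2, seed=8)

print(aggregate_reports(reports).to_string(index=False))
print("Mean RV to the true configuration per scenario and method: the "
      "multiple-imputation compromise (MI) degrades the least as more rows "
      "go missing; mean imputation (MVI) degrades the fastest.")
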