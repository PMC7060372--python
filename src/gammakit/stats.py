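"""Group statistics: normality testing and two-group comparisons.

Normalized (percent-of-baseline) metrics are compared with Student's unpaired
two-sample t test (pooled variance); absolute peak powers, being log-normally
distributed, are compared with the non-parametric Mann–Whitney U test.
Normality is assessed with the D'Agostino–Pearson omnibus K² test. All tests
are two-sided at a nominal significance level of .05; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "dagostino_pearson_k2",
    "unpaired_t",
    "mann_whitney_u",
    "compare_groups",
]

#: Pooled sample size at or below which the Mann–Whitney p is computed by
#: exact enumeration (ties permitting); above it, the tie-corrected normal
#: approximation is used.
EXACT_MWU_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple[int, ...]
    alternative: str = "two-sided"
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def dagostino_pearson_k2(x) -> TestResult:
    """D'Agostino–Pearson omnibus normality test.

    K² combines the normalized sample skewness and kurtosis; under normality
    K² is chi-square with 2 df. Requires n >= 8 (the kurtosis normalization is
    undefined below) and non-zero variance.
    """
    v = np.asarray(x, dtype=float)
    if v.size < 8:
        raise ValueError("D'Agostino–Pearson requires n >= 8")
    if np.ptp(v) == 0:
        raise ValueError("zero variance: normality test undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kurtosistest small-n notice
        k2, p = sps.normaltest(v)
    return TestResult(float(k2), float(p), "dagostino-pearson", (int(v.size),))


def unpaired_t(a, b) -> TestResult:
    """Student's unpaired two-sample t test (pooled variance, two-sided)."""
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
        return TestResult(
            float("nan"),
            float("nan"),
            "student-t",
            (int(va.size), int(vb.size)),
            note="degenerate: both groups constant and equal",
        )
    t, p = sps.ttest_ind(va, vb, equal_var=True)
    return TestResult(float(t), float(p), "student-t", (int(va.size), int(vb.size)))


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test; U is reported as min(U_a, U_b).

    The p-value is computed by exact enumeration for pooled n <= 12 without
    ties, and by the tie-corrected normal approximation otherwise.
    """
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([va, vb])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(va, vb, alternative=alternative, method=method)
    u_a = float(res.statistic)
    u_min = min(u_a, va.size * vb.size - u_a)
    return TestResult(
        u_min,
        float(res.pvalue),
        f"mann-whitney-u ({method})",
        (int(va.size), int(vb.size)),
        alternative=alternative,
    )


def compare_groups(
    metric: str, drug_values, control_values, absolute: bool = False
) -> TestResult:
    """Dispatch the comparison the way the analysis workflow prescribes.

    Normalized metrics → Student's unpaired t; absolute peak powers
    (``absolute=True``) → Mann–Whitney U.
    """
    if len(drug_values) == 0 or len(control_values) == 0:
        raise ValueError("empty group")
    if absolute:
        res = mann_whitney_u(drug_values, control_values)
    else:
        res = unpaired_t(drug_values, control_values)
    res.note = (res.note + f" metric={metric}").strip()
    return res
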