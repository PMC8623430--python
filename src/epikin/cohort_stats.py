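"""Study-level statistics: enrollment size, normality and group comparison.

* :func:`min_sample_size` — minimum patients needed to estimate a rare
  disease's prevalence within a confidence interval of full amplitude D:
  n = z^2 p (1 - p) / (D/2)^2.  D is the *full* interval width; its
  half-width D/2 enters the denominator.
* :func:`ks_normality` — one-sample Kolmogorov-Smirnov test against a
  normal with the sample's mean and standard deviation.  Because the
  parameters are estimated from the same data, the asymptotic p-value is
  conservative (the Lilliefors caveat); the method tag records this
  rather than silently switching tests.
* :func:`mann_whitney` — two-sided Mann-Whitney U; exact by enumeration
  for small tie-free groups (min n <= 8), otherwise the normal
  approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SampleSizeParams", "TestResult", "min_sample_size", "mann_whitney", "ks_normality", "compare_phases"]

#: Largest min(n1, n2) for which the exact Mann-Whitney null is enumerated.
EXACT_MW_THRESHOLD = 8


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs of the prevalence sample-size formula."""

    prevalence: float  # p, proportion in (0, 1)
    z: float  # standard-normal quantile for the confidence level
    amplitude: float  # D, full confidence-interval width, proportion

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not self.z > 0:
            raise ValueError("z must be > 0")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude D must be in (0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must be in [0, 1]")


def min_sample_size(prevalence: float, z: float = 1.96, amplitude: float = 0.02) -> float:
    """Minimum enrollment to estimate a prevalence within +-D/2.

    Returns the unrounded n = z^2 p (1-p) / (D/2)^2; display at two
    decimals.  For a 1/3500 prevalence at 95% confidence and D = 2%,
    n = 10.97.
    """
    params = SampleSizeParams(prevalence, z, amplitude)
    half_width = params.amplitude / 2.0
    return params.z**2 * params.prevalence * (1.0 - params.prevalence) / half_width**2


def mann_whitney(before, after) -> TestResult:
    """Two-sided Mann-Whitney U test between two recording groups.

    Exact null enumeration is used when min(n1, n2) <= 8 and the pooled
    data carry no ties (the study's per-phase group sizes of 3-4 videos
    fall in this regime); otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= EXACT_MW_THRESHOLD and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(int(x.size), int(y.size)),
        method="exact" if exact else "approximate (normal, tie and continuity corrected)",
    )


def ks_normality(values) -> TestResult:
    """One-sample KS test against N(sample mean, sample sd).

    Requires n >= 4.  The p-value comes from the asymptotic KS
    distribution and is conservative because the reference parameters
    are estimated from the sample (Lilliefors caveat, recorded in the
    method tag).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("ks_normality requires at least 4 values")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample standard deviation is zero")
    res = stats.kstest(x, "norm", args=(mean, sd))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size),),
        method="approximate (asymptotic KS; parameters estimated from sample)",
    )


def compare_phases(table, parameter: str, per_patient: bool = False) -> TestResult:
    """Mann-Whitney comparison of a kinematic parameter before vs after.

    ``table`` is a per-recording DataFrame with ``phase`` and parameter
    columns.  With ``per_patient=True`` the test compares per-patient
    means instead of per-video values.
    """
    if parameter not in table.columns:
        raise ValueError(f"no column {parameter!r} in the table")
    if per_patient:
        table = table.groupby(["patient_id", "phase"], as_index=False)[parameter].mean()
    before = table.loc[table["phase"] == "before", parameter].to_numpy()
    after = table.loc[table["phase"] == "after", parameter].to_numpy()
    return mann_whitney(before, after)
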