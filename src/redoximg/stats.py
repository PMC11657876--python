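"""Normality-gated two-group comparison.

Each group is screened with a Shapiro-Wilk test; if BOTH groups pass at the
gate alpha, an unpaired two-sided Student's t-test compares the means,
otherwise a two-sided Mann-Whitney U-test is used. Significance stars follow
the usual figure-annotation thresholds (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "star_annotation"]


@dataclass
class ComparisonResult:
    n_a: int
    n_b: int
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    stars: str
    warnings: list[str] = field(default_factory=list)


def star_annotation(p_value: float) -> str:
    """Figure star string: ns, *, **, ***, **** (strict thresholds)."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    if p_value < 1e-4:
        return "****"
    if p_value < 1e-3:
        return "***"
    if p_value < 1e-2:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_groups(
    sample_a,
    sample_b,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonResult:
    """Shapiro-Wilk-gated t-test / Mann-Whitney U comparison of two samples.

    ``equal_var=False`` switches the parametric branch to Welch's t-test.
    Zero-variance groups cannot be normality-tested and fall through to the
    nonparametric branch with a warning.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError(
            f"each group needs n >= 3 (got {len(a)} and {len(b)})"
        )
    warnings_list: list[str] = []

    shapiro_p_a = shapiro_p_b = None
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    if degenerate:
        warnings_list.append(
            "zero-variance group: normality gate skipped, using Mann-Whitney U"
        )
        normal = False
    else:
        shapiro_p_a = float(sps.shapiro(a).pvalue)
        shapiro_p_b = float(sps.shapiro(b).pvalue)
        normal = shapiro_p_a >= gate_alpha and shapiro_p_b >= gate_alpha

    if normal:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test_used = "t"
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        test_used = "mann_whitney"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            statistic, p_value = float(res.statistic), float(res.pvalue)
        except ValueError:
            # all observations identical across both groups: no evidence at all
            warnings_list.append("all observations identical; p set to 1.0")
            statistic, p_value = float("nan"), 1.0
    if np.isnan(p_value):
        warnings_list.append("degenerate test result; p set to 1.0")
        p_value = 1.0

    return ComparisonResult(
        n_a=len(a),
        n_b=len(b),
        shapiro_p_a=shapiro_p_a,
        shapiro_p_b=shapiro_p_b,
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        alpha=alpha,
        significant=p_value < alpha,
        stars=star_annotation(p_value),
        warnings=warnings_list,
    )
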