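"""Cohort-level statistics: Mann-Whitney, Spearman, repeated-measures ANOVA
with Greenhouse-Geisser correction, and the normality/log-transform screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "spearman_rho",
    "rm_anova_gg",
    "log_transform_if_nonnormal",
    "EXACT_MW_MAX_N",
]

#: Combined sample size at or below which the Mann-Whitney p is exact.
EXACT_MW_MAX_N = 12

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of rank arrangements when the combined sample is
    small (n_x + n_y <= 12) and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size <= EXACT_MW_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        extras={"U": float(res.statistic), "exact": exact, "n_x": x.size, "n_y": y.size},
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties; p from the
    t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples with n >= 3 required")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: ranks undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        test="spearman_rho", statistic=float(rho), p_value=float(p), extras={"rho": float(rho)}
    )


def _gg_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the eigenvalues of the double-centered
    covariance of the repeated measures (computed across all subjects)."""
    k = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    # double centering
    C = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    lam = np.linalg.eigvalsh(C)
    lam = np.clip(lam, 0.0, None)
    num = lam.sum() ** 2
    den = (k - 1) * np.sum(lam**2)
    if den <= 0:
        return 1.0
    eps = float(num / den)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(measures: np.ndarray, groups=None) -> dict:
    """Mixed repeated-measures ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    measures : (n_subjects, k) array
        One row per subject, one column per repeated measure.
    groups : sequence of length n_subjects, optional
        Between-subject group labels; omit for a single-group design.

    Returns a dict of :class:`TestResult` for the within-subject effect
    (``measure``), and, with groups, the ``group`` main effect and the
    ``interaction``. Within-effect and interaction degrees of freedom are
    multiplied by epsilon before the p computation. With k = 2 repeated
    measures sphericity is automatic and epsilon = 1 exactly.
    """
    Y = np.asarray(measures, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a subjects x measures matrix with >= 2 measures")
    n, k = Y.shape
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    glabels = np.unique(groups)
    counts = np.array([(groups == g).sum() for g in glabels])
    if np.any(counts < 2):
        raise ValueError("need >= 2 subjects per group")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    meas_means = Y.mean(axis=0)
    group_means = np.array([Y[groups == g].mean() for g in glabels])
    cell_means = np.array([Y[groups == g].mean(axis=0) for g in glabels])  # (G, k)

    ss_between = k * np.sum(counts * (group_means - grand) ** 2)
    ss_subj_within = k * np.sum(
        (subj_means - group_means[np.searchsorted(glabels, groups)]) ** 2
    )
    ss_measure = n * np.sum((meas_means - grand) ** 2)
    ss_inter = np.sum(
        counts[:, None]
        * (cell_means - group_means[:, None] - meas_means[None, :] + grand) ** 2
    )
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_between - ss_subj_within - ss_measure - ss_inter

    G = glabels.size
    df_group, df_subj = G - 1, n - G
    df_meas, df_inter = k - 1, (k - 1) * (G - 1)
    df_err = (k - 1) * (n - G)

    eps = _gg_epsilon(Y, groups)
    out: dict[str, TestResult] = {}

    ms_err = ss_err / df_err
    F_meas = (ss_measure / df_meas) / ms_err
    p_meas = float(sps.f.sf(F_meas, df_meas * eps, df_err * eps))
    out["measure"] = TestResult(
        "rm_anova_gg",
        float(F_meas),
        p_meas,
        extras={"epsilon": eps, "df1": df_meas * eps, "df2": df_err * eps},
    )
    if G > 1:
        F_group = (ss_between / df_group) / (ss_subj_within / df_subj)
        out["group"] = TestResult(
            "rm_anova_gg",
            float(F_group),
            float(sps.f.sf(F_group, df_group, df_subj)),
            extras={"df1": df_group, "df2": df_subj},
        )
        F_int = (ss_inter / df_inter) / ms_err
        out["interaction"] = TestResult(
            "rm_anova_gg",
            float(F_int),
            float(sps.f.sf(F_int, df_inter * eps, df_err * eps)),
            extras={"epsilon": eps, "df1": df_inter * eps, "df2": df_err * eps},
        )
    return out


def log_transform_if_nonnormal(x, alpha: float = ALPHA):
    """Log-transform a sample when a Shapiro-Wilk screen rejects normality.

    Returns ``(values, transformed_flag)``. Raises if a transformation is
    required but the sample contains non-positive values.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for the normality screen")
    _, p = sps.shapiro(x)
    if p >= alpha:
        return x, False
    if np.any(x <= 0):
        raise ValueError("non-normal sample contains non-positive values; cannot log-transform")
    return np.log(x), True
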