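"""Group statistics: covariate adjustment, region-wise tests with FDR,
correlations, and comparison of two correlation coefficients.

Group differences are assessed on covariate-adjusted outcomes: the outcome
is residualized on an intercept plus the confound design (sex, brain
volume, motion summaries, optionally network strength and density) and the
residuals are compared with a pooled-variance two-sample t-test, with
Benjamini–Hochberg FDR correction across regions.  Development rates are
Pearson correlations between a controllability metric and postmenstrual age
within a scan window, and rates are compared between windows or groups with
the Fisher r-to-z test for independent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ParameterError, ValidationError


@dataclass(frozen=True)
class RegionTestResult:
    """Result of one region's covariate-adjusted group test."""

    node_id: str
    statistic: float
    df: int
    p_raw: float
    p_fdr: float
    significant_at_q: bool


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher r-to-z comparison of two correlations.

    ``z = 0`` iff ``r1 == r2`` and ``sign(z) == sign(r1 - r2)``.
    """

    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p_one_sided: float
    p_two_sided: float


def residualize(y, covariates) -> np.ndarray:
    """OLS residuals of ``y`` on an intercept plus the covariate columns.

    ``covariates`` may be a DataFrame or 2-D array; ``None``/empty design
    residualizes on the intercept only (i.e. centers ``y``).  A
    rank-deficient design raises rather than silently dropping columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return y - y.mean()
    X = np.asarray(
        covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
        dtype=float,
    )
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        return y - y.mean()
    if X.shape[0] != y.size:
        raise ValidationError("covariate rows do not match outcome length")
    if y.size <= X.shape[1] + 1:
        raise ValidationError("need more subjects than covariates")
    design = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("collinear covariate design (rank deficient)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def two_sample_t(a, b) -> tuple:
    """Pooled-variance two-sample two-sided Student t-test.

    Returns ``(t, df, p_two_sided)`` with ``df = n_a + n_b - 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateInputError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return float(res.statistic), df, float(res.pvalue)


def regionwise_group_test(
    values: np.ndarray,
    groups,
    node_ids,
    covariates=None,
    q: float = 0.05,
    group_order: tuple | None = None,
) -> list:
    """Covariate-adjusted per-region group tests with BH-FDR correction.

    Parameters
    ----------
    values : (n_subjects, n_nodes) array
        One metric value per subject and region.
    groups : sequence of labels (exactly two levels)
        ``t > 0`` means the first level of ``group_order`` (default: sorted
        label order) has the larger adjusted mean.
    covariates : optional DataFrame/array aligned with subjects
    q : FDR level for the reported significance flags.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    node_ids = list(node_ids)
    if values.ndim != 2 or values.shape[1] != len(node_ids):
        raise ValidationError("values must be (n_subjects, n_nodes)")
    if values.shape[0] != groups.size:
        raise ValidationError("group labels do not match subject rows")
    levels = tuple(group_order) if group_order else tuple(sorted(set(groups)))
    if len(levels) != 2 or set(levels) != set(np.unique(groups)):
        raise ValidationError(f"need exactly two group levels, got {levels}")
    mask_a = groups == levels[0]

    t_stats, p_raw = [], []
    df = values.shape[0] - 2
    for j in range(values.shape[1]):
        resid = residualize(values[:, j], covariates)
        t, df, p = two_sample_t(resid[mask_a], resid[~mask_a])
        t_stats.append(t)
        p_raw.append(p)
    reject, p_fdr, *_ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return [
        RegionTestResult(
            node_id=node_ids[j],
            statistic=t_stats[j],
            df=df,
            p_raw=p_raw[j],
            p_fdr=float(p_fdr[j]),
            significant_at_q=bool(reject[j]),
        )
        for j in range(len(node_ids))
    ]


def region_results_frame(results) -> pd.DataFrame:
    """Tabulate a list of :class:`RegionTestResult`."""
    return pd.DataFrame(
        [
            {
                "node_id": r.node_id,
                "t": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "significant": r.significant_at_q,
            }
            for r in results
        ]
    )


def pearson(x, y) -> tuple:
    """Sample Pearson correlation with its two-sided t-distribution p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need n >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ParameterError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ParameterError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.sf(abs(z)))
    return CorrelationComparison(
        r1=float(r1),
        n1=int(n1),
        r2=float(r2),
        n2=int(n2),
        z=float(z),
        p_one_sided=p_one,
        p_two_sided=2.0 * p_one,
    )


def compare_dependent_correlations(x1, y1, x2, y2) -> CorrelationComparison:
    """Compare cor(x1, y1) with cor(x2, y2) measured on the *same* subjects
    (dependent, non-overlapping correlations; Raghunathan–Rosenthal–Rubin
    variant of the Pearson–Filon statistic).

    Requires the raw data since the cross-correlations between the four
    variables enter the covariance of the two correlation estimates.  Not
    the default comparison: printed summary statistics only permit the
    independent test in :func:`compare_correlations`.
    """
    arrs = [np.asarray(a, dtype=float) for a in (x1, y1, x2, y2)]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n <= 3:
        raise ParameterError("need four aligned samples with n > 3")
    R = np.corrcoef(np.vstack(arrs))
    r_jk, r_hm = R[0, 1], R[2, 3]
    r_jh, r_jm, r_kh, r_km = R[0, 2], R[0, 3], R[1, 2], R[1, 3]
    cov = (
        0.5 * r_jk * r_hm * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
        + r_jh * r_km
        + r_jm * r_kh
        - (r_jk * r_jh * r_jm + r_jk * r_kh * r_km)
        - (r_hm * r_jh * r_kh + r_hm * r_jm * r_km)
    )
    c = cov / ((1 - r_jk**2) * (1 - r_hm**2))
    c = min(c, 1.0 - 1e-12)
    z = (np.arctanh(r_jk) - np.arctanh(r_hm)) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p_one = float(sps.norm.sf(abs(z)))
    return CorrelationComparison(
        r1=float(r_jk),
        n1=n,
        r2=float(r_hm),
        n2=n,
        z=float(z),
        p_one_sided=p_one,
        p_two_sided=2.0 * p_one,
    )


def development_rate(metric_values, pma_values) -> tuple:
    """Development rate of a metric within a scan window: Pearson r vs PMA."""
    return pearson(metric_values, pma_values)
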