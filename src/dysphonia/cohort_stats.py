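"""Cohort-level statistics: group comparison, effect sizes, correlations.

The comparison protocol mirrors standard clinical-acoustics practice: a
Kolmogorov–Smirnov normality gate routes each measure to a two-sample
t-test (normal) or Mann–Whitney U-test (otherwise); Pearson or Spearman
correlation is selected the same way; significance is Bonferroni-adjusted
for the number of tests within the same phonatory dimension; effect sizes
are Cohen's d on the pooled standard deviation.  The disease burden score
``age * (CAG - 35.5)`` summarises cumulative exposure to the expanded
huntingtin CAG repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .wald import DIMENSIONS

__all__ = [
    "normality_gate",
    "compare_groups",
    "cohens_d",
    "cohens_d_from_summary",
    "correlate",
    "disease_burden",
    "group_report",
]

ALPHA = 0.05


def normality_gate(values: np.ndarray, lilliefors: bool = False) -> str:
    """Classify a sample as ``"normal"`` or ``"non_normal"``.

    One-sample Kolmogorov–Smirnov test against a Gaussian with the sample
    mean and SD; ``lilliefors=True`` uses the Lilliefors correction for the
    estimated parameters (statsmodels).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 5:
        raise ValueError("normality gate needs at least 5 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        return "non_normal"
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(values, dist="norm")
    else:
        _, p = st.kstest(values, "norm", args=(values.mean(), sd))
    return "non_normal" if p < ALPHA else "normal"


def cohens_d(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Cohen's d with the pooled standard deviation.

    ``(m1 - m2) / s_pooled`` with
    ``s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / s_pooled)


def cohens_d_from_summary(group1: tuple, group2: tuple) -> float:
    """Cohen's d from printed summary statistics ``(mean, sd, n)``."""
    (m1, s1, n1), (m2, s2, n2) = group1, group2
    return cohens_d(m1, s1, n1, m2, s2, n2)


def _cohens_d_samples(a: np.ndarray, b: np.ndarray) -> float:
    return cohens_d(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
    )


@dataclass
class ComparisonRow:
    """Result of one two-group comparison."""

    test: str  # "t" | "mann_whitney"
    p_value: float
    cohens_d: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def compare_groups(a: np.ndarray, b: np.ndarray, gate: str | None = None) -> ComparisonRow:
    """Two-sided two-group comparison with gate-selected test.

    ``gate`` is ``"normal"``/``"non_normal"``; if ``None`` the normality
    gate is applied to the pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if gate is None:
        gate = normality_gate(np.concatenate([a, b]))
    if gate == "normal":
        test = "t"
        _, p = st.ttest_ind(a, b)
    else:
        test = "mann_whitney"
        _, p = st.mannwhitneyu(a, b, alternative="two-sided")
    try:
        d = _cohens_d_samples(a, b)
    except ValueError:
        d = np.nan
    return ComparisonRow(
        test=test,
        p_value=float(p),
        cohens_d=d,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
    )


def correlate(
    x: np.ndarray, y: np.ndarray, gate: str | None = None
) -> tuple[float, float, str]:
    """Correlation with gate-selected method: ``(r, p, method)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("correlation needs at least 5 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if gate is None:
        gate = (
            "normal"
            if normality_gate(x) == "normal" and normality_gate(y) == "normal"
            else "non_normal"
        )
    if gate == "normal":
        r, p = st.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = st.spearmanr(x, y)
    return float(r), float(p), "spearman"


def disease_burden(age: float, cag: float) -> float:
    """Disease burden score: ``age * (CAG - 35.5)``."""
    if age <= 0:
        raise ValueError("age must be positive")
    return float(age * (cag - 35.5))


def group_report(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    group_a: str,
    group_b: str,
    dim_map: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Full per-measure comparison report for a two-group cohort.

    One row per measure: group means (SD) and ranges, the test used, the
    raw p value, the Bonferroni-adjusted significance (the divisor is the
    number of measures in the same phonatory dimension) and Cohen's d of
    group A versus group B.
    """
    if dim_map is None:
        dim_map = dict(DIMENSIONS)
    labels = np.asarray(labels)
    rows = []
    for dim, measures in dim_map.items():
        present = [m for m in measures if m in table.columns]
        k = max(len(present), 1)
        for m in present:
            x = pd.to_numeric(table[m], errors="coerce").to_numpy(dtype=float)
            a = x[labels == group_a]
            b = x[labels == group_b]
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if a.size < 3 or b.size < 3:
                continue
            row = compare_groups(a, b)
            rows.append(
                {
                    "dimension": dim,
                    "measure": m,
                    f"mean_{group_a}": row.mean_a,
                    f"sd_{group_a}": row.sd_a,
                    f"range_{group_a}": f"{a.min():.3g}-{a.max():.3g}",
                    f"mean_{group_b}": row.mean_b,
                    f"sd_{group_b}": row.sd_b,
                    f"range_{group_b}": f"{b.min():.3g}-{b.max():.3g}",
                    "test": row.test,
                    "p": row.p_value,
                    "bonferroni_k": k,
                    "significant": row.p_value < ALPHA / k,
                    "cohens_d": row.cohens_d,
                }
            )
    return pd.DataFrame(rows)
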