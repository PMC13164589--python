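"""Two-group comparison machinery for karyotype indices.

Welch's unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
two-sided p-values, and Cohen's d on the pooled SD, entered either from raw
per-plate values or from (mean, sd, n) summaries. The summary path matters
because published karyology routinely reports only ``mean ± SD`` per
species: it is the reproducible entry point when raw plate measurements are
unavailable, and gives slightly different statistics than the raw data the
original test was run on.

Formulas, for groups a and b with means m, sds s and sizes n:

    t  = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    df = (s_a^2/n_a + s_b^2/n_b)^2
         / ((s_a^2/n_a)^2/(n_a-1) + (s_b^2/n_b)^2/(n_b-1))
    d  = |m_a - m_b| / s_pooled,
    s_pooled = sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2))

d is reported unsigned with a separate direction field and a magnitude
label at the conventional thresholds: small 0.2, medium 0.5, large 0.8,
very large > 1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .karyomorph import INDEX_FIELDS

__all__ = [
    "GroupSummary",
    "WelchResult",
    "summarize",
    "welch_t",
    "cohens_d",
    "effect_label",
    "welch_with_effect",
    "compare_indices",
    "compare_index_summaries",
    "significance_stars",
]


@dataclass(frozen=True)
class GroupSummary:
    """(mean, sd, n) of one group; the currency of summary-statistic tests."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size n={self.n} < 2: variance undefined")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float
    d_effect: float | None = None
    d_label: str | None = None
    direction: str | None = None  # "a>b" | "a<b" | "a=b"


def summarize(values: Iterable[float]) -> GroupSummary:
    arr = np.asarray(list(values), dtype=float)
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr))


def _as_summary(group: GroupSummary | Iterable[float]) -> GroupSummary:
    return group if isinstance(group, GroupSummary) else summarize(group)


def welch_t(
    a: GroupSummary | Iterable[float], b: GroupSummary | Iterable[float]
) -> WelchResult:
    """Welch's two-sided t-test from raw values or group summaries."""
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0.0:
        if a.mean == b.mean:
            raise ValueError("both variances zero with equal means: t undefined")
        return WelchResult(
            t_statistic=math.copysign(math.inf, a.mean - b.mean),
            df=float(a.n + b.n - 2),
            p_value=0.0,
        )
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t_statistic=t, df=df, p_value=float(p))


def effect_label(d: float) -> str:
    """Conventional magnitude label for Cohen's d."""
    d = abs(d)
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    if d <= 1.2:
        return "large"
    return "very large"


def cohens_d(
    a: GroupSummary | Iterable[float], b: GroupSummary | Iterable[float]
) -> tuple[float, str]:
    """Unsigned Cohen's d on the pooled SD, with its magnitude label."""
    a, b = _as_summary(a), _as_summary(b)
    if a.n + b.n < 3:
        raise ValueError("need n_a + n_b >= 3 for a pooled SD")
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0.0:
        if a.mean == b.mean:
            return 0.0, "negligible"
        raise ValueError("zero pooled SD with different means: d undefined")
    d = abs(a.mean - b.mean) / math.sqrt(pooled_var)
    return d, effect_label(d)


def welch_with_effect(
    a: GroupSummary | Iterable[float], b: GroupSummary | Iterable[float]
) -> WelchResult:
    a, b = _as_summary(a), _as_summary(b)
    base = welch_t(a, b)
    d, label = cohens_d(a, b)
    direction = "a>b" if a.mean > b.mean else ("a<b" if a.mean < b.mean else "a=b")
    return WelchResult(base.t_statistic, base.df, base.p_value, d, label, direction)


def significance_stars(p: float) -> str:
    """Footnote convention of the karyology tables: * p<0.05, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def compare_indices(
    indices_a: pd.DataFrame,
    indices_b: pd.DataFrame,
    labels: tuple[str, str] = ("a", "b"),
    adjust: str | None = None,
) -> pd.DataFrame:
    """Welch comparison of per-plate karyotype indices between two groups.

    ``indices_a``/``indices_b`` are per-plate index tables (one column per
    index, e.g. from :func:`karyodelim.karyomorph.indices_by_plate`). Returns
    one row per index with group means/SDs, t, df, p, Cohen's d with label,
    and significance stars. ``adjust="bh"`` optionally applies
    Benjamini–Hochberg across the index family (off by default: the
    conventional report leaves these eight comparisons unadjusted).
    """
    indexes = [f for f in INDEX_FIELDS if f in indices_a.columns]
    missing = [f for f in indexes if f not in indices_b.columns]
    if missing:
        raise ValueError(f"index column(s) missing from second group: {', '.join(missing)}")
    if len(indices_a) < 2 or len(indices_b) < 2:
        raise ValueError("need >= 2 plates per group")
    rows = []
    for name in indexes:
        res = welch_with_effect(indices_a[name].to_numpy(), indices_b[name].to_numpy())
        rows.append(
            {
                "index": name,
                f"mean_{labels[0]}": indices_a[name].mean(),
                f"sd_{labels[0]}": indices_a[name].std(ddof=1),
                f"mean_{labels[1]}": indices_b[name].mean(),
                f"sd_{labels[1]}": indices_b[name].std(ddof=1),
                "t": res.t_statistic,
                "df": res.df,
                "p": res.p_value,
                "d": res.d_effect,
                "d_label": res.d_label,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["stars"] = out["p_adj"].map(significance_stars)
    else:
        out["stars"] = out["p"].map(significance_stars)
    return out


def compare_index_summaries(
    summaries_a: dict[str, GroupSummary],
    summaries_b: dict[str, GroupSummary],
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Summary-statistic Welch comparison per index (the reproducible path
    when only published mean ± SD values are available)."""
    rows = []
    for name in summaries_a:
        if name not in summaries_b:
            raise ValueError(f"index {name!r} missing from second group")
        res = welch_with_effect(summaries_a[name], summaries_b[name])
        rows.append(
            {
                "index": name,
                f"mean_{labels[0]}": summaries_a[name].mean,
                f"sd_{labels[0]}": summaries_a[name].sd,
                f"mean_{labels[1]}": summaries_b[name].mean,
                f"sd_{labels[1]}": summaries_b[name].sd,
                "t": res.t_statistic,
                "df": res.df,
                "p": res.p_value,
                "d": res.d_effect,
                "d_label": res.d_label,
                "stars": significance_stars(res.p_value),
            }
        )
    return pd.DataFrame(rows)
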