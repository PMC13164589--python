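"""Seed morphometry: derived ratios, summaries and two-group comparisons.

Five dimensionless ratios are derived per seed — EL/SL (embryo development),
TL/TW (overall elongation), SW/WW (body vs wing), SL/SW (body elongation),
TL/CPL (position of the widest point) — and compared between species.

The mean of per-seed ratios is not in general the ratio of the group means;
published seed tables mix the two conventions, so the report prints both
(``mean_of_ratios`` and ``ratio_of_means``) with the per-seed mean as the
primary statistic.

Two-group comparisons run behind a normality-screen policy: Shapiro–Wilk
per group at alpha = 0.05, a {identity, log} transform ladder, Welch's t
where the screen passes and a Wilcoxon rank-sum test otherwise; the chosen
path is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import SeedRecord, ValidationError
from .karyostats import welch_t

__all__ = [
    "RATIOS",
    "SeedDerived",
    "SeedTestResult",
    "seed_ratios",
    "seed_ratio_frame",
    "compare_seed_trait",
    "seed_mass_summary",
    "seed_summary_table",
]

#: ratio name -> (numerator measurement, denominator measurement)
RATIOS: dict[str, tuple[str, str]] = {
    "EL_SL": ("EL", "SL"),
    "TL_TW": ("TL", "TW"),
    "SW_WW": ("SW", "WW"),
    "SL_SW": ("SL", "SW"),
    "TL_CPL": ("TL", "CPL"),
}


@dataclass(frozen=True)
class SeedDerived:
    EL_SL: float
    TL_TW: float
    SW_WW: float
    SL_SW: float
    TL_CPL: float


@dataclass(frozen=True)
class SeedTestResult:
    trait: str
    path: str  # "welch_t" | "welch_t_log" | "rank_sum"
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool


def seed_ratios(record: SeedRecord) -> SeedDerived:
    values = {}
    for name, (num, den) in RATIOS.items():
        d = getattr(record, den)
        if d == 0:
            raise ValidationError(f"seed {record.seed_id}: zero denominator {den}")
        values[name] = getattr(record, num) / d
    return SeedDerived(**values)


def seed_ratio_frame(records: Sequence[SeedRecord]) -> pd.DataFrame:
    """Per-seed ratio table with species and seed labels."""
    rows = []
    for r in records:
        d = seed_ratios(r)
        rows.append(
            {"species_id": r.species_id, "seed_id": r.seed_id,
             **{k: getattr(d, k) for k in RATIOS}}
        )
    return pd.DataFrame(rows)


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if len(np.unique(values)) < 3:
        return False
    return stats.shapiro(values).pvalue >= alpha


def compare_seed_trait(
    a: Iterable[float],
    b: Iterable[float],
    policy: str = "auto",
    alpha: float = 0.05,
    trait: str = "",
) -> SeedTestResult:
    """Two-group comparison under an explicit test policy.

    ``policy="auto"`` screens both groups with Shapiro–Wilk; if both pass
    on the raw scale Welch's t is used, if both pass after log transform
    Welch's t on logs, otherwise the rank-sum path. ``policy="t"`` or
    ``"rank"`` forces a path.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    norm_a = norm_b = False
    if policy == "auto":
        norm_a, norm_b = _is_normal(a, alpha), _is_normal(b, alpha)
        if norm_a and norm_b:
            path = "welch_t"
        elif (a > 0).all() and (b > 0).all() and _is_normal(np.log(a), alpha) and _is_normal(np.log(b), alpha):
            path = "welch_t_log"
        else:
            path = "rank_sum"
    elif policy == "t":
        path = "welch_t"
    elif policy == "rank":
        path = "rank_sum"
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if path == "rank_sum":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat = float(stat)
        p = float(p)
    else:
        xa, xb = (np.log(a), np.log(b)) if path == "welch_t_log" else (a, b)
        if np.std(xa, ddof=1) == 0 and np.std(xb, ddof=1) == 0 and xa.mean() == xb.mean():
            stat, p = 0.0, 1.0
        else:
            res = welch_t(xa, xb)
            stat, p = res.t_statistic, res.p_value
    return SeedTestResult(trait, path, stat, p, norm_a, norm_b)


def seed_mass_summary(batch_mass_g: float, count: int) -> float:
    """Mean per-seed mass (g) from a weighed batch, to 4 significant digits."""
    if batch_mass_g <= 0:
        raise ValueError("batch mass must be positive")
    if count <= 0:
        raise ValueError("seed count must be positive")
    per_seed = batch_mass_g / count
    return float(f"{per_seed:.4g}")


def seed_summary_table(
    records: Sequence[SeedRecord], policy: str = "auto", alpha: float = 0.05
) -> pd.DataFrame:
    """Species-level seed report: measurements and ratios with letters.

    For each measurement and each per-seed ratio: ``mean ± SD`` per species,
    the chosen test path, p-value, and a/b letters at ``alpha``. Ratio rows
    also carry the ratio of group means (``ratio_of_means``) beside the
    mean of per-seed ratios, since the two conventions differ.
    """
    from .io_tables import SEED_MEASUREMENTS, seed_frame

    meas = seed_frame(records)
    ratio = seed_ratio_frame(records)
    species = sorted(meas["species_id"].unique().tolist())
    if len(species) != 2:
        raise ValueError("seed report compares exactly two species")
    rows = []
    for trait_set, frame in (("measurement", meas), ("ratio", ratio)):
        traits = list(SEED_MEASUREMENTS) if trait_set == "measurement" else list(RATIOS)
        for trait in traits:
            a = frame.loc[frame["species_id"] == species[0], trait].to_numpy()
            b = frame.loc[frame["species_id"] == species[1], trait].to_numpy()
            res = compare_seed_trait(a, b, policy=policy, alpha=alpha, trait=trait)
            sig = res.p_value < alpha
            row = {
                "trait": trait,
                "kind": trait_set,
                f"mean_{species[0]}": a.mean(),
                f"sd_{species[0]}": a.std(ddof=1),
                f"mean_{species[1]}": b.mean(),
                f"sd_{species[1]}": b.std(ddof=1),
                "test_path": res.path,
                "p": res.p_value,
                f"letter_{species[0]}": "a",
                f"letter_{species[1]}": "b" if sig else "a",
            }
            if trait_set == "ratio":
                num, den = RATIOS[trait]
                for sp in species:
                    sub = meas[meas["species_id"] == sp]
                    row[f"ratio_of_means_{sp}"] = sub[num].mean() / sub[den].mean()
            rows.append(row)
    return pd.DataFrame(rows)
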