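"""Karyomorphometry: per-chromosome metrics, morphology classes, karyotype
formulas and asymmetry indices.

Per-chromosome quantities for a pair with long arm ``l`` and short arm ``s``
(micrometres, ``l >= s > 0``):

* total length ``l + s``
* arm ratio (r-index) ``r = l/s``
* centromeric index ``ci = l/(l + s)`` — long-arm convention, so
  ``ci in [0.5, 1)``
* arm difference ratio ``adr = (l - s)/(l + s) = 2*ci - 1``
* relative length ``(l + s)/TCL`` with ``TCL`` the total length of the full
  2n complement.

Aggregates over a complement (or over replicate metaphase plates):
min/max chromosome length, TCL, average chromosome length ACL = TCL/2n,
total haploid length THL = TCL/2, interchromosomal asymmetry
``CV_CL = 100*sd/mean`` of chromosome lengths, intrachromosomal asymmetry
``M_CA = 100*mean(adr)``, and ``CV_CI = 100*sd/mean`` of centromeric
indices. The identity ``adr = 2*ci - 1`` is linear and therefore survives
any averaging of chromosomes; ``r = ci/(1 - ci)`` is nonlinear and holds
per chromosome only.

Chromosome morphology categories follow arm-ratio intervals (default
Levan-derived): m for r in [1, 1.7), sm for [1.7, 3), st for [3, 7),
t for r >= 7, with a configurable borderline band around the sm/st cutoff
reported as the mixed class "sm/st".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import ChromosomeRecord, ValidationError

__all__ = [
    "ChromosomeMetrics",
    "KaryotypeIndices",
    "CategoryAssignment",
    "ClassificationThresholds",
    "chromosome_metrics",
    "relative_lengths",
    "classify_chromosome",
    "classify_complement",
    "classify_r_values",
    "karyotype_formula",
    "aggregate_indices",
    "indices_by_plate",
    "complement_table",
    "INDEX_FIELDS",
]

N_PAIRS_DEFAULT = 12


@dataclass(frozen=True)
class ChromosomeMetrics:
    total_length: float
    r_index: float
    centromeric_index: float
    arm_difference_ratio: float
    relative_length: float | None = None  # deferred until the complement is known


@dataclass(frozen=True)
class KaryotypeIndices:
    """Aggregate karyotype statistics for one complement (lengths in um)."""

    min_length: float
    max_length: float
    tcl: float
    acl: float
    thl: float
    cv_cl: float
    m_ca: float
    cv_ci: float


INDEX_FIELDS = ("min_length", "max_length", "tcl", "acl", "thl", "cv_cl", "m_ca", "cv_ci")


@dataclass(frozen=True)
class CategoryAssignment:
    pair_index: int
    category: str  # m | sm | sm/st | st | t
    sat: bool


@dataclass(frozen=True)
class ClassificationThresholds:
    """Arm-ratio cutoffs between morphology categories.

    ``m_sm``/``sm_st``/``st_t`` are the lower bounds of sm, st and t;
    ``borderline_band`` widens the sm/st cutoff into a mixed class:
    ``|r - sm_st| <= borderline_band`` is reported "sm/st".
    """

    m_sm: float = 1.7
    sm_st: float = 3.0
    st_t: float = 7.0
    borderline_band: float = 0.05


def chromosome_metrics(pair: ChromosomeRecord | tuple[float, float]) -> ChromosomeMetrics:
    """Per-chromosome metrics from one pair's arm lengths.

    The exact identities ``adr = 2*ci - 1`` and ``r = ci/(1 - ci)`` hold on
    the returned values. ``relative_length`` is left unset; use
    :func:`relative_lengths` once the full complement is available.
    """
    l, s = (pair.long_arm, pair.short_arm) if isinstance(pair, ChromosomeRecord) else pair
    if not s > 0:
        raise ValidationError("short arm must be > 0 (r-index undefined)")
    if l < s:
        raise ValidationError(f"arms not ordered: l={l} < s={s}")
    total = l + s
    return ChromosomeMetrics(
        total_length=total,
        r_index=l / s,
        centromeric_index=l / total,
        arm_difference_ratio=(l - s) / total,
    )


def _check_complement(pairs: Sequence[ChromosomeRecord], n_pairs: int) -> None:
    got = sorted(p.pair_index for p in pairs)
    expected = list(range(1, n_pairs + 1))
    if got != expected:
        missing = sorted(set(expected) - set(got))
        extra = sorted(set(got) - set(expected))
        detail = []
        if missing:
            detail.append(f"missing pair indices {missing}")
        if extra:
            detail.append(f"unexpected pair indices {extra}")
        raise ValidationError(f"incomplete complement: {'; '.join(detail)}")


def relative_lengths(
    pairs: Sequence[ChromosomeRecord], n_pairs: int = N_PAIRS_DEFAULT
) -> dict[int, float]:
    """Relative length (l+s)/TCL per pair, TCL = 2 * sum of pair lengths.

    The denominator is the full 2n complement, so the values sum to 1 over
    the 24 chromosomes (0.5 over the 12 pairs).
    """
    _check_complement(pairs, n_pairs)
    tcl = 2.0 * sum(p.total_length for p in pairs)
    return {p.pair_index: p.total_length / tcl for p in pairs}


def classify_chromosome(
    r_index: float, thresholds: ClassificationThresholds | None = None
) -> str:
    """Morphology category from the arm ratio."""
    t = thresholds or ClassificationThresholds()
    if r_index < 1:
        raise ValidationError(f"r-index {r_index} < 1: arms not ordered")
    if abs(r_index - t.sm_st) <= t.borderline_band:
        return "sm/st"
    if r_index < t.m_sm:
        return "m"
    if r_index < t.sm_st:
        return "sm"
    if r_index < t.st_t:
        return "st"
    return "t"


def classify_complement(
    pairs: Sequence[ChromosomeRecord],
    thresholds: ClassificationThresholds | None = None,
) -> list[CategoryAssignment]:
    return [
        CategoryAssignment(
            pair_index=p.pair_index,
            category=classify_chromosome(chromosome_metrics(p).r_index, thresholds),
            sat=p.sat,
        )
        for p in sorted(pairs, key=lambda p: p.pair_index)
    ]


def classify_r_values(
    r_values: Mapping[int, float],
    sat_pairs: Iterable[int] = (),
    thresholds: ClassificationThresholds | None = None,
) -> list[CategoryAssignment]:
    """Assignments from explicit per-pair arm ratios.

    Use this when the available r-indices are plate-level ratio means (as in
    published karyotype tables), which generally differ from ratios
    recomputed from mean arm lengths — the ratio of means is not the mean
    of ratios.
    """
    sat = set(sat_pairs)
    return [
        CategoryAssignment(
            pair_index=i, category=classify_chromosome(r, thresholds), sat=i in sat
        )
        for i, r in sorted(r_values.items())
    ]


_CATEGORY_ORDER = ("m", "m-SAT", "sm", "sm-SAT", "sm/st", "sm/st-SAT", "st", "st-SAT", "t", "t-SAT")


def karyotype_formula(
    assignments: Iterable[CategoryAssignment], n_pairs: int = N_PAIRS_DEFAULT
) -> str:
    """Karyotype formula string, e.g. ``"8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st"``.

    Counts are chromosome counts (two per homologous pair); terms appear in
    canonical category order and must sum to 2n.
    """
    assignments = list(assignments)
    if len(assignments) != n_pairs:
        raise ValidationError(
            f"expected one assignment per pair ({n_pairs}), got {len(assignments)}"
        )
    counts: Counter[str] = Counter()
    for a in assignments:
        term = f"{a.category}-SAT" if a.sat else a.category
        counts[term] += 2
    if sum(counts.values()) != 2 * n_pairs:
        raise ValidationError("term counts do not sum to 2n")  # pragma: no cover
    terms = [f"{counts[c]} {c}" for c in _CATEGORY_ORDER if counts[c]]
    return " + ".join(terms)


def aggregate_indices(
    pairs: Sequence[ChromosomeRecord],
    n_pairs: int = N_PAIRS_DEFAULT,
    ddof: int = 1,
) -> KaryotypeIndices:
    """Karyotype/asymmetry indices for one complement.

    Lengths and centromeric indices enter the CVs at pair level (one value
    per homologous pair, as measured). ``ddof=1`` uses the sample-SD
    denominator conventional for CV reporting; pass ``ddof=0`` for the
    population denominator.
    """
    _check_complement(pairs, n_pairs)
    lengths = np.array([p.total_length for p in pairs], dtype=float)
    if len(np.unique(lengths)) < 2 and len(lengths) < 2:
        raise ValidationError("CV undefined for a single chromosome")
    metrics = [chromosome_metrics(p) for p in pairs]
    ci = np.array([m.centromeric_index for m in metrics])
    adr = np.array([m.arm_difference_ratio for m in metrics])
    tcl = 2.0 * lengths.sum()
    return KaryotypeIndices(
        min_length=float(lengths.min()),
        max_length=float(lengths.max()),
        tcl=float(tcl),
        acl=float(tcl / (2 * n_pairs)),
        thl=float(tcl / 2),
        cv_cl=float(100.0 * lengths.std(ddof=ddof) / lengths.mean()),
        m_ca=float(100.0 * adr.mean()),
        cv_ci=float(100.0 * ci.std(ddof=ddof) / ci.mean()),
    )


def indices_by_plate(
    records: Sequence[ChromosomeRecord],
    n_pairs: int = N_PAIRS_DEFAULT,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-plate indices plus the across-plate mean and SD of each index.

    Returns a DataFrame indexed by plate_id with one column per index; the
    reporting convention for multi-plate karyology is the across-plate
    ``mean ± SD`` of every index, available via ``.mean()``/``.std()`` on
    the result.
    """
    by_plate: dict[str, list[ChromosomeRecord]] = {}
    for r in records:
        by_plate.setdefault(r.plate_id, []).append(r)
    rows = {}
    for plate, pairs in sorted(by_plate.items()):
        idx = aggregate_indices(pairs, n_pairs=n_pairs, ddof=ddof)
        rows[plate] = {f: getattr(idx, f) for f in INDEX_FIELDS}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plate_id"
    return out


def complement_table(
    pairs: Sequence[ChromosomeRecord],
    thresholds: ClassificationThresholds | None = None,
    n_pairs: int = N_PAIRS_DEFAULT,
) -> pd.DataFrame:
    """Per-pair report table: arms, metrics, relative length and category.

    Rounding follows the reporting convention: 2 decimals for um
    quantities, 3 for dimensionless ratios.
    """
    rel = relative_lengths(pairs, n_pairs)
    rows = []
    for p in sorted(pairs, key=lambda p: p.pair_index):
        m = chromosome_metrics(p)
        rows.append(
            {
                "pair_index": p.pair_index,
                "long_arm": round(p.long_arm, 2),
                "short_arm": round(p.short_arm, 2),
                "total_length": round(m.total_length, 2),
                "r_index": round(m.r_index, 3),
                "centromeric_index": round(m.centromeric_index, 3),
                "arm_difference_ratio": round(m.arm_difference_ratio, 3),
                "relative_length": round(rel[p.pair_index], 3),
                "category": classify_chromosome(m.r_index, thresholds),
                "sat": "sat" if p.sat else "none",
            }
        )
    return pd.DataFrame(rows)
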