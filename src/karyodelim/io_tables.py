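"""Reading, validation and writing of the three measurement-table schemas.

Three CSV schemas flow through the pipeline:

* chromosome tables — one row per homologous pair per metaphase plate, with
  long/short arm lengths in micrometres and a satellite flag;
* trait matrices — one row per individual plant, one column per quantitative
  trait, with population and species labels and a sidecar unit map;
* seed tables — one row per seed with the seven linear measurements in mm.

Units are declared, never inferred (the field protocol mixes cm and mm
across traits). Decimal separator is ".", no locale handling. Missing
values are empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "ChromosomeRecord",
    "TraitMatrix",
    "SeedRecord",
    "read_chromosome_table",
    "chromosome_frame",
    "write_chromosome_table",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_seed_table",
    "seed_frame",
    "write_seed_table",
    "write_summary_table",
    "read_summary_table",
]


class SchemaError(ValueError):
    """A required column is missing or an unknown column is present."""


class ValidationError(ValueError):
    """A cell value violates a schema invariant (with row context)."""


# ---------------------------------------------------------------------------
# chromosome tables


@dataclass(frozen=True)
class ChromosomeRecord:
    """One homologous chromosome pair on one metaphase plate.

    ``long_arm >= short_arm > 0`` by convention (lengths in um); ``sat``
    marks satellite presence on the pair (satellite length is excluded
    from the arm lengths — it is an annotation only).
    """

    species_id: str
    plate_id: str
    pair_index: int
    long_arm: float
    short_arm: float
    sat: bool = False

    def __post_init__(self) -> None:
        if not self.short_arm > 0:
            raise ValidationError(
                f"pair {self.pair_index}: short arm must be > 0, got {self.short_arm}"
            )
        if self.long_arm < self.short_arm:
            raise ValidationError(
                f"pair {self.pair_index}: long arm ({self.long_arm}) < "
                f"short arm ({self.short_arm}); arms are not ordered"
            )

    @property
    def total_length(self) -> float:
        return self.long_arm + self.short_arm


_CHROM_ALIASES = {
    "species": "species_id",
    "plate": "plate_id",
    "pair": "pair_index",
    "chromosome_pair": "pair_index",
    "l": "long_arm",
    "long_arm_l": "long_arm",
    "s": "short_arm",
    "short_arm_s": "short_arm",
    "sat_flag": "sat",
    "satellite": "sat",
}

_CHROM_REQUIRED = ("species_id", "pair_index", "long_arm", "short_arm")


def _canonicalize(columns: Iterable[str], aliases: Mapping[str, str]) -> dict[str, str]:
    out = {}
    for c in columns:
        key = c.strip().lower().replace(" ", "_")
        out[c] = aliases.get(key, key)
    return out


def _parse_sat(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"", "none", "nan", "0", "false", "no"}:
        return False
    if text in {"sat", "1", "true", "yes"}:
        return True
    raise ValidationError(f"unrecognized satellite flag {value!r}")


def read_chromosome_table(path: str | Path) -> list[ChromosomeRecord]:
    """Read a per-pair chromosome measurement CSV.

    Headers may use canonical names (``species_id, plate_id, pair_index,
    long_arm, short_arm, sat``) or the short aliases ``l``/``s``/``sat_flag``.
    ``plate_id`` is optional: a table of across-plate mean arm lengths is
    accepted with an implicit single plate ``"mean"``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).rename(
        columns=_canonicalize(pd.read_csv(path, nrows=0).columns, _CHROM_ALIASES)
    )
    missing = [c for c in _CHROM_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if "plate_id" not in df.columns:
        df["plate_id"] = "mean"
    if "sat" not in df.columns:
        df["sat"] = ""

    records: list[ChromosomeRecord] = []
    for i, row in df.iterrows():
        try:
            long_arm = float(row["long_arm"])
            short_arm = float(row["short_arm"])
            pair_index = int(row["pair_index"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name} row {i}: non-numeric value ({exc})") from exc
        try:
            rec = ChromosomeRecord(
                species_id=str(row["species_id"]),
                plate_id=str(row["plate_id"]),
                pair_index=pair_index,
                long_arm=long_arm,
                short_arm=short_arm,
                sat=_parse_sat(row["sat"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
        records.append(rec)

    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.species_id, rec.plate_id, rec.pair_index)
        if key in seen:
            raise ValidationError(
                f"{path.name}: duplicate pair_index {rec.pair_index} for "
                f"({rec.species_id}, {rec.plate_id})"
            )
        seen.add(key)
    if not records:
        logger.warning("%s: no data rows (header only)", path.name)
    logger.info("%s: read %d chromosome records", path.name, len(records))
    return records


def chromosome_frame(records: Sequence[ChromosomeRecord]) -> pd.DataFrame:
    """Tabulate records as a canonical-header DataFrame."""
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "plate_id": [r.plate_id for r in records],
            "pair_index": [r.pair_index for r in records],
            "long_arm": [r.long_arm for r in records],
            "short_arm": [r.short_arm for r in records],
            "sat": ["sat" if r.sat else "none" for r in records],
        }
    )


def write_chromosome_table(records: Sequence[ChromosomeRecord], path: str | Path) -> None:
    chromosome_frame(records).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# trait matrices


@dataclass
class TraitMatrix:
    """Individuals x quantitative traits with group labels and units.

    ``data`` holds one row per individual with ``individual_id``,
    ``population`` and ``species`` label columns followed by trait columns;
    ``units`` maps every trait column to its declared unit ("" for
    dimensionless ratios).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    LABELS = ("individual_id", "population", "species")

    def __post_init__(self) -> None:
        for col in self.LABELS:
            if col not in self.data.columns:
                raise SchemaError(f"trait matrix missing label column {col!r}")
        unmapped = [t for t in self.traits if t not in self.units]
        if unmapped:
            raise SchemaError(f"trait column(s) without declared unit: {', '.join(unmapped)}")
        values = self.data[self.traits]
        bad = values.lt(0)
        if bad.any().any():
            trait = bad.any()[bad.any()].index[0]
            row = int(bad[trait].idxmax())
            raise ValidationError(f"negative value in trait {trait!r} at row {row}")
        pops = self.data.groupby("population")["species"].nunique()
        if (pops > 1).any():
            raise ValidationError(
                f"population(s) mapped to multiple species: "
                f"{', '.join(pops[pops > 1].index)}"
            )

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.LABELS]

    @property
    def n_per_population(self) -> dict[str, int]:
        return self.data["population"].value_counts().to_dict()

    def values(self, traits: Sequence[str] | None = None) -> pd.DataFrame:
        return self.data[list(traits) if traits is not None else self.traits]

    def drop_incomplete(self, traits: Sequence[str]) -> "TraitMatrix":
        """Exclude individuals missing any of ``traits`` (logged)."""
        mask = self.data[list(traits)].notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("excluding %d individuals with missing trait values", dropped)
        return TraitMatrix(self.data[mask].reset_index(drop=True), dict(self.units))


def read_trait_matrix(path: str | Path, unit_map: Mapping[str, str]) -> TraitMatrix:
    """Read an individuals-by-traits CSV; ``unit_map`` must cover every trait."""
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    traits = [c for c in df.columns if c not in TraitMatrix.LABELS]
    unknown = [t for t in traits if t not in unit_map]
    if unknown:
        raise SchemaError(f"{path.name}: trait column(s) not in unit map: {', '.join(unknown)}")
    tm = TraitMatrix(df, {t: unit_map[t] for t in traits})
    logger.info(
        "%s: read %d individuals, %d traits, %d populations",
        path.name, len(df), len(traits), df["population"].nunique(),
    )
    return tm


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    tm.data.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# seed tables

SEED_MEASUREMENTS = ("TL", "TW", "EL", "SL", "SW", "WW", "CPL")


@dataclass(frozen=True)
class SeedRecord:
    """Seven linear measurements (mm) of one seed.

    TL/TW: total length/width including the wing; SL/SW: seed body
    length/width; EL: embryo length; WW: wing width; CPL: distance from the
    TL x TW crossing point to the nearest seed edge. Invariants: all > 0,
    SL <= TL, SW <= TW, EL <= SL.
    """

    species_id: str
    seed_id: str
    TL: float
    TW: float
    EL: float
    SL: float
    SW: float
    WW: float
    CPL: float

    def __post_init__(self) -> None:
        for name in SEED_MEASUREMENTS:
            if not getattr(self, name) > 0:
                raise ValidationError(f"seed {self.seed_id}: {name} must be > 0")
        if self.SL > self.TL:
            raise ValidationError(f"seed {self.seed_id}: SL > TL")
        if self.SW > self.TW:
            raise ValidationError(f"seed {self.seed_id}: SW > TW")
        if self.EL > self.SL:
            raise ValidationError(f"seed {self.seed_id}: EL > SL")


def read_seed_table(path: str | Path) -> list[SeedRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ("species_id", "seed_id", *SEED_MEASUREMENTS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SeedRecord(
                    species_id=str(row["species_id"]),
                    seed_id=str(row["seed_id"]),
                    **{m: float(row[m]) for m in SEED_MEASUREMENTS},
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
    logger.info("%s: read %d seed records", path.name, len(records))
    return records


def seed_frame(records: Sequence[SeedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "seed_id": [r.seed_id for r in records],
            **{m: [getattr(r, m) for r in records] for m in SEED_MEASUREMENTS},
        }
    )


def write_seed_table(records: Sequence[SeedRecord], path: str | Path) -> None:
    seed_frame(records).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# summary tables (mean +/- sd reporting, round-trippable)


def write_summary_table(
    summaries: pd.DataFrame, path: str | Path, decimals: int = 2
) -> None:
    """Write a long-format summary table (group, trait, mean, sd, n).

    The mean and sd are also combined into a human-readable
    ``"mean ± sd"`` display column at the requested precision. Reading the
    file back with :func:`read_summary_table` recovers means and sds to
    that printed precision.
    """
    if summaries.empty:
        raise ValidationError("summary table is empty")
    required = {"group", "trait", "mean", "sd", "n"}
    missing = required - set(summaries.columns)
    if missing:
        raise SchemaError(f"summary frame missing column(s): {', '.join(sorted(missing))}")
    out = summaries.copy()
    out["display"] = [
        f"{m:.{decimals}f} ± {s:.{decimals}f}" for m, s in zip(out["mean"], out["sd"])
    ]
    out.to_csv(path, index=False, float_format=f"%.{decimals + 2}f")


def read_summary_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"group", "trait", "mean", "sd", "n"} - set(df.columns)
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s): {', '.join(sorted(missing))}")
    return df
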