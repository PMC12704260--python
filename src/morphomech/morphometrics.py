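"""Species measurement tables: reading, validation, proportions, summaries.

A skull is measured by five lateral-view lengths — total skull length,
rostrum length (premaxilla to lacrimal), orbital-region length (lacrimal to
postorbital/jugal contact), braincase length (postorbital/jugal contact to
quadrate/squamosal contact), and skull height — plus clade, diet and epoch
labels.  The three region lengths are converted to compositional fractions on
the ternary simplex; skull elongation is the length-to-height ratio.

Because the three measured regions use anatomical endpoints that need not
tile the skull length exactly, ternary coordinates are normalized by the sum
of the three region lengths (canonical) rather than by skull length; both
denominators are reported in summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: exact CSV schema, in column order
CSV_COLUMNS = [
    "species",
    "clade",
    "diet",
    "epoch",
    "skull_length_mm",
    "rostrum_mm",
    "orbit_mm",
    "braincase_mm",
    "skull_height_mm",
]

_MEASUREMENT_COLUMNS = CSV_COLUMNS[4:]

KNOWN_CLADES = (
    "Theropoda",
    "Ceratopsia",
    "Sauropodomorpha",
    "Ornithopoda",
    "Thyreophora",
    "Pachycephalosauria",
    "other",
)
KNOWN_DIETS = ("carnivore", "herbivore", "other/unknown")
KNOWN_EPOCHS = ("Triassic", "Jurassic", "Cretaceous")


class SchemaError(ValueError):
    """The CSV is missing a required column."""


class RowError(ValueError):
    """One or more rows failed to parse or violated a record invariant."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid rows:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class TernaryCoord:
    """Compositional (rostrum, orbit, braincase) fractions summing to 1."""

    r: float
    o: float
    b: float

    def __post_init__(self):
        for name, v in (("r", self.r), ("o", self.o), ("b", self.b)):
            if not math.isfinite(v) or v < -1e-12:
                raise ValueError(f"ternary component {name}={v} must be >= 0")
        s = self.r + self.o + self.b
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"ternary components sum to {s}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.o, self.b])


@dataclass(frozen=True)
class SpeciesRecord:
    """One measured skull: five lengths (mm) plus taxonomic/ecological labels."""

    species_name: str
    clade: str
    diet: str
    epoch: str
    skull_length: float
    rostrum_length: float
    orbit_length: float
    braincase_length: float
    skull_height: float

    def validate(self) -> None:
        """Raise ValueError on invariant violations; warn on soft violations.

        Hard errors: non-positive lengths, a region length not smaller than
        skull length, or a region-length sum outside [0.5, 1.5] x skull
        length.  A sum outside [0.85, 1.15] x skull length only logs a
        warning (measurement endpoints need not tile the skull exactly).
        """
        lengths = {
            "skull_length": self.skull_length,
            "rostrum_length": self.rostrum_length,
            "orbit_length": self.orbit_length,
            "braincase_length": self.braincase_length,
            "skull_height": self.skull_height,
        }
        for name, v in lengths.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.species_name}: {name}={v} must be strictly positive")
        for name in ("rostrum_length", "orbit_length", "braincase_length"):
            if lengths[name] >= self.skull_length:
                raise ValueError(
                    f"{self.species_name}: {name}={lengths[name]} must be < skull_length={self.skull_length}"
                )
        total = self.rostrum_length + self.orbit_length + self.braincase_length
        rel = total / self.skull_length
        if not (0.5 <= rel <= 1.5):
            raise ValueError(
                f"{self.species_name}: region sum {total:.1f} is {rel:.2f}x skull length, outside [0.5, 1.5]"
            )
        if not (0.85 <= rel <= 1.15):
            logger.warning(
                "%s: region sum is %.2fx skull length (outside [0.85, 1.15])",
                self.species_name,
                rel,
            )


def proportions(rec: SpeciesRecord) -> TernaryCoord:
    """Compositional fractions of the three skull regions.

    Normalized by the sum of the three region lengths so the result lies
    exactly on the simplex.
    """
    total = rec.rostrum_length + rec.orbit_length + rec.braincase_length
    if total <= 0:
        raise ValueError(f"{rec.species_name}: zero region-length sum")
    return TernaryCoord(
        rec.rostrum_length / total,
        rec.orbit_length / total,
        rec.braincase_length / total,
    )


def skull_ratio(rec: SpeciesRecord) -> float:
    """Length-to-height ratio (dimensionless elongation measure)."""
    if rec.skull_height <= 0:
        raise ValueError(f"{rec.species_name}: skull_height must be > 0")
    return rec.skull_length / rec.skull_height


def records_to_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical CSV schema."""
    return pd.DataFrame(
        {
            "species": [r.species_name for r in records],
            "clade": [r.clade for r in records],
            "diet": [r.diet for r in records],
            "epoch": [r.epoch for r in records],
            "skull_length_mm": [r.skull_length for r in records],
            "rostrum_mm": [r.rostrum_length for r in records],
            "orbit_mm": [r.orbit_length for r in records],
            "braincase_mm": [r.braincase_length for r in records],
            "skull_height_mm": [r.skull_height for r in records],
        }
    )


def write_species_table(records: list[SpeciesRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6g")


def _record_from_row(row: pd.Series) -> SpeciesRecord:
    diet = row["diet"] if isinstance(row["diet"], str) and row["diet"].strip() else "other/unknown"
    epoch = row["epoch"] if isinstance(row["epoch"], str) and row["epoch"].strip() else "other/unknown"
    clade = row["clade"] if isinstance(row["clade"], str) and row["clade"].strip() else "other"
    return SpeciesRecord(
        species_name=str(row["species"]),
        clade=clade,
        diet=diet,
        epoch=epoch,
        skull_length=float(row["skull_length_mm"]),
        rostrum_length=float(row["rostrum_mm"]),
        orbit_length=float(row["orbit_mm"]),
        braincase_length=float(row["braincase_mm"]),
        skull_height=float(row["skull_height_mm"]),
    )


def read_species_table(path) -> list[SpeciesRecord]:
    """Read and validate a species measurement CSV.

    Duplicate species rows (a redundant-measurement design) are collapsed by
    the arithmetic mean of the measurements; duplicate pairs differing by
    more than 20% in any measurement are flagged to the log.  Invalid rows
    are collected and reported together in a :class:`RowError`, never
    silently dropped.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    problems: list[str] = []
    for col in _MEASUREMENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            problems.append(f"row {i + 2} ({df.at[i, 'species']}): non-numeric {col}={df.at[i, col]!r}")
        df[col] = coerced
    nan_rows = df.index[df[_MEASUREMENT_COLUMNS].isna().any(axis=1)]
    for i in nan_rows:
        if not any(f"row {i + 2} " in p for p in problems):
            problems.append(f"row {i + 2} ({df.at[i, 'species']}): missing measurement")
    if problems:
        raise RowError(problems)

    # collapse redundant measurements of the same species
    for name, group in df.groupby("species", sort=False):
        if len(group) > 1:
            vals = group[_MEASUREMENT_COLUMNS].to_numpy(float)
            spread = vals.max(axis=0) / np.maximum(vals.min(axis=0), 1e-300) - 1.0
            if (spread > 0.20).any():
                cols = [c for c, s in zip(_MEASUREMENT_COLUMNS, spread) if s > 0.20]
                logger.warning(
                    "species %s: duplicate measurements differ by >20%% in %s", name, ", ".join(cols)
                )
    agg = {c: "mean" for c in _MEASUREMENT_COLUMNS}
    agg.update({"clade": "first", "diet": "first", "epoch": "first"})
    collapsed = df.groupby("species", sort=False, as_index=False).agg(agg)

    records = []
    for _, row in collapsed.iterrows():
        rec = _record_from_row(row)
        try:
            rec.validate()
        except ValueError as exc:
            problems.append(str(exc))
            continue
        records.append(rec)
    if problems:
        raise RowError(problems)
    return records


@dataclass
class DatasetSummary:
    """Per-metric descriptive statistics, overall and grouped by label.

    Metrics: the three ternary components as percentages (both of the
    region-length sum, canonical, and of skull length) and the
    length-to-height skull ratio.
    """

    n_species: int
    overall: pd.DataFrame
    by_clade: pd.DataFrame = field(repr=False, default=None)
    by_diet: pd.DataFrame = field(repr=False, default=None)
    by_epoch: pd.DataFrame = field(repr=False, default=None)

    def __str__(self) -> str:
        parts = [f"Dataset summary: {self.n_species} species", "", str(self.overall.round(3))]
        for label, tbl in (("clade", self.by_clade), ("diet", self.by_diet), ("epoch", self.by_epoch)):
            if tbl is not None and len(tbl):
                parts += ["", f"By {label}:", str(tbl.round(3))]
        return "\n".join(parts)

    def to_csv(self, path) -> None:
        self.overall.to_csv(path)


_STATS = ("min", "max", "mean", "std")


def _metric_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    rows = {}
    for rec in records:
        t = proportions(rec)
        sl = rec.skull_length
        rows[rec.species_name] = {
            "rostrum_pct": 100 * t.r,
            "orbit_pct": 100 * t.o,
            "braincase_pct": 100 * t.b,
            "rostrum_pct_skull": 100 * rec.rostrum_length / sl,
            "orbit_pct_skull": 100 * rec.orbit_length / sl,
            "braincase_pct_skull": 100 * rec.braincase_length / sl,
            "skull_ratio": skull_ratio(rec),
            "clade": rec.clade,
            "diet": rec.diet,
            "epoch": rec.epoch,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize(records: list[SpeciesRecord]) -> DatasetSummary:
    """Min/max/mean/sd of ternary percentages and skull ratio.

    Grouped breakdowns by clade, diet and epoch exclude records whose label
    is "other/unknown"; such records remain in the overall statistics.
    """
    if not records:
        raise ValueError("summarize requires at least one record")
    df = _metric_frame(records)
    metric_cols = [c for c in df.columns if c not in ("clade", "diet", "epoch")]
    overall = df[metric_cols].agg(list(_STATS)).T

    def grouped(label: str) -> pd.DataFrame:
        sub = df[~df[label].isin(("other/unknown", "other"))] if label != "clade" else df
        if sub.empty:
            return pd.DataFrame()
        return sub.groupby(label)[metric_cols].agg(list(_STATS))

    return DatasetSummary(
        n_species=len(records),
        overall=overall,
        by_clade=grouped("clade"),
        by_diet=grouped("diet"),
        by_epoch=grouped("epoch"),
    )
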