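"""Domain records, tidy-CSV input/output, and soil-chemistry helpers.

Four tabular schemas are supported, all UTF-8 comma-delimited CSV with a
mandatory header row, ``.`` decimal mark, and missing values written as an
empty field:

``germination``
    Long format, one row per census observation:
    ``accession_id, treatment, n_sown, n_viable, census_day,
    cumulative_germinated``. Rows sharing ``accession_id`` and ``treatment``
    are assembled into one :class:`GerminationTrial`.
``ordinal``
    One row per seed: ``accession_id, species, soil_code, block, treatment,
    seed_index, score`` (score on the 0-5 establishment scale).
``growth``
    One row per seedling: ``accession_id, species, ph_level, das, replicate,
    hypocotyl_mm, epicotyl_mm`` (either organ may be empty = not measured).
``soil``
    One row per soil: physicochemical descriptors plus the as-reported
    Ca-based cation ratios (never recomputed here, since Ca concentration is
    not part of the profile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SPECIES = ("albus", "angustifolius", "luteus")
TREATMENTS = ("NS", "S")
PH_LEVELS = (5.5, 7.0, 8.5)
DAS_LEVELS = (7, 14)
SOIL_CODES = ("MEC", "BV", "COPSA", "COPMO", "MBG3")

#: equivalent weights in g/eq, fixed by convention: Mg2+ 24.305/2 -> 12.153, K+ 39.098/1
EQUIV_WEIGHT_MG = 12.153
EQUIV_WEIGHT_K = 39.098


class SchemaError(ValueError):
    """Unknown schema, missing file, or header/column mismatch."""


class RecordValidationError(ValueError):
    """A row violates a type invariant; carries the 1-based data row and field."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", field '{field}'" if field else "") + ")"
        super().__init__(message + loc)


def _require(cond: bool, message: str, row: int | None = None, field: str | None = None) -> None:
    if not cond:
        raise RecordValidationError(message, row=row, field=field)


@dataclass(frozen=True)
class GerminationTrial:
    """Weekly germination census for one accession x scarification treatment.

    ``cumulative_germinated`` is aligned to ``census_days`` (days since
    sowing) and counts seeds germinated by each census, out of ``n_viable``
    viable seeds (non-germinated seeds are viability-checked at the end of
    the assay, so the viable count is known per dish).
    """

    accession_id: str
    treatment: str
    n_sown: int
    n_viable: int
    census_days: tuple[int, ...]
    cumulative_germinated: tuple[int, ...]

    def __post_init__(self):
        _require(self.treatment in TREATMENTS, f"treatment must be one of {TREATMENTS}, got {self.treatment!r}", field="treatment")
        _require(0 <= self.n_viable <= self.n_sown, "need 0 <= n_viable <= n_sown", field="n_viable")
        days = self.census_days
        cum = self.cumulative_germinated
        _require(len(days) == len(cum) and len(days) > 0, "census_days and cumulative_germinated must align and be non-empty", field="census_days")
        _require(all(d >= 1 for d in days), "census days must be >= 1", field="census_day")
        _require(all(days[i] < days[i + 1] for i in range(len(days) - 1)), "census days must be strictly increasing", field="census_day")
        _require(all(int(c) == c and c >= 0 for c in cum), "cumulative counts must be non-negative integers", field="cumulative_germinated")
        _require(all(cum[i] <= cum[i + 1] for i in range(len(cum) - 1)), "cumulative counts must be non-decreasing", field="cumulative_germinated")
        _require(cum[-1] <= self.n_viable, "cumulative count exceeds viable seeds", field="cumulative_germinated")

    @property
    def newly_germinated(self) -> tuple[int, ...]:
        prev = (0,) + self.cumulative_germinated[:-1]
        return tuple(c - p for c, p in zip(self.cumulative_germinated, prev))


@dataclass(frozen=True)
class OrdinalOutcomeRecord:
    """One seed's 0-5 establishment score in the multi-soil trial."""

    accession_id: str
    species: str
    soil_code: str
    block: int
    treatment: str
    seed_index: int
    score: int

    def __post_init__(self):
        _require(self.species in SPECIES, f"species must be one of {SPECIES}, got {self.species!r}", field="species")
        _require(self.treatment in TREATMENTS, f"treatment must be one of {TREATMENTS}", field="treatment")
        _require(1 <= self.block <= 3, "block must be 1..3", field="block")
        _require(self.score in range(6), f"score must be in 0..5, got {self.score}", field="score")


@dataclass(frozen=True)
class SeedlingGrowthRecord:
    """One seedling's organ lengths in the substrate-pH trial.

    Either organ may be ``None`` (not measured); such seedlings are retained
    but excluded from growth and allocation analyses downstream.
    """

    accession_id: str
    species: str
    ph_level: float
    das: int
    replicate: int
    hypocotyl_mm: float | None
    epicotyl_mm: float | None

    def __post_init__(self):
        _require(self.species in SPECIES, f"species must be one of {SPECIES}", field="species")
        _require(self.ph_level in PH_LEVELS, f"ph_level must be one of {PH_LEVELS}, got {self.ph_level}", field="ph_level")
        _require(self.das in DAS_LEVELS, f"das must be one of {DAS_LEVELS}, got {self.das}", field="das")
        _require(1 <= self.replicate <= 3, "replicate must be 1..3", field="replicate")
        for f in ("hypocotyl_mm", "epicotyl_mm"):
            v = getattr(self, f)
            _require(v is None or v >= 0, f"{f} must be >= 0 when present", field=f)


@dataclass(frozen=True)
class SoilProfile:
    """Physicochemical descriptors of one experimental soil.

    ``ca_mg`` and ``ca_k`` are stored as reported (Ca concentration is not a
    field, so they cannot be recomputed); the Mg/K charge-equivalent ratio is
    computed from the ppm concentrations via :func:`cation_ratio_mg_k`.
    """

    soil_code: str
    ph_h2o: float
    ph_kcl: float
    om_pct: float
    p_ppm: float
    k_ppm: float
    mg_ppm: float
    cec: float
    ec: float
    texture: str
    ca_mg: float | None = None
    ca_k: float | None = None

    def __post_init__(self):
        _require(0 < self.ph_h2o < 14, "ph_h2o must be in (0, 14)", field="ph_h2o")
        for f in ("om_pct", "p_ppm", "k_ppm", "mg_ppm", "cec", "ec"):
            _require(getattr(self, f) >= 0, f"{f} must be >= 0", field=f)

    @property
    def mg_k_equiv_ratio(self) -> float:
        return cation_ratio_mg_k(self.mg_ppm, self.k_ppm)


def cation_ratio_mg_k(mg_ppm: float, k_ppm: float) -> float:
    """Charge-equivalent (meq-basis) Mg/K ratio from mg/kg concentrations.

    Converts each concentration to meq/100g-equivalent units by dividing by
    the equivalent weight (Mg 12.153, K 39.098 g/eq) before taking the ratio,
    so the result is dimensionless and homogeneous of degree 0.
    """
    if k_ppm == 0:
        raise ValueError("Mg/K ratio undefined: k_ppm is zero")
    if mg_ppm < 0 or k_ppm < 0:
        raise ValueError("concentrations must be non-negative")
    return (mg_ppm / EQUIV_WEIGHT_MG) / (k_ppm / EQUIV_WEIGHT_K)


def reference_soils() -> list[SoilProfile]:
    """The bundled five-soil Mediterranean citrus-orchard panel.

    Composite-sample means for the five experimental soils (MEC, BV, COPSA,
    COPMO, MBG3) spanning acidic to very alkaline pH and low to very high
    organic matter.
    """
    rows = [
        ("MEC", 8.4, 7.9, 1.6, 21.0, 172.0, 206.1, 26.7, 0.10, "loam", 15.1, 56.7),
        ("BV", 7.3, 7.3, 7.2, 187.1, 1504.0, 696.1, 34.5, 0.70, "clay loam", 4.0, 6.5),
        ("COPSA", 8.3, 7.6, 2.5, 12.0, 204.0, 184.0, 31.6, 0.17, "clay loam", 20.1, 57.5),
        ("COPMO", 8.2, 7.4, 3.1, 44.0, 566.0, 312.0, 34.9, 0.13, "clay loam", 12.0, 21.8),
        ("MBG3", 6.3, 5.7, 5.6, 54.0, 130.0, 96.1, 12.9, 0.00, "clay loam", 15.1, 36.3),
    ]
    return [
        SoilProfile(code, ph_h2o, ph_kcl, om, p, k, mg, cec, ec, tex, ca_mg=cm, ca_k=ck)
        for code, ph_h2o, ph_kcl, om, p, k, mg, cec, ec, tex, cm, ck in rows
    ]


# ---------------------------------------------------------------------------
# CSV schemas


GERMINATION_COLUMNS = ["accession_id", "treatment", "n_sown", "n_viable", "census_day", "cumulative_germinated"]
ORDINAL_COLUMNS = ["accession_id", "species", "soil_code", "block", "treatment", "seed_index", "score"]
GROWTH_COLUMNS = ["accession_id", "species", "ph_level", "das", "replicate", "hypocotyl_mm", "epicotyl_mm"]
SOIL_COLUMNS = ["soil_code", "ph_h2o", "ph_kcl", "om_pct", "p_ppm", "k_ppm", "mg_ppm", "cec", "ec", "texture", "ca_mg", "ca_k"]

SCHEMAS = {
    "germination": GERMINATION_COLUMNS,
    "ordinal": ORDINAL_COLUMNS,
    "growth": GROWTH_COLUMNS,
    "soil": SOIL_COLUMNS,
}


def _read_csv(path: str | Path, schema: str) -> pd.DataFrame:
    path = Path(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise SchemaError(f"{path}: header mismatch for schema {schema!r}: missing {missing}, unknown {unknown}")
    return df


def _to_int(value: str, row: int, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise RecordValidationError(f"expected integer, got {value!r}", row=row, field=field) from None


def _to_float(value: str, row: int, field: str, optional: bool = False) -> float | None:
    if value == "":
        if optional:
            return None
        raise RecordValidationError("missing value", row=row, field=field)
    try:
        return float(value)
    except ValueError:
        raise RecordValidationError(f"expected number, got {value!r}", row=row, field=field) from None


def read_table(path: str | Path, schema: str):
    """Read and validate a tidy CSV; returns a list of typed records.

    Raises :class:`SchemaError` on file/header problems and
    :class:`RecordValidationError` (naming the 1-based data row and field)
    on the first invariant violation.
    """
    df = _read_csv(path, schema)
    if schema == "germination":
        return _read_germination(df)
    builders = {"ordinal": _read_ordinal_row, "growth": _read_growth_row, "soil": _read_soil_row}
    build = builders[schema]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(build(row, i))
        except RecordValidationError as exc:
            if exc.row is None:
                raise RecordValidationError(exc.args[0], row=i, field=exc.field) from exc
            raise
        except ValueError as exc:
            raise RecordValidationError(str(exc), row=i) from exc
    return records


def _read_germination(df: pd.DataFrame) -> list[GerminationTrial]:
    trials: list[GerminationTrial] = []
    df = df.copy()
    df["_row"] = range(1, len(df) + 1)
    for (acc, trt), grp in df.groupby(["accession_id", "treatment"], sort=True):
        first_row = int(grp["_row"].iloc[0])
        n_sown = {_to_int(v, int(r), "n_sown") for v, r in zip(grp["n_sown"], grp["_row"])}
        n_viable = {_to_int(v, int(r), "n_viable") for v, r in zip(grp["n_viable"], grp["_row"])}
        if len(n_sown) != 1 or len(n_viable) != 1:
            raise RecordValidationError(f"inconsistent n_sown/n_viable within trial {acc}/{trt}", row=first_row)
        pairs = sorted(
            (_to_int(d, int(r), "census_day"), _to_int(c, int(r), "cumulative_germinated"))
            for d, c, r in zip(grp["census_day"], grp["cumulative_germinated"], grp["_row"])
        )
        try:
            trials.append(
                GerminationTrial(
                    accession_id=str(acc),
                    treatment=str(trt),
                    n_sown=n_sown.pop(),
                    n_viable=n_viable.pop(),
                    census_days=tuple(p[0] for p in pairs),
                    cumulative_germinated=tuple(p[1] for p in pairs),
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(f"trial {acc}/{trt}: {exc.args[0]}", row=first_row, field=exc.field) from exc
    return trials


def _read_ordinal_row(row, i: int) -> OrdinalOutcomeRecord:
    return OrdinalOutcomeRecord(
        accession_id=row.accession_id,
        species=row.species,
        soil_code=row.soil_code,
        block=_to_int(row.block, i, "block"),
        treatment=row.treatment,
        seed_index=_to_int(row.seed_index, i, "seed_index"),
        score=_to_int(row.score, i, "score"),
    )


def _read_growth_row(row, i: int) -> SeedlingGrowthRecord:
    return SeedlingGrowthRecord(
        accession_id=row.accession_id,
        species=row.species,
        ph_level=_to_float(row.ph_level, i, "ph_level"),
        das=_to_int(row.das, i, "das"),
        replicate=_to_int(row.replicate, i, "replicate"),
        hypocotyl_mm=_to_float(row.hypocotyl_mm, i, "hypocotyl_mm", optional=True),
        epicotyl_mm=_to_float(row.epicotyl_mm, i, "epicotyl_mm", optional=True),
    )


def _read_soil_row(row, i: int) -> SoilProfile:
    return SoilProfile(
        soil_code=row.soil_code,
        ph_h2o=_to_float(row.ph_h2o, i, "ph_h2o"),
        ph_kcl=_to_float(row.ph_kcl, i, "ph_kcl"),
        om_pct=_to_float(row.om_pct, i, "om_pct"),
        p_ppm=_to_float(row.p_ppm, i, "p_ppm"),
        k_ppm=_to_float(row.k_ppm, i, "k_ppm"),
        mg_ppm=_to_float(row.mg_ppm, i, "mg_ppm"),
        cec=_to_float(row.cec, i, "cec"),
        ec=_to_float(row.ec, i, "ec"),
        texture=row.texture,
        ca_mg=_to_float(row.ca_mg, i, "ca_mg", optional=True),
        ca_k=_to_float(row.ca_k, i, "ca_k", optional=True),
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)  # shortest repr round-trips exactly
    return str(value)


def write_table(path: str | Path, records: Sequence) -> None:
    """Write typed records back to their tidy CSV schema (inverse of read_table)."""
    if not records:
        raise ValueError("cannot infer schema from an empty record collection")
    first = records[0]
    if isinstance(first, GerminationTrial):
        rows = []
        for t in records:
            for d, c in zip(t.census_days, t.cumulative_germinated):
                rows.append([t.accession_id, t.treatment, t.n_sown, t.n_viable, d, c])
        df = pd.DataFrame(rows, columns=GERMINATION_COLUMNS)
    elif isinstance(first, (OrdinalOutcomeRecord, SeedlingGrowthRecord, SoilProfile)):
        cols = [f.name for f in dc_fields(type(first))]
        df = pd.DataFrame([[_fmt(getattr(r, c)) for c in cols] for r in records], columns=cols)
    else:
        raise TypeError(f"unsupported record type {type(first).__name__}")
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Flatten a homogeneous record collection to a DataFrame (analysis-side view)."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    cols = [f.name for f in dc_fields(type(records[0]))]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
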