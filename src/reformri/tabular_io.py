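"""Domain types and tabular I/O.

The package works with flat tables of subject scans (one row per scan:
id, age, sex, site/batch, a continuous phenotype value, and an optional
clinical group) and exchanges fitted reference intervals as small gridded
CSV files (sex, age, lower, upper) so that a chart fitted at one site can
be calibrated at another without sharing subject-level reference data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, RowParseError, SchemaError

__all__ = [
    "TableSchema",
    "PhenotypeRecord",
    "DataSplit",
    "ReferenceInterval",
    "GriddedInterval",
    "read_phenotype_table",
    "write_phenotype_table",
    "records_to_frame",
    "frame_to_records",
    "write_gridded_interval",
    "read_gridded_interval",
    "interpolate_interval",
    "evaluate_bounds",
]

SEX_LEVELS = ("F", "M")
GROUP_LEVELS = ("CN", "CASE")


@dataclass(frozen=True)
class TableSchema:
    """Column naming and level conventions for a phenotype table."""

    subject_id: str = "subject_id"
    age: str = "age"
    sex: str = "sex"
    batch: str = "batch"
    value: str = "value"
    group: str = "group"
    sex_levels: tuple = SEX_LEVELS
    group_levels: tuple = GROUP_LEVELS
    age_range: tuple = (18.0, 100.0)
    delimiter: str | None = None  # None -> sniffed by pandas


@dataclass(frozen=True)
class PhenotypeRecord:
    """One subject scan."""

    subject_id: str
    age: float
    sex: str
    batch: str
    value: float
    group: str = "CN"

    def validate(self, schema: TableSchema = TableSchema()) -> "PhenotypeRecord":
        if not np.isfinite(self.age):
            raise SchemaError(f"record {self.subject_id}: non-finite age")
        lo, hi = schema.age_range
        if not (lo <= self.age <= hi):
            raise SchemaError(
                f"record {self.subject_id}: age {self.age} outside study range [{lo}, {hi}]"
            )
        if not np.isfinite(self.value):
            raise SchemaError(f"record {self.subject_id}: non-finite value")
        if self.sex not in schema.sex_levels:
            raise SchemaError(
                f"record {self.subject_id}: unknown sex level {self.sex!r} "
                f"(expected one of {schema.sex_levels})"
            )
        if self.group not in schema.group_levels:
            raise SchemaError(
                f"record {self.subject_id}: unknown group level {self.group!r}"
            )
        return self


@dataclass(frozen=True)
class DataSplit:
    """Disjoint reference / calibration / validation subject-id sets."""

    reference_ids: frozenset
    calibration_ids: frozenset
    validation_ids: frozenset

    def __post_init__(self):
        object.__setattr__(self, "reference_ids", frozenset(self.reference_ids))
        object.__setattr__(self, "calibration_ids", frozenset(self.calibration_ids))
        object.__setattr__(self, "validation_ids", frozenset(self.validation_ids))
        pairs = [
            (self.reference_ids, self.calibration_ids),
            (self.reference_ids, self.validation_ids),
            (self.calibration_ids, self.validation_ids),
        ]
        if any(a & b for a, b in pairs):
            raise SchemaError("data split sets must be pairwise disjoint")

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)


@dataclass
class ReferenceInterval:
    """A covariate-dependent band [lower(x), upper(x)] at miscoverage alpha.

    ``lower`` and ``upper`` are callables mapping ``(ages, sexes)`` arrays to
    bound values.  Naive intervals satisfy lower <= upper everywhere they are
    evaluable; calibrated intervals may cross (empty-interval semantics) and
    then carry a crossing note in ``provenance``.
    """

    alpha: float
    lower: Callable
    upper: Callable
    calibrated: bool = False
    provenance: str = ""

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise SchemaError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def constant(cls, alpha: float, lower: float, upper: float, **kw) -> "ReferenceInterval":
        lo, hi = float(lower), float(upper)
        return cls(
            alpha=alpha,
            lower=lambda ages, sexes: np.full(np.shape(np.atleast_1d(ages)), lo),
            upper=lambda ages, sexes: np.full(np.shape(np.atleast_1d(ages)), hi),
            **kw,
        )

    def shifted(self, c_lower: float, c_upper: float, **kw) -> "ReferenceInterval":
        """Widen by subtracting ``c_lower`` below and adding ``c_upper`` above."""
        base_lower, base_upper = self.lower, self.upper
        return replace(
            self,
            lower=lambda ages, sexes: base_lower(ages, sexes) - c_lower,
            upper=lambda ages, sexes: base_upper(ages, sexes) + c_upper,
            **kw,
        )


def evaluate_bounds(interval: ReferenceInterval, ages, sexes):
    """Evaluate (lower, upper) at paired covariates; returns two arrays."""
    ages = np.atleast_1d(np.asarray(ages, float))
    sexes = np.atleast_1d(np.asarray(sexes, dtype=object))
    if sexes.shape != ages.shape:
        sexes = np.broadcast_to(sexes, ages.shape)
    lo = np.asarray(interval.lower(ages, sexes), float)
    hi = np.asarray(interval.upper(ages, sexes), float)
    return lo, hi


# ---------------------------------------------------------------------------
# Phenotype tables


def _parse_float(raw: str, column: str, line_number: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowParseError(
            f"line {line_number}: cannot parse {column}={raw!r} as a number",
            line_number=line_number,
        ) from None


def read_phenotype_table(path, schema: TableSchema = TableSchema()):
    """Read a delimited phenotype table into validated records.

    Rows with a *missing* age, sex or value are dropped (the dropped count is
    returned); a present but unparseable numeric raises :class:`RowParseError`
    naming the offending line.

    Returns ``(records, n_dropped)``.
    """
    sep = schema.delimiter
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else None,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
        comment="#",
    )
    required = [schema.subject_id, schema.age, schema.sex, schema.batch, schema.value]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandated column {col!r}")
    has_group = schema.group in df.columns
    records, n_dropped = [], 0
    for idx, row in df.iterrows():
        line_number = idx + 2  # header is line 1
        age_raw = row[schema.age].strip()
        sex_raw = row[schema.sex].strip()
        val_raw = row[schema.value].strip()
        if not age_raw or not sex_raw or not val_raw:
            n_dropped += 1
            continue
        rec = PhenotypeRecord(
            subject_id=str(row[schema.subject_id]).strip(),
            age=_parse_float(age_raw, schema.age, line_number),
            sex=sex_raw,
            batch=str(row[schema.batch]).strip(),
            value=_parse_float(val_raw, schema.value, line_number),
            group=(row[schema.group].strip() or "CN") if has_group else "CN",
        )
        records.append(rec.validate(schema))
    return records, n_dropped


def records_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    recs = list(records)
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recs],
            "age": np.array([r.age for r in recs], float),
            "sex": [r.sex for r in recs],
            "batch": [r.batch for r in recs],
            "value": np.array([r.value for r in recs], float),
            "group": [r.group for r in recs],
        }
    )


def frame_to_records(df: pd.DataFrame, schema: TableSchema = TableSchema()):
    return [
        PhenotypeRecord(
            subject_id=str(row[schema.subject_id]),
            age=float(row[schema.age]),
            sex=str(row[schema.sex]),
            batch=str(row[schema.batch]),
            value=float(row[schema.value]),
            group=str(row[schema.group]) if schema.group in df.columns else "CN",
        ).validate(schema)
        for _, row in df.iterrows()
    ]


def write_phenotype_table(records, path, schema: TableSchema = TableSchema()):
    df = records_to_frame(records)
    df.columns = [
        schema.subject_id,
        schema.age,
        schema.sex,
        schema.batch,
        schema.value,
        schema.group,
    ]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gridded reference-interval exchange format


@dataclass
class GriddedInterval:
    """A reference interval tabulated on an age grid, one block per sex."""

    alpha: float
    age_grid: np.ndarray
    bounds: dict  # sex -> (lower values, upper values)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, float)
        if self.age_grid.ndim != 1 or np.any(np.diff(self.age_grid) <= 0):
            raise SchemaError("age grid must be strictly increasing")
        for sex, (lo, hi) in self.bounds.items():
            lo, hi = np.asarray(lo, float), np.asarray(hi, float)
            if lo.shape != self.age_grid.shape or hi.shape != self.age_grid.shape:
                raise SchemaError(f"sex {sex}: bound arrays must match the age grid")
            if np.any(hi < lo):
                raise SchemaError(f"sex {sex}: upper < lower at a grid point")
            self.bounds[sex] = (lo, hi)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_gridded_interval(
    interval: ReferenceInterval,
    age_grid,
    sexes: Sequence[str],
    path,
    metadata: dict | None = None,
) -> GriddedInterval:
    """Tabulate ``interval`` on ``age_grid`` per sex and write it as CSV.

    Floats are serialised via ``repr`` so a write -> read -> write cycle is
    byte-identical.  Metadata lines are ``#``-prefixed ``key: value`` pairs;
    alpha and the calibration flag are always recorded.
    """
    age_grid = np.asarray(age_grid, float)
    meta = dict(metadata or {})
    meta.pop("calibrated", None)  # recorded from the interval itself
    meta.setdefault("model", interval.provenance or "unspecified")
    bounds = {}
    for sex in sexes:
        sex_arr = np.full(age_grid.shape, sex, dtype=object)
        lo = np.asarray(interval.lower(age_grid, sex_arr), float)
        hi = np.asarray(interval.upper(age_grid, sex_arr), float)
        bad = ~(np.isfinite(lo) & np.isfinite(hi))
        if np.any(bad):
            age_bad = age_grid[bad][0]
            raise ExtrapolationError(
                f"interval not evaluable at (age={age_bad}, sex={sex})"
            )
        bounds[sex] = (lo, hi)
    gridded = GriddedInterval(
        alpha=interval.alpha, age_grid=age_grid, bounds=bounds, metadata=meta
    )
    buf = io.StringIO()
    buf.write(f"# alpha: {_fmt(interval.alpha)}\n")
    buf.write(f"# calibrated: {str(interval.calibrated).lower()}\n")
    for key in sorted(meta):
        buf.write(f"# {key}: {meta[key]}\n")
    buf.write("sex,age,lower,upper\n")
    for sex in sexes:
        lo, hi = bounds[sex]
        for a, l, u in zip(age_grid, lo, hi):
            buf.write(f"{sex},{_fmt(a)},{_fmt(l)},{_fmt(u)}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return gridded


def read_gridded_interval(path) -> GriddedInterval:
    meta, rows = {}, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line)
    if not rows or rows[0] != "sex,age,lower,upper":
        raise SchemaError("gridded interval file must carry a sex,age,lower,upper header")
    if "alpha" not in meta:
        raise SchemaError("gridded interval file is missing the alpha metadata line")
    alpha = float(meta.pop("alpha"))
    calibrated = meta.pop("calibrated", "false") == "true"
    per_sex: dict = {}
    for i, row in enumerate(rows[1:], start=2):
        parts = row.split(",")
        if len(parts) != 4:
            raise RowParseError(f"line {i}: expected 4 fields", line_number=i)
        sex = parts[0]
        age = _parse_float(parts[1], "age", i)
        lo = _parse_float(parts[2], "lower", i)
        hi = _parse_float(parts[3], "upper", i)
        per_sex.setdefault(sex, []).append((age, lo, hi))
    first_grid = None
    bounds = {}
    for sex, triples in per_sex.items():
        arr = np.asarray(triples, float)
        grid = arr[:, 0]
        if first_grid is None:
            first_grid = grid
        elif grid.shape != first_grid.shape or np.any(grid != first_grid):
            raise SchemaError("all sexes must share one age grid")
        bounds[sex] = (arr[:, 1], arr[:, 2])
    gridded = GriddedInterval(alpha=alpha, age_grid=first_grid, bounds=bounds, metadata=meta)
    gridded.metadata["calibrated"] = "true" if calibrated else "false"
    return gridded


def interpolate_interval(gridded: GriddedInterval, margin: float = 0.0) -> ReferenceInterval:
    """Turn a gridded interval back into evaluable bound functions.

    Bounds are piecewise-linear in age within each sex and exact at grid
    points.  Ages inside the margin band beyond the grid take the boundary
    value; ages beyond the margin raise :class:`ExtrapolationError`.
    """
    grid = gridded.age_grid
    lo_edge, hi_edge = grid[0] - margin, grid[-1] + margin
    calibrated = gridded.metadata.get("calibrated", "false") == "true"

    def _make(which):
        def bound(ages, sexes):
            ages = np.atleast_1d(np.asarray(ages, float))
            sexes = np.atleast_1d(np.asarray(sexes, dtype=object))
            if sexes.shape != ages.shape:
                sexes = np.broadcast_to(sexes, ages.shape)
            if np.any((ages < lo_edge) | (ages > hi_edge)):
                bad = ages[(ages < lo_edge) | (ages > hi_edge)][0]
                raise ExtrapolationError(
                    f"age {bad} outside the gridded range "
                    f"[{grid[0]}, {grid[-1]}] (margin {margin})"
                )
            out = np.empty(ages.shape, float)
            for sex in np.unique(sexes):
                if sex not in gridded.bounds:
                    raise ExtrapolationError(f"sex {sex!r} not present in the grid")
                vals = gridded.bounds[sex][which]
                mask = sexes == sex
                out[mask] = np.interp(ages[mask], grid, vals)
            return out

        return bound

    return ReferenceInterval(
        alpha=gridded.alpha,
        lower=_make(0),
        upper=_make(1),
        calibrated=calibrated,
        provenance=gridded.metadata.get("model", "gridded"),
    )
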