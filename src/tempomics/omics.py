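"""Structured container for mapped omics measurements.

The central data structure is the :class:`OmicsObject`: a two-level ordered
mapping whose outer keys are sample labels (for time-course experiments the
labels encode the sampling times, e.g. days of a study) and whose inner keys
are component identifiers (genes, proteins, metabolites).  Every component
entry carries two parallel lists — numeric measurements and free-form
metadata — so that intensities and annotations travel together through the
whole pipeline.

Missing measurements are represented by the :data:`MISSING` sentinel, which
is distinct from zero and from an absent key.  When per-component time
series are extracted (:func:`create_time_series`) both kinds of absence —
an explicit ``MISSING`` value and a component not measured in a sample —
are canonicalised to ``NaN`` in the resulting float vectors, the single
missing representation the downstream spectral code understands.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "Missing",
    "ComponentEntry",
    "OmicsObject",
    "TimePoint",
    "TimeSeriesSet",
    "ImportSchema",
    "ImportReport",
    "OmicsInputError",
    "build_omics_object",
    "import_delimited",
    "export_omics_object",
    "merge_objects",
    "extract_times",
    "create_time_series",
]


class Missing:
    """Singleton sentinel marking a missing measurement.

    Never conflated with zero: ``MISSING == 0`` is ``False`` and arithmetic
    with it is a type error by design.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "Missing"

    def __reduce__(self):
        return (Missing, ())


MISSING = Missing()


class OmicsInputError(ValueError):
    """Raised for malformed records, schemas, or inconsistent inputs."""


def _is_number(x) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating)) and not isinstance(
        x, bool
    )


@dataclass
class ComponentEntry:
    """Measurements plus metadata for one component in one sample."""

    measurements: list = field(default_factory=list)
    metadata: list = field(default_factory=list)

    def __post_init__(self):
        for v in self.measurements:
            if v is not MISSING and not _is_number(v):
                raise OmicsInputError(
                    f"non-numeric measurement {v!r}; use the MISSING sentinel "
                    "for absent values"
                )


@dataclass
class OmicsObject:
    """Two-level mapping: sample label -> component id -> ComponentEntry."""

    samples: dict = field(default_factory=dict)
    provenance: str = ""

    # -- queries -----------------------------------------------------------
    @property
    def sample_labels(self) -> list:
        return list(self.samples)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def components(self, sample: str) -> list:
        return list(self.samples[sample])

    def all_components(self) -> list:
        """Lexicographically sorted union of component ids over samples."""
        out = set()
        for comps in self.samples.values():
            out.update(comps)
        return sorted(out)

    def channel_count(self, sample: str) -> int:
        comps = self.samples[sample]
        if not comps:
            return 0
        return max(len(e.measurements) for e in comps.values())

    def copy(self) -> "OmicsObject":
        new = {
            s: {
                c: ComponentEntry(list(e.measurements), list(e.metadata))
                for c, e in comps.items()
            }
            for s, comps in self.samples.items()
        }
        return OmicsObject(new, self.provenance)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OmicsObject):
            return NotImplemented
        return self.samples == other.samples


def build_omics_object(records: Iterable[tuple]) -> OmicsObject:
    """Assemble an OmicsObject from ``(sample, component, measurements,
    metadata)`` records.

    Later records for the same (sample, component) pair replace earlier ones
    with a warning.
    """
    obj = OmicsObject()
    for rec in records:
        try:
            sample, comp, meas, meta = rec
        except (TypeError, ValueError) as exc:
            raise OmicsInputError(f"malformed record {rec!r}") from exc
        if not isinstance(sample, str) or not sample:
            raise OmicsInputError(f"invalid sample label in record {rec!r}")
        if not isinstance(comp, str) or not comp:
            raise OmicsInputError(f"invalid component id in record {rec!r}")
        for v in meas:
            if v is not MISSING and not _is_number(v):
                raise OmicsInputError(
                    f"non-numeric measurement {v!r} in record "
                    f"(sample={sample!r}, component={comp!r})"
                )
        comps = obj.samples.setdefault(sample, {})
        if comp in comps:
            warnings.warn(
                f"duplicate record for (sample={sample!r}, component={comp!r});"
                " keeping the later one",
                stacklevel=2,
            )
        comps[comp] = ComponentEntry(list(meas), list(meta))
    return obj


# ---------------------------------------------------------------------------
# Delimited / spreadsheet import and export
# ---------------------------------------------------------------------------


@dataclass
class ImportSchema:
    """Column layout of a delimited/spreadsheet omics table.

    ``sample_from`` is either ``"filename"`` (label = file stem),
    ``"sheet"`` (label = worksheet name, Excel only), or ``"labels"``
    (explicit labels passed to :func:`import_delimited`).
    """

    id_column: str
    measurement_columns: Sequence[str]
    metadata_columns: Sequence[str] = ()
    sample_from: str = "filename"


@dataclass
class ImportReport:
    """Per-sample counts of cells that could not be parsed as numbers."""

    unparseable: dict = field(default_factory=dict)
    empty_samples: list = field(default_factory=list)

    @property
    def total_unparseable(self) -> int:
        return sum(self.unparseable.values())


def _read_table(path: Path) -> list:
    """Returns list of (label_hint, DataFrame). Excel yields one per sheet."""
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls", ".xlsm"}:
        sheets = pd.read_excel(path, sheet_name=None, dtype=str, na_filter=False)
        return [(name, df) for name, df in sheets.items()]
    sep = "," if suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return [(path.stem, df)]


def import_delimited(
    paths: Sequence, schema: ImportSchema, labels: Sequence[str] | None = None
) -> tuple[OmicsObject, ImportReport]:
    """Import CSV/TSV files or Excel workbooks into an OmicsObject.

    One sample per file (or per worksheet for Excel with
    ``sample_from="sheet"``).  Cells in measurement columns that do not
    parse as numbers become :data:`MISSING` and are tallied in the returned
    :class:`ImportReport`.
    """
    obj = OmicsObject()
    report = ImportReport()
    tables: list = []
    for path in paths:
        tables.extend((Path(path), hint, df) for hint, df in _read_table(Path(path)))
    if labels is not None and len(labels) != len(tables):
        raise OmicsInputError(
            f"{len(labels)} labels supplied for {len(tables)} tables"
        )
    for i, (path, hint, df) in enumerate(tables):
        if labels is not None:
            label = labels[i]
        elif schema.sample_from in ("filename", "sheet"):
            label = hint if schema.sample_from == "sheet" else path.stem
        else:
            raise OmicsInputError(
                f"sample_from={schema.sample_from!r} requires explicit labels"
            )
        if schema.id_column not in df.columns:
            raise OmicsInputError(
                f"identifier column {schema.id_column!r} not found in {path} "
                f"(columns: {list(df.columns)})"
            )
        for col in list(schema.measurement_columns) + list(schema.metadata_columns):
            if col not in df.columns:
                raise OmicsInputError(f"column {col!r} not found in {path}")
        comps = obj.samples.setdefault(label, {})
        n_bad = 0
        for _, row in df.iterrows():
            meas = []
            for col in schema.measurement_columns:
                cell = row[col]
                try:
                    v = float(cell)
                    if not np.isfinite(v):
                        raise ValueError(cell)
                    meas.append(v)
                except (TypeError, ValueError):
                    meas.append(MISSING)
                    n_bad += 1
            meta = [
                "" if pd.isna(row[col]) else row[col]
                for col in schema.metadata_columns
            ]
            comps[str(row[schema.id_column])] = ComponentEntry(meas, meta)
        report.unparseable[label] = n_bad
        if not comps:
            report.empty_samples.append(label)
            warnings.warn(f"sample {label!r} imported with zero components")
    obj.provenance = "imported from: " + ", ".join(str(p) for p in paths)
    return obj, report


def export_omics_object(obj: OmicsObject, directory) -> Path:
    """Write one TSV per sample plus a JSON manifest; returns the manifest
    path.  Round-trips through :func:`import_delimited`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "samples": [],
        "provenance": obj.provenance,
    }
    for label, comps in obj.samples.items():
        n_chan = obj.channel_count(label)
        n_meta = max((len(e.metadata) for e in comps.values()), default=0)
        meas_cols = [f"value_{i + 1}" for i in range(n_chan)]
        meta_cols = [f"meta_{i + 1}" for i in range(n_meta)]
        rows = []
        for comp in sorted(comps):
            e = comps[comp]
            row = {"id": comp}
            for i, col in enumerate(meas_cols):
                v = e.measurements[i] if i < len(e.measurements) else MISSING
                row[col] = "NA" if v is MISSING else repr(float(v))
            for i, col in enumerate(meta_cols):
                row[col] = e.metadata[i] if i < len(e.metadata) else ""
            rows.append(row)
        fname = directory / f"{label}.tsv"
        pd.DataFrame(rows, columns=["id"] + meas_cols + meta_cols).to_csv(
            fname, sep="\t", index=False
        )
        manifest["samples"].append(
            {
                "label": label,
                "file": fname.name,
                "measurement_columns": meas_cols,
                "metadata_columns": meta_cols,
            }
        )
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_workspace(manifest_path) -> tuple[OmicsObject, ImportReport]:
    """Load an OmicsObject previously written by :func:`export_omics_object`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    obj = OmicsObject(provenance=manifest.get("provenance", ""))
    report = ImportReport()
    for entry in manifest["samples"]:
        schema = ImportSchema(
            id_column="id",
            measurement_columns=entry["measurement_columns"],
            metadata_columns=entry["metadata_columns"],
        )
        sub, rep = import_delimited(
            [manifest_path.parent / entry["file"]], schema, labels=[entry["label"]]
        )
        obj.samples[entry["label"]] = sub.samples[entry["label"]]
        report.unparseable.update(rep.unparseable)
    return obj, report


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_objects(objects: Sequence[OmicsObject], mode: str = "union") -> OmicsObject:
    """Merge OmicsObjects into one.

    ``union`` keeps every component seen in any sample, padding absent
    (sample, component) pairs with MISSING-valued entries; ``intersection``
    keeps only components present in every sample.  Duplicate sample labels
    are allowed only when their content is identical.
    """
    if mode not in ("union", "intersection"):
        raise OmicsInputError(f"unknown merge mode {mode!r}")
    merged: dict = {}
    conflicts = []
    for obj in objects:
        for label, comps in obj.samples.items():
            if label in merged:
                if merged[label] != comps:
                    conflicts.append(label)
                continue
            merged[label] = {
                c: ComponentEntry(list(e.measurements), list(e.metadata))
                for c, e in comps.items()
            }
    if conflicts:
        raise OmicsInputError(
            "conflicting duplicate sample labels: " + ", ".join(sorted(set(conflicts)))
        )
    out = OmicsObject(merged, provenance="; ".join(o.provenance for o in objects))
    all_comps = set()
    common = None
    for comps in merged.values():
        keys = set(comps)
        all_comps |= keys
        common = keys if common is None else (common & keys)
    common = common or set()
    if mode == "intersection":
        for label in out.samples:
            out.samples[label] = {
                c: out.samples[label][c] for c in sorted(common)
            }
    else:
        for label, comps in out.samples.items():
            n_chan = max((len(e.measurements) for e in comps.values()), default=1)
            for c in sorted(all_comps - set(comps)):
                comps[c] = ComponentEntry([MISSING] * n_chan, [])
            out.samples[label] = {c: comps[c] for c in sorted(comps)}
    return out


# ---------------------------------------------------------------------------
# Time extraction and time-series creation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimePoint:
    """A sample label together with the real-valued time parsed from it."""

    label: str
    time: float


_DEFAULT_TIME_RE = re.compile(r"\d+(?:\.\d+)?")


def parse_time(label: str, pattern=None) -> float:
    """Extract one real number from a sample label.

    Default rule: the first maximal run of digits (optionally with one
    decimal point).  ``pattern`` may be a regex (first group or whole match
    is used) or a callable label -> float.
    """
    if callable(pattern):
        return float(pattern(label))
    rx = _DEFAULT_TIME_RE if pattern is None else re.compile(pattern)
    m = rx.search(label)
    if not m:
        raise OmicsInputError(f"no parseable time in sample label {label!r}")
    text = m.group(1) if m.groups() else m.group(0)
    t = float(text)
    if not np.isfinite(t):
        raise OmicsInputError(f"non-finite time parsed from label {label!r}")
    return t


def extract_times(obj: OmicsObject, pattern=None) -> list:
    """One TimePoint per sample, sorted by time (labels retained)."""
    pts = [TimePoint(label, parse_time(label, pattern)) for label in obj.samples]
    return sorted(pts, key=lambda p: p.time)


@dataclass
class TimeSeriesSet:
    """Per-component value vectors aligned on a shared (possibly uneven)
    time grid.

    ``series`` maps component id -> float vector of length ``len(times)``;
    missing entries are ``NaN``.
    """

    times: list  # list[TimePoint], strictly increasing
    series: dict  # component -> np.ndarray
    channel: int = 0

    @property
    def time_values(self) -> np.ndarray:
        return np.array([p.time for p in self.times], dtype=float)

    @property
    def components(self) -> list:
        return list(self.series)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: v for c, v in self.series.items()},
            index=self.time_values,
        ).T

    def copy(self) -> "TimeSeriesSet":
        return TimeSeriesSet(
            list(self.times), {c: v.copy() for c, v in self.series.items()}, self.channel
        )


def create_time_series(
    obj: OmicsObject, channel: int = 0, pattern=None
) -> TimeSeriesSet:
    """Extract one value vector per component over the sorted time grid.

    A component absent from a sample, or carrying the MISSING sentinel
    there, contributes NaN at that time.  Components are ordered
    lexicographically.
    """
    times = extract_times(obj, pattern)
    if len({p.time for p in times}) != len(times):
        raise OmicsInputError("duplicate times parsed from sample labels")
    for label in obj.samples:
        comps = obj.samples[label]
        for comp, e in comps.items():
            if e.measurements and channel >= len(e.measurements):
                raise OmicsInputError(
                    f"channel {channel} out of range in sample {label!r} "
                    f"(component {comp!r} has {len(e.measurements)} channels)"
                )
    series = {}
    for comp in obj.all_components():
        vec = np.full(len(times), np.nan)
        for i, pt in enumerate(times):
            entry = obj.samples[pt.label].get(comp)
            if entry is None or not entry.measurements:
                continue
            v = entry.measurements[channel]
            if v is not MISSING:
                vec[i] = float(v)
        series[comp] = vec
    return TimeSeriesSet(times, series, channel)
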