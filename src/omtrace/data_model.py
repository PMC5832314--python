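"""Domain types and delimited-text I/O for tracer and oxygen-incubation tables.

Tracer tables hold one row per composite sample (source material or channel
bed sediment) with its fingerprint-property values: stable isotope ratios
(per mil), elemental contents (%), and near-infrared constituent band
intensities (arbitrary units).  Oxygen tables hold headspace O2 mass versus
time for incubation flasks (samples and blanks).

All files are comma-separated UTF-8 with a "." decimal separator and one
header row; tracer names are matched case-sensitively after trimming
whitespace.  Missing tracer cells are disallowed rather than imputed: the
mixing model requires complete tracer vectors.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .robust import qn_scale

logger = logging.getLogger(__name__)

SOURCE = "source"
SEDIMENT = "sediment"

#: the four organic-matter source categories sampled in the study design
DEFAULT_CATEGORIES = (
    "farmyard_manure",
    "road_verge",
    "instream_vegetation",
    "septic_waste",
)

TRACER_KINDS = ("isotope", "elemental", "nir_band")

_RESERVED_COLUMNS = ("sample_id", "role", "category", "subcatchment", "replicate")


class SchemaError(ValueError):
    """A table is missing required columns."""


class ParseError(ValueError):
    """A table cell could not be parsed."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class TracerPanel:
    """The set of fingerprint properties under consideration.

    Parameters
    ----------
    names : sequence of str
        Unique tracer identifiers (e.g. ``"d13C"``, ``"HC=CH"``).
    kinds : mapping, optional
        Tracer name -> one of ``isotope`` (per mil), ``elemental`` (%),
        ``nir_band`` (arbitrary intensity).  Defaults to ``nir_band``.
    valid_ranges : mapping, optional
        Tracer name -> closed physically valid interval; unbounded if absent.
    """

    names: tuple
    kinds: Mapping[str, str] = field(default_factory=dict)
    valid_ranges: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(str(n).strip() for n in self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValidationError("tracer names must be unique")
        for name, kind in self.kinds.items():
            if kind not in TRACER_KINDS:
                raise ValidationError(f"unknown tracer kind {kind!r} for {name!r}")
        for name in list(self.kinds) + list(self.valid_ranges):
            if name not in names:
                raise ValidationError(f"{name!r} is not a tracer in the panel")

    def kind(self, name: str) -> str:
        return self.kinds.get(name, "nir_band")

    def valid_range(self, name: str) -> tuple:
        return self.valid_ranges.get(name, (-math.inf, math.inf))


@dataclass(frozen=True)
class SampleRecord:
    """One composite sample (source material or bed sediment).

    ``role`` is ``"source"`` or ``"sediment"``; source records carry a
    ``category``, sediment records must not.  ``values`` maps tracer name to
    a finite number.  ``replicate_index`` distinguishes analytical repeat
    runs of the same composite sample (1-based).
    """

    sample_id: str
    role: str
    subcatchment: str
    values: Mapping[str, float]
    category: str | None = None
    replicate_index: int = 1

    def __post_init__(self):
        if self.role not in (SOURCE, SEDIMENT):
            raise ValidationError(
                f"sample {self.sample_id!r}: role must be source or sediment"
            )
        if self.role == SOURCE and not self.category:
            raise ValidationError(f"source sample {self.sample_id!r} needs a category")
        if self.role == SEDIMENT and self.category:
            raise ValidationError(
                f"sediment sample {self.sample_id!r} must not carry a category"
            )
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        for name, value in self.values.items():
            if not np.isfinite(value):
                raise ValidationError(
                    f"sample {self.sample_id!r}: tracer {name!r} is not finite"
                )

    def validate_against(self, panel: TracerPanel) -> None:
        missing = [n for n in panel.names if n not in self.values]
        if missing:
            raise ValidationError(
                f"sample {self.sample_id!r}: missing tracer values for {missing}"
            )
        extra = [n for n in self.values if n not in panel.names]
        if extra:
            raise ValidationError(
                f"sample {self.sample_id!r}: tracers not in panel: {extra}"
            )
        for name in panel.names:
            lo, hi = panel.valid_range(name)
            v = self.values[name]
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name!r}={v} outside valid "
                    f"range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class TracerSummary:
    """Per-tracer median, Qn scale, min, max for one group of samples."""

    tracers: tuple
    median: Mapping[str, float]
    qn: Mapping[str, float]
    vmin: Mapping[str, float]
    vmax: Mapping[str, float]
    n_samples: int

    def __post_init__(self):
        for t in self.tracers:
            if not (self.vmin[t] <= self.median[t] <= self.vmax[t]):
                raise ValidationError(f"tracer {t!r}: median outside [min, max]")
            if self.qn[t] < 0:
                raise ValidationError(f"tracer {t!r}: negative Qn scale")


@dataclass(frozen=True)
class SedimentSummary(TracerSummary):
    """Channel-bed sediment group summary; medians are the C_i of the mixing model."""


@dataclass(frozen=True)
class SourceSummary(TracerSummary):
    """Source-category group summary.

    Medians are the S_si of the mixing model; the inverse of ``cv`` is the
    within-source variability weighting SV_si.  ``cv`` is NaN where undefined
    (zero mean, or a single sample); those tracers then receive a neutral
    SV weight of 1.
    """

    category: str = ""
    cv: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OxygenTimeSeries:
    """Headspace O2 mass versus time for one incubation flask.

    Times are days (strictly increasing, >= 0), masses mg O2; blanks carry no
    dry sediment mass.
    """

    flask_id: str
    times: np.ndarray
    o2_mass: np.ndarray
    temperature_c: float
    is_blank: bool = False
    dry_mass_g: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        o2 = np.asarray(self.o2_mass, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "o2_mass", o2)
        if times.size != o2.size:
            raise ValidationError(f"flask {self.flask_id!r}: times/o2_mass length mismatch")
        if times.size and times[0] < 0:
            raise ValidationError(f"flask {self.flask_id!r}: negative time")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"flask {self.flask_id!r}: times must be strictly increasing"
            )
        if np.any(o2 < 0):
            raise ValidationError(f"flask {self.flask_id!r}: negative O2 mass")
        if not self.is_blank:
            if self.dry_mass_g is None or not self.dry_mass_g > 0:
                raise ValidationError(
                    f"flask {self.flask_id!r}: sample flasks need dry_mass_g > 0"
                )


# ---------------------------------------------------------------------------
# tracer table I/O


def read_tracer_table(path, panel: TracerPanel, categories=DEFAULT_CATEGORIES):
    """Read a tracer table CSV into validated SampleRecords.

    Required columns: sample_id, role, category, subcatchment; optional
    ``replicate`` (defaults to 1); one numeric column per panel tracer.
    Replicate rows are retained (use :func:`average_replicates` to collapse).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    required = ["sample_id", "role", "category", "subcatchment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    missing_tracers = [t for t in panel.names if t not in df.columns]
    if missing_tracers:
        raise SchemaError(f"{path}: missing tracer columns {missing_tracers}")

    records = []
    for idx, row in df.iterrows():
        values = {}
        for t in panel.names:
            cell = row[t].strip()
            try:
                values[t] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {idx + 2}, "
                    f"column {t!r}"
                ) from None
        category = row["category"].strip() or None
        role = row["role"].strip()
        if role == SOURCE and categories is not None and category not in categories:
            raise ValidationError(
                f"{path}: unknown source category {category!r} at row {idx + 2}"
            )
        replicate = 1
        if "replicate" in df.columns and row["replicate"].strip():
            try:
                replicate = int(row["replicate"])
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer replicate at row {idx + 2}"
                ) from None
        record = SampleRecord(
            sample_id=row["sample_id"].strip(),
            role=role,
            category=category,
            subcatchment=row["subcatchment"].strip(),
            values=values,
            replicate_index=replicate,
        )
        record.validate_against(panel)
        records.append(record)
    return records


def write_tracer_table(records: Sequence[SampleRecord], path, panel: TracerPanel):
    """Write SampleRecords to a tracer table CSV (lossless for finite floats)."""
    rows = []
    for r in records:
        r.validate_against(panel)
        row = {
            "sample_id": r.sample_id,
            "role": r.role,
            "category": r.category or "",
            "subcatchment": r.subcatchment,
            "replicate": r.replicate_index,
        }
        row.update({t: repr(float(r.values[t])) for t in panel.names})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_RESERVED_COLUMNS) + list(panel.names)).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# oxygen table I/O


def read_oxygen_table(path):
    """Read a long-format oxygen incubation CSV into OxygenTimeSeries.

    Columns: flask_id, time_days, o2_mass_mg, temperature_c, is_blank,
    dry_mass_g (empty for blanks).  Rows are grouped by flask_id.
    """
    df = pd.read_csv(path)
    required = ["flask_id", "time_days", "o2_mass_mg", "temperature_c", "is_blank"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    series = []
    for flask_id, grp in df.groupby("flask_id", sort=True):
        grp = grp.sort_values("time_days")
        is_blank = bool(np.asarray(grp["is_blank"])[0])
        dry = None
        if not is_blank:
            if "dry_mass_g" not in grp.columns:
                raise SchemaError(f"{path}: missing dry_mass_g column")
            dry = float(np.asarray(grp["dry_mass_g"], dtype=float)[0])
        temp = float(np.asarray(grp["temperature_c"], dtype=float)[0])
        series.append(
            OxygenTimeSeries(
                flask_id=str(flask_id),
                times=np.asarray(grp["time_days"], dtype=float),
                o2_mass=np.asarray(grp["o2_mass_mg"], dtype=float),
                temperature_c=temp,
                is_blank=is_blank,
                dry_mass_g=dry,
            )
        )
    return series


def write_oxygen_table(series: Sequence[OxygenTimeSeries], path):
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "flask_id": s.flask_id,
                    "time_days": s.times,
                    "o2_mass_mg": s.o2_mass,
                    "temperature_c": s.temperature_c,
                    "is_blank": s.is_blank,
                    "dry_mass_g": s.dry_mass_g if s.dry_mass_g is not None else "",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grouping operations


def average_replicates(records: Sequence[SampleRecord]):
    """Collapse analytical repeat runs: one record per sample_id, tracer values
    averaged arithmetically across replicates.

    Raises ValidationError if replicates of one sample disagree on role,
    category or subcatchment.
    """
    groups: dict = {}
    order = []
    for r in records:
        if r.sample_id not in groups:
            groups[r.sample_id] = []
            order.append(r.sample_id)
        groups[r.sample_id].append(r)

    out = []
    for sample_id in order:
        grp = groups[sample_id]
        first = grp[0]
        for r in grp[1:]:
            if (r.role, r.category, r.subcatchment) != (
                first.role,
                first.category,
                first.subcatchment,
            ):
                raise ValidationError(
                    f"sample {sample_id!r}: inconsistent role/category/"
                    "subcatchment across replicates"
                )
        tracers = first.values.keys()
        values = {
            t: float(np.mean([r.values[t] for r in grp])) for t in tracers
        }
        out.append(replace(first, values=values, replicate_index=1))
    return out


def summarize_group(records: Sequence[SampleRecord]):
    """Summarise one group of samples per tracer: median, Qn scale, CV
    (sources only), min, max.

    All records must share a role (and category, for sources).  Returns a
    :class:`SourceSummary` or :class:`SedimentSummary`.  With a single sample
    the Qn scale is 0 and the CV undefined; a zero-mean tracer also has an
    undefined CV (flagged as NaN, logged).
    """
    if not records:
        raise ValidationError("cannot summarise an empty group")
    roles = {r.role for r in records}
    if len(roles) != 1:
        raise ValidationError("group mixes source and sediment records")
    role = roles.pop()
    category = None
    if role == SOURCE:
        cats = {r.category for r in records}
        if len(cats) != 1:
            raise ValidationError("source group mixes categories")
        category = cats.pop()

    tracers = tuple(records[0].values.keys())
    median, qn, vmin, vmax, cv = {}, {}, {}, {}, {}
    n = len(records)
    for t in tracers:
        # sorted so the summary is exactly invariant to record order
        x = np.sort(np.array([r.values[t] for r in records], dtype=float))
        median[t] = float(np.median(x))
        vmin[t] = float(x.min())
        vmax[t] = float(x.max())
        if n >= 2:
            qn[t] = qn_scale(x)
            mean = float(x.mean())
            if mean == 0.0:
                logger.warning("tracer %r: zero mean, CV undefined", t)
                cv[t] = float("nan")
            else:
                cv[t] = float(x.std(ddof=1) / abs(mean))
        else:
            qn[t] = 0.0
            cv[t] = float("nan")

    if role == SEDIMENT:
        return SedimentSummary(
            tracers=tracers, median=median, qn=qn, vmin=vmin, vmax=vmax, n_samples=n
        )
    return SourceSummary(
        tracers=tracers,
        median=median,
        qn=qn,
        vmin=vmin,
        vmax=vmax,
        n_samples=n,
        category=category,
        cv=cv,
    )
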