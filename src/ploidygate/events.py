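"""Event and sample data model, CSV I/O, and the packaged sample table.

A cytometry *event* is one object passing the detector: DNA (PI)
fluorescence, projected cell area, a gradient-RMS-like focus metric, and —
when the instrument images each event — optional morphology counts (nuclei,
pyrenoids, accumulation bodies, outer lobes). Optional counts use pandas'
nullable integer dtype so that "not imaged" stays distinct from an observed
count of zero.

The packaged fixture (``data/table1.csv``) transcribes the per-sample DNA
content percentages of the 20 coral-symbiont samples of the source study:
10 analysed by imaging flow cytometry (IFC) and 10 by sorting flow
cytometry, from three Pocillopora colonies under control and heat
treatments. Note two quirks transcribed as printed: the published table
heads its last column "(< 2C-4C)" although the surrounding text calls the
region "(> 2C-4C)", and sample 6's percentages sum to 98.4 rather than
~100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Canonical per-event columns, in storage order. The focus metric is kept
#: nullable so tables from instruments without one still load; the focus
#: filter itself then refuses to run on them.
MANDATORY_FIELDS = ("dna_fluorescence", "cell_area")
OPTIONAL_REAL_FIELDS = ("focus_metric", "nuclear_aspect_ratio")
OPTIONAL_COUNT_FIELDS = (
    "nuclei_count",
    "pyrenoid_count",
    "accumulation_body_count",
    "lobe_count",
)
ALL_FIELDS = ("event_id",) + MANDATORY_FIELDS + OPTIONAL_REAL_FIELDS + OPTIONAL_COUNT_FIELDS


@dataclass(frozen=True)
class CellEvent:
    """One cytometer event. Optional fields are ``None`` when not measured."""

    event_id: str
    dna_fluorescence: float
    cell_area: float
    focus_metric: float | None = None
    nuclear_aspect_ratio: float | None = None
    nuclei_count: int | None = None
    pyrenoid_count: int | None = None
    accumulation_body_count: int | None = None
    lobe_count: int | None = None


class EventSet:
    """Ordered collection of events backed by a :class:`pandas.DataFrame`.

    The table always carries every canonical column; unmeasured optional
    fields hold missing markers (``NaN`` / ``pd.NA``), never zero.
    """

    def __init__(self, table: pd.DataFrame, channel_metadata: Mapping | None = None):
        self.table = _canonicalize(table)
        self.channel_metadata = dict(channel_metadata or {})
        _validate_events(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[CellEvent]:
        for row in self.table.itertuples(index=False):
            yield CellEvent(
                event_id=str(row.event_id),
                dna_fluorescence=float(row.dna_fluorescence),
                cell_area=float(row.cell_area),
                **{
                    f: (None if pd.isna(getattr(row, f)) else float(getattr(row, f)))
                    for f in OPTIONAL_REAL_FIELDS
                },
                **{
                    f: (None if pd.isna(getattr(row, f)) else int(getattr(row, f)))
                    for f in OPTIONAL_COUNT_FIELDS
                },
            )

    def copy(self) -> "EventSet":
        out = EventSet.__new__(EventSet)
        out.table = self.table.copy()
        out.channel_metadata = dict(self.channel_metadata)
        return out

    def subset(self, mask) -> "EventSet":
        """Row-subset by boolean mask, preserving order and metadata."""
        out = EventSet.__new__(EventSet)
        out.table = self.table.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        out.channel_metadata = dict(self.channel_metadata)
        return out

    def equals(self, other: "EventSet") -> bool:
        return self.table.equals(other.table)


def _canonicalize(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "event_id" not in df.columns:
        df["event_id"] = [str(i) for i in range(len(df))]
    df["event_id"] = df["event_id"].astype(str)
    for col in MANDATORY_FIELDS + OPTIONAL_REAL_FIELDS:
        if col not in df.columns:
            if col in MANDATORY_FIELDS:
                raise FormatError(f"missing mandatory column: {col!r}")
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in OPTIONAL_COUNT_FIELDS:
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = pd.array(df[col], dtype="Int64")
    extra = [c for c in df.columns if c not in ALL_FIELDS]
    return df[list(ALL_FIELDS) + extra].reset_index(drop=True)


def _validate_events(df: pd.DataFrame) -> None:
    bad = df.index[
        (df["dna_fluorescence"] <= 0)
        | df["dna_fluorescence"].isna()
        | (df["cell_area"] <= 0)
        | df["cell_area"].isna()
    ].tolist()
    if bad:
        raise ValidationError(
            f"non-positive or missing dna_fluorescence/cell_area at rows {bad}"
        )
    if (df["focus_metric"] < 0).any():
        rows = df.index[df["focus_metric"] < 0].tolist()
        raise ValidationError(f"negative focus_metric at rows {rows}")
    for col in OPTIONAL_COUNT_FIELDS:
        neg = df[col].dropna() < 0
        if neg.any():
            raise ValidationError(f"negative {col} values present")


def read_event_table(
    source,
    column_map: Mapping[str, str] | None = None,
    channel_metadata: Mapping | None = None,
) -> EventSet:
    """Read a one-row-per-event CSV table into an :class:`EventSet`.

    ``column_map`` maps canonical field names to the file's column headers,
    e.g. ``{"dna_fluorescence": "pi", "cell_area": "area"}``. Exports from
    instrument software carry unstable headers, so no header guessing is
    attempted: unmapped optional fields are simply marked absent. With no
    map the file must already use canonical headers.
    """
    raw = pd.read_csv(source, float_precision="round_trip")
    if column_map:
        unknown = [f for f in column_map if f not in ALL_FIELDS]
        if unknown:
            raise FormatError(f"unknown CellEvent fields in column map: {unknown}")
        missing = [c for f, c in column_map.items() if c not in raw.columns]
        if missing:
            raise FormatError(f"mapped columns absent from file: {missing}")
        raw = raw[[c for c in column_map.values()]].rename(
            columns={c: f for f, c in column_map.items()}
        )
    return EventSet(raw, channel_metadata)


def write_event_table(events: EventSet, path) -> None:
    """Write the canonical event table as CSV.

    Reals use the shortest representation that parses back to the same
    float, so write -> read -> write is byte-stable and lossless.
    """
    events.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sample-level fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One analysed sample: identity, treatment, timing and DNA-content %."""

    sample_id: str
    colony_id: str
    treatment: str  # "control" | "heat"
    hours_after_t0: int
    time_of_day: str  # HH:MM
    analysis_type: str  # "IFC" | "sorting"
    pct_c1_plus_s: float
    pct_c2: float
    pct_hyper: float

    def __post_init__(self):
        for name in ("pct_c1_plus_s", "pct_c2", "pct_hyper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v} outside [0, 100]")


def load_table1_fixture() -> list[SampleRecord]:
    """The packaged 20-sample DNA-content table (10 IFC + 10 sorting)."""
    df = table1_dataframe()
    return [
        SampleRecord(
            sample_id=str(r.sample_id),
            colony_id=r.colony_id,
            treatment=r.treatment,
            hours_after_t0=int(r.hours_after_t0),
            time_of_day=r.time_of_day,
            analysis_type=r.analysis_type,
            pct_c1_plus_s=float(r.pct_c1_plus_s),
            pct_c2=float(r.pct_c2),
            pct_hyper=float(r.pct_hyper),
        )
        for r in df.itertuples(index=False)
    ]


def table1_dataframe() -> pd.DataFrame:
    """The sample table as a DataFrame (column per :class:`SampleRecord` field)."""
    with resources.files("ploidygate.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, dtype={"time_of_day": str})
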