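"""Spike-time and session-metadata tables, and conversion to binned spike trains.

Spike data are exchanged as plain delimited text (comma or tab, auto-detected,
UTF-8, header row).  Three tables describe a study:

* spikes:   ``session_id,unit_id,region,spike_time``  (region CA3 or CA1,
  spike_time in seconds)
* metadata: ``session_id,animal_id,condition,performance``  (condition
  control or THC, performance in percent correct)
* events:   ``session_id,event_time``  (sample-phase event times, seconds)

Spike times are mapped into binary series on a half-open 4 ms grid: bin ``i``
covers ``[t_start + i*bin_width, t_start + (i+1)*bin_width)``.  A bin holding
two or more spikes is clipped to 1; clipping and out-of-window drops are
counted on the returned train so no spike is lost silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError, ParameterError

REGIONS = ("CA3", "CA1")
CONDITIONS = ("control", "THC")

SPIKE_COLUMNS = ["session_id", "unit_id", "region", "spike_time"]
META_COLUMNS = ["session_id", "animal_id", "condition", "performance"]
EVENT_COLUMNS = ["session_id", "event_time"]


@dataclass
class SpikeTrain:
    """Binary binned spike series for one unit.

    ``values`` holds one 0/1 entry per 4 ms (default) bin; ``n_clipped`` and
    ``n_dropped`` audit spikes lost to binarisation or to the time window.
    """

    unit_id: str
    region: str
    bin_width: float
    t_start: float
    values: np.ndarray
    session_id: str | None = None
    n_clipped: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValidationError("spike train values must be 0/1")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def spike_times(self) -> np.ndarray:
        """Bin-centre times of the spikes (seconds)."""
        idx = np.flatnonzero(self.values)
        return self.t_start + (idx + 0.5) * self.bin_width


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"session_id": str, "unit_id": str,
                                             "animal_id": str})


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column '{col}'")


def load_spike_table(
    path: str | Path,
    meta_path: str | Path,
    events_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Load and validate the spike, metadata and (optional) event tables.

    Returns ``(spikes, meta, events)`` with spike times sorted ascending within
    each (session, unit) and exact duplicate (unit, time) rows dropped.
    """
    spikes = _read_delimited(path)
    meta = _read_delimited(meta_path)
    _require_columns(spikes, SPIKE_COLUMNS, "spike")
    _require_columns(meta, META_COLUMNS, "metadata")

    bad_regions = set(spikes["region"].unique()) - set(REGIONS)
    if bad_regions:
        raise ValidationError(f"unknown region token(s): {sorted(bad_regions)}")
    bad_cond = set(meta["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown condition token(s): {sorted(bad_cond)}")
    if (spikes["spike_time"] < 0).any():
        raise ValidationError("negative spike times present")
    perf = meta["performance"].to_numpy(dtype=float)
    if ((perf < 0) | (perf > 100)).any():
        raise ValidationError("performance must lie in [0, 100]")
    if meta["session_id"].duplicated().any():
        dups = meta.loc[meta["session_id"].duplicated(), "session_id"].tolist()
        raise ValidationError(f"duplicate metadata rows for session(s) {dups}")

    missing = set(spikes["session_id"].unique()) - set(meta["session_id"])
    if missing:
        raise ReferentialError(
            f"sessions present in spikes but absent from metadata: {sorted(missing)}")

    spikes = (spikes
              .drop_duplicates(subset=["session_id", "unit_id", "spike_time"])
              .sort_values(["session_id", "unit_id", "spike_time"],
                           kind="mergesort")
              .reset_index(drop=True))
    meta = meta.sort_values("session_id", kind="mergesort").reset_index(drop=True)

    events = None
    if events_path is not None:
        events = _read_delimited(events_path)
        _require_columns(events, EVENT_COLUMNS, "event")
        missing = set(events["session_id"].unique()) - set(meta["session_id"])
        if missing:
            raise ReferentialError(
                f"sessions present in events but absent from metadata: {sorted(missing)}")
        events = events.sort_values(["session_id", "event_time"],
                                    kind="mergesort").reset_index(drop=True)
    return spikes, meta, events


def write_spike_table(
    spikes: pd.DataFrame,
    meta: pd.DataFrame,
    out_dir: str | Path,
    events: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the study tables as CSV (times at 6 decimals). Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"spikes": out_dir / "spikes.csv", "meta": out_dir / "sessions.csv"}
    spikes.to_csv(paths["spikes"], index=False, float_format="%.6f")
    meta.to_csv(paths["meta"], index=False, float_format="%.6f")
    if events is not None:
        paths["events"] = out_dir / "events.csv"
        events.to_csv(paths["events"], index=False, float_format="%.6f")
    return paths


def bin_spikes(
    times: Sequence[float],
    bin_width: float,
    t_start: float,
    t_end: float,
    unit_id: str = "",
    region: str = "CA1",
    session_id: str | None = None,
) -> SpikeTrain:
    """Bin sorted spike times into a binary train over ``[t_start, t_end)``.

    Conservation holds exactly: placed + clipped + dropped = len(times).
    """
    times = np.asarray(times, dtype=float)
    if t_end <= t_start:
        raise ParameterError("t_end must exceed t_start")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if times.size and (np.diff(times) < 0).any():
        raise ParameterError("spike times must be sorted ascending")

    n_bins = int(round((t_end - t_start) / bin_width))
    inside = (times >= t_start) & (times < t_end)
    n_dropped = int(times.size - inside.sum())
    idx = np.floor((times[inside] - t_start) / bin_width).astype(int)
    idx = idx[idx < n_bins]  # guard against float edge at t_end
    counts = np.bincount(idx, minlength=n_bins)
    n_clipped = int((counts - 1).clip(min=0).sum())
    if n_clipped:
        warnings.warn(f"bin_spikes: clipped {n_clipped} spike(s) sharing a bin "
                      f"(unit {unit_id!r})", stacklevel=2)
    values = (counts > 0).astype(np.int8)
    return SpikeTrain(unit_id=unit_id, region=region, bin_width=bin_width,
                      t_start=t_start, values=values, session_id=session_id,
                      n_clipped=n_clipped, n_dropped=n_dropped)


def extract_peri_event(
    train: SpikeTrain,
    events: Sequence[float],
    pre: float,
    post: float,
) -> tuple[list[SpikeTrain], int]:
    """Cut peri-event segments ``[event - pre, event + post)`` from a train.

    Events whose window leaves the train extent are skipped and counted.
    Returns ``(segments, n_skipped)``; segments are concatenable for fitting.
    """
    if pre < 0 or post < 0:
        raise ParameterError("pre and post must be non-negative")
    bw = train.bin_width
    seg_len = int(round((pre + post) / bw))
    segments: list[SpikeTrain] = []
    n_skipped = 0
    for ev in events:
        start_bin = int(round((ev - pre - train.t_start) / bw))
        if start_bin < 0 or start_bin + seg_len > train.n_bins:
            n_skipped += 1
            continue
        seg = SpikeTrain(unit_id=train.unit_id, region=train.region,
                         bin_width=bw,
                         t_start=train.t_start + start_bin * bw,
                         values=train.values[start_bin:start_bin + seg_len],
                         session_id=train.session_id)
        segments.append(seg)
    return segments, n_skipped


@dataclass
class Session:
    """Binned trains and metadata for one recording session."""

    session_id: str
    animal_id: str
    condition: str
    performance: float
    ca3: list[SpikeTrain] = field(default_factory=list)
    ca1: list[SpikeTrain] = field(default_factory=list)
    events: np.ndarray = field(default_factory=lambda: np.empty(0))


def sessions_from_tables(
    spikes: pd.DataFrame,
    meta: pd.DataFrame,
    events: pd.DataFrame | None = None,
    bin_width: float = 0.004,
    duration: float | None = None,
) -> dict[str, Session]:
    """Bin every unit of every session into :class:`Session` containers.

    ``duration`` fixes the common window ``[0, duration)``; when omitted it is
    taken per session as the latest spike time rounded up to a whole bin.
    """
    out: dict[str, Session] = {}
    ev_by_session: dict[str, np.ndarray] = {}
    if events is not None:
        for sid, grp in events.groupby("session_id"):
            ev_by_session[str(sid)] = grp["event_time"].to_numpy(dtype=float)
    for _, row in meta.iterrows():
        sid = str(row["session_id"])
        sess_spikes = spikes[spikes["session_id"] == sid]
        if duration is None:
            t_end = 0.0 if sess_spikes.empty else float(sess_spikes["spike_time"].max())
            t_end = (np.floor(t_end / bin_width) + 1) * bin_width
        else:
            t_end = duration
        sess = Session(session_id=sid, animal_id=str(row["animal_id"]),
                       condition=str(row["condition"]),
                       performance=float(row["performance"]),
                       events=ev_by_session.get(sid, np.empty(0)))
        for (uid, region), grp in sess_spikes.groupby(["unit_id", "region"]):
            train = bin_spikes(grp["spike_time"].to_numpy(dtype=float), bin_width,
                               0.0, t_end, unit_id=str(uid), region=str(region),
                               session_id=sid)
            (sess.ca3 if region == "CA3" else sess.ca1).append(train)
        sess.ca3.sort(key=lambda t: t.unit_id)
        sess.ca1.sort(key=lambda t: t.unit_id)
        out[sid] = sess
    return out
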