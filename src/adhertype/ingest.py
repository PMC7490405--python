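"""EMD event-log ingestion: from raw actuation rows to per-patient dose grids.

A *dose* is one or more actuations within a 12-hour half-day window
(midnight-midday = AM, midday-midnight = PM), so each patient has at most
two doses per calendar day. Days inside declared device-malfunction periods
are masked as unobserved and excluded from every denominator downstream;
actuations recorded inside a malfunction block are treated as spurious and
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EventParseError, UndefinedProfileError

logger = logging.getLogger(__name__)

__all__ = [
    "ActuationEvent",
    "MalfunctionPeriod",
    "DoseGrid",
    "parse_event_log",
    "parse_malfunction_table",
    "assign_dose_window",
    "build_dose_grid",
    "write_grids",
    "read_grids",
]

REQUIRED_EVENT_COLUMNS = ("patient_id", "timestamp", "n_actuations")


@dataclass(frozen=True)
class ActuationEvent:
    patient_id: str
    timestamp: pd.Timestamp
    n_actuations: int = 1


@dataclass(frozen=True)
class MalfunctionPeriod:
    """Inclusive date range during which the device log is unusable."""

    patient_id: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"{self.patient_id}: malfunction start after end")


@dataclass
class DoseGrid:
    """Per-patient day x {AM, PM} dose flags with an observed mask.

    ``observed`` is False inside malfunction periods; dose flags are always
    False on unobserved days. ``n_observed_days`` is the "days with device"
    denominator used by all five adherence measures.
    """

    patient_id: str
    start_date: pd.Timestamp
    am_taken: np.ndarray
    pm_taken: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.am_taken = np.asarray(self.am_taken, dtype=bool)
        self.pm_taken = np.asarray(self.pm_taken, dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.am_taken) == len(self.pm_taken) == len(self.observed)):
            raise ValueError("am/pm/observed arrays must share a length")
        # masking contract: no dose flags on unobserved days
        self.am_taken = self.am_taken & self.observed
        self.pm_taken = self.pm_taken & self.observed

    @property
    def n_days(self) -> int:
        return len(self.observed)

    @property
    def n_observed_days(self) -> int:
        return int(self.observed.sum())

    @property
    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def doses_per_day(self) -> np.ndarray:
        return self.am_taken.astype(int) + self.pm_taken.astype(int)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return (self.patient_id == other.patient_id
                and self.start_date == other.start_date
                and np.array_equal(self.am_taken, other.am_taken)
                and np.array_equal(self.pm_taken, other.pm_taken)
                and np.array_equal(self.observed, other.observed))


def parse_event_log(source) -> list[ActuationEvent]:
    """Parse a delimited event log into sorted actuation events.

    ``source`` is a path or file-like object for a CSV with header columns
    ``patient_id, timestamp, n_actuations``. Rows that fail to parse raise
    :class:`EventParseError` carrying their 1-based line numbers.
    """
    try:
        raw = pd.read_csv(source, dtype=str)
    except pd.errors.EmptyDataError:
        raise EventParseError("event log has no header")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise EventParseError(f"event log missing required columns: {missing}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    n_act = pd.to_numeric(raw["n_actuations"], errors="coerce")
    bad = ts.isna() | n_act.isna() | (n_act < 1) | raw["patient_id"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]  # +2: header + 1-based
        raise EventParseError(
            f"{len(lines)} unparseable event rows (lines {lines[:10]}"
            f"{'...' if len(lines) > 10 else ''})", lines=lines)

    events = [ActuationEvent(p, t, int(n))
              for p, t, n in zip(raw["patient_id"], ts, n_act)]
    events.sort(key=lambda e: (e.patient_id, e.timestamp))
    return events


def parse_malfunction_table(source) -> list[MalfunctionPeriod]:
    raw = pd.read_csv(source, dtype=str)
    missing = [c for c in ("patient_id", "start_date", "end_date")
               if c not in raw.columns]
    if missing:
        raise EventParseError(f"malfunction table missing columns: {missing}")
    return [MalfunctionPeriod(r.patient_id,
                              pd.Timestamp(r.start_date),
                              pd.Timestamp(r.end_date))
            for r in raw.itertuples()]


def assign_dose_window(timestamp: pd.Timestamp) -> str:
    """AM iff the clock time lies in [00:00, 12:00); 12:00 itself is PM."""
    return "AM" if pd.Timestamp(timestamp).hour < 12 else "PM"


def build_dose_grid(
    events,
    malfunction_periods,
    followup_windows: dict[str, tuple[pd.Timestamp, pd.Timestamp]],
) -> dict[str, DoseGrid]:
    """Aggregate actuation events into one DoseGrid per patient.

    A window flag is set iff at least one actuation falls in that day-window;
    repeated actuations collapse to one dose. Events outside a patient's
    follow-up window, or inside a malfunction block, are discarded with a
    warning. Patients whose every day is masked are excluded with a warning.

    ``followup_windows`` comes from cohort metadata (inclusive start/end
    dates per patient) rather than being inferred from the events, so that
    dose-free tails count as non-adherence.
    """
    if isinstance(events, pd.DataFrame):
        events = [ActuationEvent(r.patient_id, pd.Timestamp(r.timestamp),
                                 int(getattr(r, "n_actuations", 1)))
                  for r in events.itertuples()]
    if isinstance(malfunction_periods, pd.DataFrame):
        malfunction_periods = [
            MalfunctionPeriod(r.patient_id, pd.Timestamp(r.start_date),
                              pd.Timestamp(r.end_date))
            for r in malfunction_periods.itertuples()]

    grids: dict[str, DoseGrid] = {}
    for pid, (start, end) in followup_windows.items():
        start, end = pd.Timestamp(start).normalize(), pd.Timestamp(end).normalize()
        n_days = (end - start).days + 1
        grids[pid] = DoseGrid(pid, start,
                              np.zeros(n_days, bool),
                              np.zeros(n_days, bool),
                              np.ones(n_days, bool))

    for period in malfunction_periods:
        grid = grids.get(period.patient_id)
        if grid is None:
            logger.warning("malfunction period for unknown patient %s ignored",
                           period.patient_id)
            continue
        i0 = (period.start_date.normalize() - grid.start_date).days
        i1 = (period.end_date.normalize() - grid.start_date).days
        i0, i1 = max(i0, 0), min(i1, grid.n_days - 1)
        if i1 >= i0:
            grid.observed[i0:i1 + 1] = False

    n_outside = n_masked = 0
    for ev in events:
        grid = grids.get(ev.patient_id)
        day = (ev.timestamp.normalize() - grid.start_date).days if grid else -1
        if grid is None or not 0 <= day < grid.n_days:
            n_outside += 1
            continue
        if not grid.observed[day]:
            n_masked += 1  # malfunction masking wins over recorded events
            continue
        if assign_dose_window(ev.timestamp) == "AM":
            grid.am_taken[day] = True
        else:
            grid.pm_taken[day] = True
    if n_outside:
        logger.warning("%d events outside follow-up windows discarded", n_outside)
    if n_masked:
        logger.warning("%d events inside malfunction periods discarded", n_masked)

    empty = [pid for pid, g in grids.items() if g.n_observed_days == 0]
    for pid in empty:
        logger.warning("patient %s has zero observed days; excluded", pid)
        del grids[pid]
    return grids


def write_grids(grids: dict[str, DoseGrid], path) -> None:
    """Serialize grids as long-format CSV (patient_id, date, am, pm, observed)."""
    frames = []
    for pid in sorted(grids):
        g = grids[pid]
        frames.append(pd.DataFrame({
            "patient_id": pid,
            "date": g.days.strftime("%Y-%m-%d"),
            "am_taken": g.am_taken.astype(int),
            "pm_taken": g.pm_taken.astype(int),
            "observed": g.observed.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grids(path) -> dict[str, DoseGrid]:
    long = pd.read_csv(path, dtype={"patient_id": str})
    grids = {}
    for pid, sub in long.groupby("patient_id", sort=True):
        sub = sub.sort_values("date")
        grids[pid] = DoseGrid(pid, pd.Timestamp(sub["date"].iloc[0]),
                              sub["am_taken"].to_numpy(dtype=bool),
                              sub["pm_taken"].to_numpy(dtype=bool),
                              sub["observed"].to_numpy(dtype=bool))
    return grids
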