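"""Person-level adherence measures and treatment-intermission detection.

Five measures summarise each patient's dosing record over the observed
follow-up (n = days with device; d0/d1/d2 = days with 0/1/2 doses):

    A  % of prescribed doses taken            = 100*(d1 + 2*d2) / (2n)
    B  % of days with zero doses              = 100*d0 / n
    C  % of days with both doses              = 100*d2 / n
    D  treatment intermissions per 100 days   = 100*(# intermissions) / n
    E  intermission days per 100 days         = 100*(total intermission days) / n

A and C capture *implementation* (dose-taking within a day); D and E capture
*persistence*, where a treatment intermission is a run of at least five
consecutive zero-dose days. Runs are computed within contiguous observed
segments: a malfunction-masked day terminates a run without counting toward
it, so missing data never fabricates missed doses. A run still open at the
end of follow-up is censored; censored intermissions count toward D and E
with their truncated duration by default.

The identity A = (100 - B + C) / 2 holds exactly for every grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedProfileError
from .ingest import DoseGrid

__all__ = [
    "MEASURE_NAMES",
    "Intermission",
    "AdherenceProfile",
    "detect_intermissions",
    "compute_profile",
    "cohort_measure_matrix",
]

MEASURE_NAMES = ("A", "B", "C", "D", "E")
MIN_INTERMISSION_DAYS = 5


@dataclass(frozen=True)
class Intermission:
    """A run of >= 5 consecutive zero-dose observed days.

    ``start_day`` is the 0-based day index into the patient's follow-up
    calendar; ``censored`` flags a run still open at the end of follow-up.
    """

    start_day: int
    duration: int
    censored: bool = False

    def __post_init__(self) -> None:
        if self.duration < MIN_INTERMISSION_DAYS:
            raise ValueError("intermission duration below the 5-day minimum")


@dataclass(frozen=True)
class AdherenceProfile:
    patient_id: str
    A: float
    B: float
    C: float
    D: float
    E: float
    doses_taken: int
    d0: int
    d1: int
    d2: int
    n_observed_days: int
    n_intermissions: int
    total_intermission_days: int
    first_intermission_start: int | None = None   # days after baseline
    first_intermission_duration: int | None = None

    def as_row(self) -> dict:
        return {"patient_id": self.patient_id,
                **{m: getattr(self, m) for m in MEASURE_NAMES},
                "doses_taken": self.doses_taken, "d0": self.d0, "d1": self.d1,
                "d2": self.d2, "n_observed_days": self.n_observed_days,
                "n_intermissions": self.n_intermissions,
                "total_intermission_days": self.total_intermission_days}


def _observed_segments(observed: np.ndarray):
    """Yield (start, stop) index pairs of maximal contiguous observed runs."""
    idx = np.flatnonzero(observed)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, stops):
        yield int(idx[s]), int(idx[e]) + 1


def detect_intermissions(grid: DoseGrid,
                         min_days: int = MIN_INTERMISSION_DAYS) -> list[Intermission]:
    """Find maximal runs of >= ``min_days`` consecutive zero-dose days.

    Runs are confined to contiguous observed segments. A run that reaches
    the final day of the follow-up calendar is returned with
    ``censored=True`` (the patient may still have been off treatment).
    """
    if grid.n_observed_days < 1:
        raise UndefinedProfileError(f"{grid.patient_id}: no observed days")
    zero = grid.doses_per_day() == 0
    out: list[Intermission] = []
    for seg_start, seg_stop in _observed_segments(grid.observed):
        run_start = None
        for day in range(seg_start, seg_stop + 1):
            if day < seg_stop and zero[day]:
                if run_start is None:
                    run_start = day
            else:
                if run_start is not None:
                    length = day - run_start
                    if length >= min_days:
                        censored = (day == seg_stop == grid.n_days)
                        out.append(Intermission(run_start, length, censored))
                    run_start = None
    return out


def compute_profile(grid: DoseGrid, *, include_censored: bool = True,
                    min_intermission_days: int = MIN_INTERMISSION_DAYS
                    ) -> AdherenceProfile:
    """Compute the five adherence measures for one patient.

    ``include_censored=False`` drops end-of-follow-up censored intermissions
    from the persistence measures D and E.
    """
    n = grid.n_observed_days
    if n < 1:
        raise UndefinedProfileError(f"{grid.patient_id}: no observed days")
    doses = grid.doses_per_day()[grid.observed]
    d0 = int((doses == 0).sum())
    d1 = int((doses == 1).sum())
    d2 = int((doses == 2).sum())
    doses_taken = d1 + 2 * d2

    intermissions = detect_intermissions(grid, min_intermission_days)
    if not include_censored:
        intermissions = [iv for iv in intermissions if not iv.censored]
    n_int = len(intermissions)
    int_days = sum(iv.duration for iv in intermissions)
    first = min(intermissions, key=lambda iv: iv.start_day) if intermissions else None

    return AdherenceProfile(
        patient_id=grid.patient_id,
        A=100.0 * doses_taken / (2 * n),
        B=100.0 * d0 / n,
        C=100.0 * d2 / n,
        D=100.0 * n_int / n,
        E=100.0 * int_days / n,
        doses_taken=doses_taken, d0=d0, d1=d1, d2=d2, n_observed_days=n,
        n_intermissions=n_int, total_intermission_days=int_days,
        first_intermission_start=first.start_day if first else None,
        first_intermission_duration=first.duration if first else None,
    )


def cohort_measure_matrix(profiles) -> pd.DataFrame:
    """Assemble profiles into the patients x 5 measure matrix (PCA input).

    Rows are ordered by patient_id; columns A..E. Duplicate patient ids are
    an error.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("at least two profiles required")
    ids = [p.patient_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    frame = pd.DataFrame(
        [[getattr(p, m) for m in MEASURE_NAMES] for p in profiles],
        index=pd.Index(ids, name="patient_id"), columns=list(MEASURE_NAMES))
    return frame.sort_index()
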