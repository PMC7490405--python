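"""Seeded synthetic EMD cohorts.

The original trial data behind this pipeline are not publicly deposited, so
the generator produces actuation logs with the statistical structure the
analysis assumes: twice-daily dosing with clock times concentrated in a
morning (07:00-10:00) and an evening (19:00-22:00) window, behavioural
archetypes with distinct dose-taking probabilities, treatment intermissions
(>=5-day gaps started by a per-day hazard), and battery-failure missing
blocks recorded in a device malfunction table.

Every draw flows from ``CohortConfig.seed``; the same config yields
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .errors import ConfigurationError

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "CohortData",
    "DEFAULT_ARCHETYPES",
    "generate_cohort",
    "inject_missingness",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """A behavioural archetype: per-window dose probabilities plus an
    intermission process.

    ``intermission_start_prob`` is a per-day hazard of beginning an
    intermission; during an intermission all dose probabilities are zero.
    Durations are ``5 + Geometric`` with mean extra days
    ``intermission_mean_extra_days``, so every generated intermission lasts
    at least the 5 days that the persistence definition requires.
    """

    name: str
    am_dose_prob: float
    pm_dose_prob: float
    intermission_start_prob: float = 0.0
    intermission_mean_extra_days: float = 3.0
    extra_actuation_prob: float = 0.15

    def __post_init__(self) -> None:
        for attr in ("am_dose_prob", "pm_dose_prob", "intermission_start_prob",
                     "extra_actuation_prob"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.intermission_mean_extra_days < 0:
            raise ConfigurationError(
                f"{self.name}: intermission_mean_extra_days must be >= 0")


#: Default archetypes bracketing poor / moderate / good adherence.
#: Dose probabilities and intermission hazards are set so the archetype
#: medians of measure A sit near 16%, 55% and 91%.
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("poor", 0.25, 0.25,
                  intermission_start_prob=0.054,
                  intermission_mean_extra_days=5.0,
                  extra_actuation_prob=0.20),
    ArchetypeSpec("moderate", 0.62, 0.62,
                  intermission_start_prob=0.012,
                  intermission_mean_extra_days=3.0,
                  extra_actuation_prob=0.15),
    ArchetypeSpec("good", 0.92, 0.92,
                  intermission_start_prob=0.0008,
                  intermission_mean_extra_days=2.0,
                  extra_actuation_prob=0.10),
)

#: Archetype mixture weights per arm for the optional two-arm design:
#: the control arm is dominated by poor/moderate adherence (mean A ~36%),
#: the intervention arm by good adherence (mean A ~80%).
DEFAULT_ARM_WEIGHTS: dict[str, tuple[float, ...]] = {
    "control": (0.55, 0.35, 0.10),
    "intervention": (0.05, 0.25, 0.70),
}


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    Defaults mirror the study design the pipeline targets: 211 patients,
    155-210 days of follow-up, 26% of patients with one battery-failure
    block whose length has median 22 days (clipped to 2-122), and actuation
    clock times concentrated 07:00-10:00 (96%) and 19:00-22:00 (93%).
    """

    n_patients: int = 211
    followup_days: tuple[int, int] = (155, 210)
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    archetype_weights: tuple[float, ...] = (0.30, 0.40, 0.30)
    two_arm: bool = False
    arm_weights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARM_WEIGHTS))
    missing_block_prob: float = 0.26
    missing_block_median: float = 22.0
    missing_block_sigma: float = 0.8
    missing_block_range: tuple[int, int] = (2, 122)
    am_window: tuple[int, int] = (7, 10)
    pm_window: tuple[int, int] = (19, 22)
    am_window_prob: float = 0.96
    pm_window_prob: float = 0.93
    start_date: str = "2019-01-01"
    enrollment_stagger_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        lo, hi = self.followup_days
        if not (1 <= lo <= hi <= 1000):
            raise ConfigurationError("followup_days must lie within [1, 1000]")
        if len(self.archetype_weights) != len(self.archetypes):
            raise ConfigurationError("one weight per archetype required")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ConfigurationError("archetype_weights must sum to 1")
        if self.two_arm:
            for arm, w in self.arm_weights.items():
                if len(w) != len(self.archetypes):
                    raise ConfigurationError(f"arm {arm}: one weight per archetype")
                if abs(sum(w) - 1.0) > 1e-9:
                    raise ConfigurationError(f"arm {arm}: weights must sum to 1")
        if not 0.0 <= self.missing_block_prob <= 1.0:
            raise ConfigurationError("missing_block_prob outside [0, 1]")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CohortData:
    """Generator output: long event log, malfunction table, truth labels.

    ``labels`` carries the follow-up window per patient (the cohort
    metadata downstream denominators are defined over) alongside the
    ground-truth archetype and arm.
    """

    events: pd.DataFrame        # patient_id, timestamp, n_actuations
    malfunctions: pd.DataFrame  # patient_id, start_date, end_date
    labels: pd.DataFrame        # patient_id, archetype, arm, followup_start, followup_end

    @property
    def followup_windows(self) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
        return {
            row.patient_id: (pd.Timestamp(row.followup_start),
                             pd.Timestamp(row.followup_end))
            for row in self.labels.itertuples()
        }

    def write(self, outdir) -> dict[str, str]:
        """Serialize the three tables as CSV; returns written paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        ev = self.events.copy()
        ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
        for name, frame in (("events", ev),
                            ("malfunctions", self.malfunctions),
                            ("labels", self.labels)):
            p = outdir / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


def _simulate_intermission_mask(n_days: int, spec: ArchetypeSpec,
                                rng: np.random.Generator) -> np.ndarray:
    """Boolean per-day mask of generated intermission days."""
    u = rng.random(n_days)
    p_extra = 1.0 / (1.0 + spec.intermission_mean_extra_days)
    extras = rng.geometric(p_extra, size=n_days) - 1  # mean = mean_extra
    mask = np.zeros(n_days, dtype=bool)
    remaining = 0
    for d in range(n_days):
        if remaining > 0:
            mask[d] = True
            remaining -= 1
        elif u[d] < spec.intermission_start_prob:
            mask[d] = True
            remaining = 5 + int(extras[d]) - 1  # today counts as day 1
    return mask


def _clock_times(n: int, window: tuple[int, int], in_window_prob: float,
                 half: str, rng: np.random.Generator) -> np.ndarray:
    """Minutes past midnight for n actuations in one 12-h half-day."""
    lo, hi = (0, 12) if half == "am" else (12, 24)
    inside = rng.random(n) < in_window_prob
    minutes = np.where(
        inside,
        rng.integers(window[0] * 60, window[1] * 60, size=n),
        rng.integers(lo * 60, hi * 60, size=n),
    )
    return minutes


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate a seeded cohort of EMD actuation logs.

    Returns one event row per dose (with its actuation count), the table of
    battery-failure malfunction blocks, and ground-truth labels mapping each
    patient to archetype, arm, and follow-up window.
    """
    rng = derive_rng(config.seed, "generator")
    base = pd.Timestamp(config.start_date)
    n_arch = len(config.archetypes)

    ev_pid, ev_ts, ev_n = [], [], []
    lab_rows = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        if config.two_arm:
            arm = "control" if i % 2 == 0 else "intervention"
            weights = np.asarray(config.arm_weights[arm], dtype=float)
        else:
            arm = "all"
            weights = np.asarray(config.archetype_weights, dtype=float)
        arch_idx = int(rng.choice(n_arch, p=weights))
        spec = config.archetypes[arch_idx]

        n_days = int(rng.integers(config.followup_days[0],
                                  config.followup_days[1] + 1))
        stagger = int(rng.integers(0, config.enrollment_stagger_days + 1)) \
            if config.enrollment_stagger_days > 0 else 0
        start = base + pd.Timedelta(days=stagger)

        interm = _simulate_intermission_mask(n_days, spec, rng)
        am_taken = (~interm) & (rng.random(n_days) < spec.am_dose_prob)
        pm_taken = (~interm) & (rng.random(n_days) < spec.pm_dose_prob)

        for half, taken, window, wprob in (
                ("am", am_taken, config.am_window, config.am_window_prob),
                ("pm", pm_taken, config.pm_window, config.pm_window_prob)):
            days = np.flatnonzero(taken)
            if days.size == 0:
                continue
            minutes = _clock_times(days.size, window, wprob, half, rng)
            extra = rng.random(days.size) < spec.extra_actuation_prob
            for d, m, e in zip(days, minutes, extra):
                ev_pid.append(pid)
                ev_ts.append(start + pd.Timedelta(days=int(d), minutes=int(m)))
                ev_n.append(2 if e else 1)

        lab_rows.append({
            "patient_id": pid,
            "archetype": spec.name,
            "arm": arm,
            "followup_start": start.date().isoformat(),
            "followup_end": (start + pd.Timedelta(days=n_days - 1)).date().isoformat(),
            "followup_days": n_days,
        })

    events = pd.DataFrame({"patient_id": ev_pid, "timestamp": ev_ts,
                           "n_actuations": ev_n})
    events = events.sort_values(["patient_id", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    labels = pd.DataFrame(lab_rows)

    windows = {r["patient_id"]: (pd.Timestamp(r["followup_start"]),
                                 pd.Timestamp(r["followup_end"]))
               for r in lab_rows}
    events, malfunctions = inject_missingness(events, config, windows, rng=rng)
    return CohortData(events=events, malfunctions=malfunctions, labels=labels)


def inject_missingness(
    events: pd.DataFrame,
    config: CohortConfig,
    followup_windows: dict[str, tuple[pd.Timestamp, pd.Timestamp]],
    *,
    rng: np.random.Generator | None = None,
    blocks: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove battery-failure blocks from an event log.

    If ``blocks`` is not supplied, blocks are sampled: each patient has one
    malfunction block with probability ``missing_block_prob``, with a
    log-normal length (median ``missing_block_median``) clipped to
    ``missing_block_range`` and to the follow-up length. Events whose date
    falls inside a block are dropped; the block table is returned alongside.
    """
    if blocks is None:
        if rng is None:
            rng = derive_rng(config.seed, "missingness")
        lo_len, hi_len = config.missing_block_range
        rows = []
        for pid in sorted(followup_windows):
            if rng.random() >= config.missing_block_prob:
                continue
            start_w, end_w = followup_windows[pid]
            n_days = (end_w - start_w).days + 1
            length = int(np.clip(
                round(float(np.exp(rng.normal(np.log(config.missing_block_median),
                                              config.missing_block_sigma)))),
                lo_len, min(hi_len, n_days)))
            offset = int(rng.integers(0, n_days - length + 1))
            rows.append({
                "patient_id": pid,
                "start_date": (start_w + pd.Timedelta(days=offset)).date().isoformat(),
                "end_date": (start_w + pd.Timedelta(days=offset + length - 1)
                             ).date().isoformat(),
            })
        blocks = pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date"])
    else:
        blocks = blocks.copy()
        for row in blocks.itertuples():
            if row.patient_id not in followup_windows:
                raise ConfigurationError(f"block for unknown patient {row.patient_id}")
            start_w, end_w = followup_windows[row.patient_id]
            s, e = pd.Timestamp(row.start_date), pd.Timestamp(row.end_date)
            if s > e:
                raise ConfigurationError(f"{row.patient_id}: block start after end")
            if s < start_w or e > end_w:
                raise ConfigurationError(
                    f"{row.patient_id}: malfunction block outside follow-up window")

    if blocks.empty or events.empty:
        return events.reset_index(drop=True), blocks

    keep = np.ones(len(events), dtype=bool)
    dates = pd.to_datetime(events["timestamp"]).dt.normalize()
    for row in blocks.itertuples():
        in_block = ((events["patient_id"] == row.patient_id)
                    & (dates >= pd.Timestamp(row.start_date))
                    & (dates <= pd.Timestamp(row.end_date)))
        keep &= ~in_block.to_numpy()
    return events.loc[keep].reset_index(drop=True), blocks
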