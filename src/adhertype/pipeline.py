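"""End-to-end orchestration: simulate/ingest -> measures -> PCA -> clusters ->
stability -> surrogate tree, with a reproducibility manifest.

A single master seed expands into named per-stage substreams (generator,
clustering, partitioning, CART) so re-running any stage in isolation
reproduces its part of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .cluster import order_clusters, select_scaling
from .errors import ConfigurationError
from .ingest import build_dose_grid, parse_event_log, parse_malfunction_table, write_grids
from .latent import SCALING_METHODS
from .measures import MEASURE_NAMES, compute_profile, cohort_measure_matrix
from .synthetic import CohortConfig, CohortData, generate_cohort
from .tree import (CARTParams, accuracy, evaluate, select_best_measure,
                   split_data)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort",
           "person_day_accounting"]

ARTIFACT_NAMES = ("profiles", "loadings", "wss_curve", "stability",
                  "cluster_assignments", "measure_accuracies",
                  "confusion_matrix")


@dataclass
class PipelineConfig:
    """Every protocol constant of the analysis, overridable from YAML.

    Defaults: 95% variance rule, k searched over 1..15 with 25 random
    initiations, 1,000 bootstrap replicates, dissolution threshold 0.5,
    5-day intermission minimum, CART 20/6/2 with 10-fold CV, 70/15/15 split.
    """

    seed: int = 0
    outdir: str = "results"
    cohort: CohortConfig | None = None
    events_path: str | None = None
    malfunctions_path: str | None = None
    labels_path: str | None = None
    scaling_methods: tuple[str, ...] = SCALING_METHODS
    variance_threshold: float = 0.95
    k_max: int = 15
    k_override: int | None = None
    n_init: int = 25
    n_bootstrap: int = 1000
    dissolution_threshold: float = 0.5
    min_intermission_days: int = 5
    include_censored: bool = True
    cart: CARTParams = field(default_factory=CARTParams)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be at least 1")
        if not 0 < self.variance_threshold <= 1:
            raise ConfigurationError("variance_threshold must lie in (0, 1]")
        if self.k_max < 3:
            raise ConfigurationError("k_max must be at least 3")
        if self.n_init < 1:
            raise ConfigurationError("n_init must be at least 1")
        if not 0 < self.dissolution_threshold < 1:
            raise ConfigurationError("dissolution_threshold must lie in (0, 1)")
        if self.min_intermission_days < 1:
            raise ConfigurationError("min_intermission_days must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split_fractions must sum to 1")
        unknown = set(self.scaling_methods) - set(SCALING_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown scaling methods: {sorted(unknown)}")
        has_paths = self.events_path is not None
        if not has_paths and self.cohort is None:
            self.cohort = CohortConfig()

    # -- YAML round trip --------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for key in ("seed", "outdir", "variance_threshold", "k_max",
                    "k_override", "n_init", "n_bootstrap",
                    "dissolution_threshold", "min_intermission_days",
                    "include_censored"):
            if key in d:
                kwargs[key] = d[key]
        if "scaling_methods" in d:
            kwargs["scaling_methods"] = tuple(d["scaling_methods"])
        if "split_fractions" in d:
            kwargs["split_fractions"] = tuple(d["split_fractions"])
        if "cart" in d:
            kwargs["cart"] = CARTParams(**d["cart"])
        inputs = d.get("inputs") or {}
        kwargs["events_path"] = inputs.get("events")
        kwargs["malfunctions_path"] = inputs.get("malfunctions")
        kwargs["labels_path"] = inputs.get("labels")
        if "cohort" in d and d["cohort"] is not None:
            c = dict(d["cohort"])
            from .synthetic import ArchetypeSpec
            if "archetypes" in c:
                c["archetypes"] = tuple(ArchetypeSpec(**a) for a in c["archetypes"])
            for key in ("followup_days", "archetype_weights", "missing_block_range",
                        "am_window", "pm_window"):
                if key in c:
                    c[key] = tuple(c[key])
            if "arm_weights" in c:
                c["arm_weights"] = {k: tuple(v) for k, v in c["arm_weights"].items()}
            kwargs["cohort"] = CohortConfig(**c)
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed, "outdir": self.outdir,
            "scaling_methods": list(self.scaling_methods),
            "variance_threshold": self.variance_threshold,
            "k_max": self.k_max, "k_override": self.k_override,
            "n_init": self.n_init, "n_bootstrap": self.n_bootstrap,
            "dissolution_threshold": self.dissolution_threshold,
            "min_intermission_days": self.min_intermission_days,
            "include_censored": self.include_censored,
            "cart": dataclasses.asdict(self.cart),
            "split_fractions": list(self.split_fractions),
        }
        if self.events_path:
            out["inputs"] = {"events": self.events_path,
                             "malfunctions": self.malfunctions_path,
                             "labels": self.labels_path}
        if self.cohort is not None:
            c = dataclasses.asdict(self.cohort)
            c["archetypes"] = [dataclasses.asdict(a) for a in self.cohort.archetypes]
            out["cohort"] = c
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def person_day_accounting(total_days: int, missing_days: int) -> dict:
    """Conservation summary: analyzed = total - missing, plus % missing."""
    if missing_days > total_days:
        raise ValueError("missing person-days exceed the total")
    return {
        "total_person_days": int(total_days),
        "missing_person_days": int(missing_days),
        "analyzed_person_days": int(total_days - missing_days),
        "pct_missing": round(100.0 * missing_days / total_days) if total_days else 0,
    }


def summarize_cohort(grids: dict, profiles: dict, arms: dict | None = None) -> dict:
    """Descriptive cohort report: persistence summary and person-day accounting."""
    total = sum(g.n_days for g in grids.values())
    analyzed = sum(g.n_observed_days for g in grids.values())
    out = person_day_accounting(total, total - analyzed)

    plist = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    with_int = [p for p in plist if p.n_intermissions > 0]
    out["n_patients"] = len(plist)
    out["n_with_intermission"] = len(with_int)
    out["pct_with_intermission"] = round(100.0 * len(with_int) / len(plist)) \
        if plist else 0
    if with_int:
        out["median_days_to_first_intermission"] = float(
            np.median([p.first_intermission_start for p in with_int]))
        out["median_first_intermission_duration"] = float(
            np.median([p.first_intermission_duration for p in with_int]))
    if arms:
        per_arm: dict[str, list[float]] = {}
        for p in plist:
            per_arm.setdefault(arms.get(p.patient_id, "all"), []).append(p.A)
        out["mean_pct_doses_taken_by_arm"] = {
            arm: float(np.mean(vals)) for arm, vals in sorted(per_arm.items())}
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.events_path is not None:
        events = parse_event_log(config.events_path)
        malfunctions = (parse_malfunction_table(config.malfunctions_path)
                        if config.malfunctions_path else [])
        labels = pd.read_csv(config.labels_path, dtype={"patient_id": str}) \
            if config.labels_path else None
        if labels is not None and {"followup_start", "followup_end"} <= set(labels.columns):
            windows = {r.patient_id: (pd.Timestamp(r.followup_start),
                                      pd.Timestamp(r.followup_end))
                       for r in labels.itertuples()}
        else:
            logger.warning("no follow-up windows in cohort metadata; "
                           "inferring from first/last event per patient")
            windows = {}
            for ev in events:
                lo, hi = windows.get(ev.patient_id, (ev.timestamp, ev.timestamp))
                windows[ev.patient_id] = (min(lo, ev.timestamp),
                                          max(hi, ev.timestamp))
            windows = {p: (lo.normalize(), hi.normalize())
                       for p, (lo, hi) in windows.items()}
        return events, malfunctions, labels, windows

    cohort_cfg = config.cohort.replace(seed=derive_seed(config.seed, "generator"))
    data = generate_cohort(cohort_cfg)
    return data.events, data.malfunctions, data.labels, data.followup_windows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full typology pipeline; returns the manifest (also written).

    Artifacts written to ``config.outdir``: profiles, loadings, wss_curve,
    stability, cluster_assignments, measure_accuracies, confusion_matrix
    (all CSV) plus manifest.json with config, per-stage seeds and artifact
    checksums. Identical configs yield identical checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        events, malfunctions, labels, windows = _load_inputs(config)

        stage = "ingest"
        grids = build_dose_grid(events, malfunctions, windows)

        stage = "measures"
        profiles = {pid: compute_profile(
            g, include_censored=config.include_censored,
            min_intermission_days=config.min_intermission_days)
            for pid, g in grids.items()}
        matrix = cohort_measure_matrix(profiles.values())

        stage = "clustering"
        cluster_seed = derive_seed(config.seed, "cluster")
        best, evaluations = select_scaling(
            matrix, config.scaling_methods,
            variance_threshold=config.variance_threshold,
            k_range=range(1, config.k_max + 1), k_override=config.k_override,
            n_init=config.n_init, n_bootstrap=config.n_bootstrap,
            dissolution_threshold=config.dissolution_threshold,
            seed=cluster_seed)
        ordered = order_clusters(best.solution, matrix["A"])

        stage = "surrogate-tree"
        split_seed = derive_seed(config.seed, "split")
        split = split_data(list(matrix.index), config.split_fractions,
                           seed=split_seed)
        cart_seed = derive_seed(config.seed, "cart")
        best_measure, val_accs, trees = select_best_measure(
            matrix, ordered.labels, split, config.cart, seed=cart_seed)
        test_ids = list(split.test) or list(split.validation)
        final_cm = evaluate(trees[best_measure],
                            matrix.loc[test_ids, best_measure].to_numpy(),
                            ordered.labels.loc[test_ids].to_numpy())
        test_acc = accuracy(final_cm)

        stage = "report"
        arms = None
        if labels is not None and "arm" in getattr(labels, "columns", []):
            arms = dict(zip(labels["patient_id"], labels["arm"]))
        summary = summarize_cohort(grids, profiles, arms)

        artifacts = _write_artifacts(
            outdir, profiles, matrix, best, evaluations, ordered, labels,
            val_accs, best_measure, final_cm)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "config": config.to_dict(),
        "seeds": {name: derive_seed(config.seed, name)
                  for name in ("generator", "cluster", "split", "cart")},
        "selected_scaling": best.method,
        "n_components_95": best.pca.n_components_95,
        "selected_k": best.k,
        "mean_jaccard": {m: e.stability.overall_mean_jaccard
                         for m, e in evaluations.items()},
        "dissolution_rate": {m: e.stability.overall_dissolution
                             for m, e in evaluations.items()},
        "best_measure": best_measure,
        "validation_accuracy": val_accs,
        "test_accuracy": test_acc,
        "test_n": final_cm.total,
        "tree": trees[best_measure].to_dict(),
        "summary": summary,
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=_jsonable))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_artifacts(outdir: Path, profiles, matrix, best, evaluations,
                     ordered, labels, val_accs, best_measure, final_cm
                     ) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    prof = pd.DataFrame([p.as_row() for p in profiles.values()])
    prof = prof.sort_values("patient_id")
    paths["profiles"] = outdir / "profiles.csv"
    prof.to_csv(paths["profiles"], index=False)

    load = best.pca.correlations.copy()
    load.loc["variance_explained"] = best.pca.variance_explained[:load.shape[1]]
    paths["loadings"] = outdir / "loadings.csv"
    load.to_csv(paths["loadings"], index_label="measure")

    curves = pd.concat([
        pd.DataFrame({"scaling_method": m, "k": e.curve.ks, "wss": e.curve.wss})
        for m, e in evaluations.items()], ignore_index=True)
    paths["wss_curve"] = outdir / "wss_curve.csv"
    curves.to_csv(paths["wss_curve"], index=False)

    stab = pd.concat([e.stability.as_frame() for e in evaluations.values()],
                     ignore_index=True)
    paths["stability"] = outdir / "stability.csv"
    stab.to_csv(paths["stability"], index=False)

    assign = pd.DataFrame({"patient_id": ordered.labels.index,
                           "cluster": ordered.labels.to_numpy()})
    if labels is not None and "archetype" in getattr(labels, "columns", []):
        assign = assign.merge(labels[["patient_id", "archetype", "arm"]],
                              on="patient_id", how="left")
    paths["cluster_assignments"] = outdir / "cluster_assignments.csv"
    assign.to_csv(paths["cluster_assignments"], index=False)

    acc = pd.DataFrame({"measure": list(val_accs),
                        "validation_accuracy": list(val_accs.values()),
                        "selected": [m == best_measure for m in val_accs]})
    paths["measure_accuracies"] = outdir / "measure_accuracies.csv"
    acc.to_csv(paths["measure_accuracies"], index=False)

    paths["confusion_matrix"] = outdir / "confusion_matrix.csv"
    final_cm.as_frame().to_csv(paths["confusion_matrix"], index_label="cart_group")

    return paths
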