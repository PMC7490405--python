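import numpy as np
import pandas as pd
import pytest

import adhertype as at
from adhertype._rng import derive_seed
from adhertype.cluster import kmeans_fit, order_clusters, select_k_elbow, wss_curve
from adhertype.ingest import DoseGrid
from adhertype.latent import fit_pca, scale_measures
from adhertype.tree import accuracy, evaluate, select_best_measure, split_data


def make_grid(am, pm, observed=None, patient_id="P1", start="2019-01-01"):
    am = np.asarray(am, dtype=bool)
    if observed is None:
        observed = np.ones(len(am), dtype=bool)
    return DoseGrid(patient_id, pd.Timestamp(start), am,
                    np.asarray(pm, dtype=bool), np.asarray(observed, dtype=bool))


@pytest.fixture
def toy_grid():
    """10 observed days: both doses on days 1-2, AM only day 3, zero days
    4-9, PM only day 10 -> A=30, B=60, C=20, D=10, E=60."""
    am = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    pm = [1, 1, 0, 0, 0, 0, 0, 0, 0, 1]
    return make_grid(am, pm)


def random_grid(rng, max_days=60, p_missing=0.15):
    n = int(rng.integers(5, max_days + 1))
    am = rng.random(n) < rng.uniform(0.05, 0.95)
    pm = rng.random(n) < rng.uniform(0.05, 0.95)
    observed = rng.random(n) >= p_missing
    if not observed.any():
        observed[int(rng.integers(0, n))] = True
    return make_grid(am, pm, observed)


def brute_force_intermissions(grid, min_days=5):
    """Independent oracle: enumerate every day range and keep the maximal
    all-zero, all-observed runs of at least min_days."""
    zero = grid.doses_per_day() == 0
    obs = grid.observed
    n = grid.n_days
    runs = []
    for i in range(n):
        for j in range(i, n):
            if not all(obs[d] and zero[d] for d in range(i, j + 1)):
                continue
            left_ok = i == 0 or not (obs[i - 1] and zero[i - 1])
            right_ok = j == n - 1 or not (obs[j + 1] and zero[j + 1])
            if left_ok and right_ok and j - i + 1 >= min_days:
                runs.append((i, j - i + 1, j == n - 1))
    return runs


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty seeded default cohorts (n=200) pushed through the full chain.

    Shared by the parameter-recovery and surrogate-selection checks: per run
    records the elbow k, adjusted agreement with ground-truth archetypes,
    the selected surrogate measure and its held-out test accuracy.
    """
    from sklearn.metrics import adjusted_rand_score

    runs = []
    for run in range(20):
        cfg = at.CohortConfig(n_patients=200, seed=derive_seed(123, f"run{run}"))
        data = at.generate_cohort(cfg)
        grids = at.build_dose_grid(data.events, data.malfunctions,
                                   data.followup_windows)
        profiles = [at.compute_profile(g) for g in grids.values()]
        matrix = at.cohort_measure_matrix(profiles)
        scaled, _ = scale_measures(matrix, "unit_variance")
        pca = fit_pca(scaled)
        scores = pca.scores.iloc[:, :pca.n_components_95]
        curve = wss_curve(scores, range(1, 16), seed=derive_seed(cfg.seed, "wss"))
        k = select_k_elbow(curve)
        sol = kmeans_fit(scores, k, seed=derive_seed(cfg.seed, "fit"))
        truth = data.labels.set_index("patient_id").archetype.loc[sol.labels.index]
        ari = adjusted_rand_score(truth, sol.labels)
        ordered = order_clusters(sol, matrix["A"])
        split = split_data(list(matrix.index), seed=derive_seed(cfg.seed, "split"))
        best, _, trees = select_best_measure(matrix, ordered.labels, split,
                                             seed=derive_seed(cfg.seed, "cart"))
        test_ids = list(split.test)
        cm = evaluate(trees[best], matrix.loc[test_ids, best].to_numpy(),
                      ordered.labels.loc[test_ids].to_numpy())
        runs.append({"k": k, "ari": ari, "best_measure": best,
                     "test_accuracy": accuracy(cm), "matrix": matrix,
                     "archetypes": truth})
    return runs
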