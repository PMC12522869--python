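"""Synthetic validation experiments: parameter recovery and test calibration.

These drive the simulator + inference stack end to end on data generated at
known truth, providing the evidence that the K grid scan recovers the
clustering preference and that the nonrandomness test holds its nominal
error rate. They are used by the analysis drivers and by the acceptance
checks.
"""

from __future__ import annotations

import numpy as np

from .k_inference import (
    DEFAULT_K_GRID,
    nonrandomness_test,
    paired_null_statistics,
    scan_clustering_preference,
)
from .simulator import (
    ClusterSizeDistribution,
    DEFAULT_N_POSITIONS,
    SimulationParams,
    cluster_size_distribution,
    simulate_layout,
)
from .errors import DegenerateTestError


def generate_cohort(
    k_true: float,
    n_vials: int = 30,
    egg_range: tuple[int, int] = (50, 150),
    n_positions: int = DEFAULT_N_POSITIONS,
    seed: int | None = None,
) -> list[ClusterSizeDistribution]:
    """Simulate a cohort of vials at a known clustering preference.

    Egg totals are drawn uniformly from ``egg_range`` (inclusive); each vial
    gets its own RNG substream.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_vials + 1)
    egg_rng = np.random.default_rng(children[-1])
    cohort = []
    for child in children[:n_vials]:
        n_eggs = int(egg_rng.integers(egg_range[0], egg_range[1] + 1))
        layout = simulate_layout(
            SimulationParams(k_true, n_eggs, n_positions), np.random.default_rng(child)
        )
        cohort.append(cluster_size_distribution(layout))
    return cohort


def recovery_experiment(
    k_true: float = 0.4,
    n_seeds: int = 10,
    n_vials: int = 30,
    egg_range: tuple[int, int] = (50, 150),
    n_scan_reps: int = 10,
    seed: int | None = None,
) -> dict:
    """Parameter recovery: scan K on cohorts generated at a known K.

    Returns the per-seed median best-fit K, the pooled per-vial best-fit K
    values, and the fraction of vials recovered within +-0.1 of the truth.
    """
    ss = np.random.SeedSequence(seed)
    medians = []
    all_best = []
    for run_child in ss.spawn(n_seeds):
        cohort_seed, scan_seed = (
            int(c.generate_state(1)[0] % 2**31) for c in run_child.spawn(2)
        )
        cohort = generate_cohort(k_true, n_vials, egg_range, seed=cohort_seed)
        scan_ss = np.random.SeedSequence(scan_seed)
        best = []
        for csd, child in zip(cohort, scan_ss.spawn(len(cohort))):
            curve = scan_clustering_preference(
                csd,
                n_reps=n_scan_reps,
                seed=int(child.generate_state(1)[0] % 2**31),
            )
            best.append(curve.best_k)
        medians.append(float(np.median(best)))
        all_best.extend(best)
    within = float(np.mean([abs(b - k_true) <= 0.1 + 1e-9 for b in all_best]))
    return {
        "k_true": k_true,
        "medians": medians,
        "per_vial_best_k": all_best,
        "frac_within_0.1": within,
    }


def calibration_experiment(
    k_true: float,
    n_runs: int = 100,
    n_vials: int = 30,
    egg_range: tuple[int, int] = (50, 150),
    n_null_reps: int = 1,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Rejection rate of the nonrandomness test on cohorts at a known K.

    At ``k_true > 0`` this measures power; at ``k_true == 0`` the type-I
    error rate. Degenerate runs (all paired differences zero) are counted as
    non-rejections.
    """
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for run_child in ss.spawn(n_runs):
        cohort_seed, null_seed = (
            int(c.generate_state(1)[0] % 2**31) for c in run_child.spawn(2)
        )
        cohort = generate_cohort(k_true, n_vials, egg_range, seed=cohort_seed)
        obs_stats, null_stats = paired_null_statistics(
            cohort, n_null_reps=n_null_reps, seed=null_seed
        )
        try:
            res = nonrandomness_test(obs_stats, null_stats)
        except DegenerateTestError:
            continue
        if res.p_value < alpha:
            rejections += 1
    return {
        "k_true": k_true,
        "n_runs": n_runs,
        "rejection_rate": rejections / n_runs,
        "alpha": alpha,
    }
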