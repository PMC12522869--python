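"""Synthetic datasets with the statistical structure of the oviposition assays.

Three generators emulate the three experiments:

* ``generate_social_density_experiment`` — vials of 1/2/4/8 mated females
  observed at 2, 4, 7, 10, 22 and 24 h post-mating; per-vial egg totals are
  overdispersed counts scaled by group size, placements come from the
  K-model at the treatment's true clustering preference, intermediate
  timepoints are prefixes of one placement sequence (so per-vial counts are
  monotone), and eclosed adults are binomial draws.
* ``generate_existing_cluster_trials`` — vials seeded with an existing
  edge cluster of 1/4/7/10 eggs; each newly laid egg joins it (distance 0)
  with a treatment-dependent probability or lands at a positive distance.
* ``generate_maternity_experiment`` — 1 focal + 3 dye-fed non-focal mothers
  per vial; each focal clustered egg lands in a mixed-maternity cluster
  with the configured probability.

Every generator records the true parameters it used in a ``truth`` ledger so
round-trip tests can check that the pipeline recovers them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .metrics import EggRecord, ViabilityRecord, VialObservation, proportion_clustered
from .simulator import (
    DEFAULT_N_POSITIONS,
    SimulationParams,
    prefix_cluster_sizes,
    simulate_positions,
)

#: Dish radius used for synthetic coordinates (mm); a standard vial bore.
DISH_RADIUS_MM = 12.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiments.

    Defaults are the observed conditions of the assays: group sizes 1/2/4/8
    with mean eggs per female 7/9/18/19 (SDs 10/9/8/5 per female — counts
    are overdispersed, so a negative-binomial moment match is used), laying
    likelihoods 0.667/0.833/0.967/1.0, true clustering preferences 0.0/0.3/
    0.4/0.5, egg-to-adult viability 0.77 independent of clustering, existing
    edge-cluster sizes 1/4/7/10, and a 0.795 mixed-maternity probability for
    focal clustered eggs.
    """

    treatments: tuple[int, ...] = (1, 2, 4, 8)
    true_k: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.3, 4: 0.4, 8: 0.5}
    )
    mean_eggs_per_female: Mapping[int, float] = field(
        default_factory=lambda: {1: 7.0, 2: 9.0, 4: 18.0, 8: 19.0}
    )
    sd_eggs_per_female: Mapping[int, float] = field(
        default_factory=lambda: {1: 10.0, 2: 9.0, 4: 8.0, 8: 5.0}
    )
    laying_prob: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.667, 2: 0.833, 4: 0.967, 8: 1.0}
    )
    timepoints_h: tuple[float, ...] = (2, 4, 7, 10, 22, 24)
    night_window_h: tuple[float, float] = (9.0, 21.0)  # hours post-mating
    night_dim: float = 0.15       # relative laying intensity in the dark
    viability: float = 0.77
    viability_clustering_slope: float = 0.0  # dependence knob for power studies
    n_vials: int = 30
    n_positions: int = DEFAULT_N_POSITIONS
    existing_sizes: tuple[int, ...] = (1, 4, 7, 10)
    trials_per_existing: Mapping[int, int] = field(
        default_factory=lambda: {1: 20, 4: 17, 7: 20, 10: 21}
    )
    join_prob: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.15, 4: 0.40, 7: 0.33, 10: 0.40}
    )
    nonjoin_distance_mean_mm: Mapping[int, float] = field(
        default_factory=lambda: {1: 11.0, 4: 7.0, 7: 7.5, 10: 6.5}
    )
    mixing_prob: float = 0.795
    n_vials_maternity: int = 28
    n_nonfocal_females: int = 3

    def __post_init__(self) -> None:
        probs = (
            list(self.laying_prob.values())
            + list(self.join_prob.values())
            + [self.viability, self.mixing_prob, self.night_dim]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if any(not 0.0 <= k <= 1.0 for k in self.true_k.values()):
            raise ParameterError("true K values must lie in [0, 1]")
        if any(m <= 0 for m in self.mean_eggs_per_female.values()):
            raise ParameterError("mean egg counts must be positive")
        if self.n_vials < 1 or self.n_vials_maternity < 1:
            raise ParameterError("vial counts must be >= 1")


def _cumulative_laying_fraction(config: SyntheticConfig) -> np.ndarray:
    """Fraction of the final egg total present at each observation timepoint.

    Laying intensity is 1 during the light phase and ``night_dim`` during the
    dark window; the exact shape is cosmetic (it only sets how counts accrue
    between observations) but produces the night-time plateau seen in the
    assays.
    """
    start, end = config.night_window_h

    def effective(t: float) -> float:
        light = min(t, start) + max(0.0, t - end)
        dark = min(max(t - start, 0.0), end - start)
        return light + config.night_dim * dark

    eff = np.array([effective(t) for t in config.timepoints_h])
    return eff / effective(max(config.timepoints_h))


def _draw_egg_total(
    rng: np.random.Generator, mean: float, sd: float, group_size: int
) -> int:
    """Vial-level egg total: negative binomial moment-matched to mean/SD.

    ``mean``/``sd`` are per female; the vial mean is group_size * mean and
    the vial SD is group_size * sd (females treated as correlated within a
    vial, which keeps per-female dispersion at the stated level). Falls back
    to Poisson when the stated variance does not exceed the mean.
    """
    m = mean * group_size
    var = (sd * group_size) ** 2
    if var <= m:
        return int(rng.poisson(m))
    theta = m * m / (var - m)  # NB shape: var = m + m^2/theta
    p = theta / (theta + m)
    return int(rng.negative_binomial(theta, p))


def generate_social_density_experiment(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[VialObservation], list[ViabilityRecord], dict]:
    """Simulate the social-density assay.

    Returns per-vial x timepoint observations, final viability records, and
    a truth ledger with every parameter drawn (per-vial K, egg totals,
    laying indicator).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fractions = _cumulative_laying_fraction(config)

    observations: list[VialObservation] = []
    viability: list[ViabilityRecord] = []
    truth: dict = {
        "seed": seed,
        "true_k": dict(config.true_k),
        "viability": config.viability,
        "vials": {},
    }

    for group in config.treatments:
        k = float(config.true_k[group])
        for i in range(config.n_vials):
            vial_id = f"g{group}_v{i:02d}"
            lays = bool(rng.random() < config.laying_prob[group])
            if lays:
                total = 0
                while total < 1:  # laying vials have at least one egg
                    total = _draw_egg_total(
                        rng,
                        config.mean_eggs_per_female[group],
                        config.sd_eggs_per_female[group],
                        group,
                    )
            else:
                total = 0

            if total:
                params = SimulationParams(
                    k_pref=k, n_eggs=total, n_positions=config.n_positions
                )
                positions = simulate_positions(params, rng)
                # each egg gets an effective laying quantile; counts at a
                # timepoint are the eggs laid by then (monotone prefixes)
                quantiles = np.sort(rng.random(total))
                counts = [int(np.searchsorted(quantiles, f, side="right")) for f in fractions]
                counts[-1] = total
            else:
                positions = np.empty(0, dtype=np.int64)
                counts = [0] * len(fractions)

            for t, c in zip(config.timepoints_h, counts):
                sizes = prefix_cluster_sizes(positions, c) if c else ()
                observations.append(
                    VialObservation(
                        vial_id=vial_id,
                        group_size=group,
                        timepoint_h=t,
                        cluster_sizes=sizes,
                        n_eggs=c,
                    )
                )

            final_sizes = prefix_cluster_sizes(positions, total) if total else ()
            prop = proportion_clustered(final_sizes) if total else 0.0
            v = config.viability + config.viability_clustering_slope * (prop - 0.5)
            v = min(max(v, 0.0), 1.0)
            adults = int(rng.binomial(total, v)) if total else 0
            viability.append(
                ViabilityRecord(
                    vial_id=vial_id,
                    n_eggs=total,
                    n_adults_eclosed=adults,
                    prop_clustered_final=prop,
                )
            )
            truth["vials"][vial_id] = {
                "group_size": group,
                "true_k": k,
                "laid": lays,
                "n_eggs": total,
            }

    return observations, viability, truth


def _edge_point(rng: np.random.Generator) -> tuple[float, float]:
    theta = float(rng.uniform(0, 2 * math.pi))
    return (DISH_RADIUS_MM * math.cos(theta), DISH_RADIUS_MM * math.sin(theta))


def generate_existing_cluster_trials(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[EggRecord], dict]:
    """Simulate the existing-cluster assay.

    Per trial: an existing cluster of 1/4/7/10 eggs in contact at the dish
    edge, then 1-19 newly laid eggs, each joining the cluster (distance 0,
    shared cluster_id) with the treatment's join probability or landing at a
    positive distance drawn from a gamma distribution.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eggs: list[EggRecord] = []
    truth: dict = {"seed": seed, "join_prob": dict(config.join_prob), "trials": {}}

    for size in config.existing_sizes:
        p_join = float(config.join_prob[size])
        d_mean = float(config.nonjoin_distance_mean_mm[size])
        for t in range(config.trials_per_existing[size]):
            vial_id = f"ex{size}_t{t:02d}"
            ex_x, ex_y = _edge_point(rng)
            cluster_id = f"{vial_id}_existing"
            for j in range(size):
                eggs.append(
                    EggRecord(
                        egg_id=f"{vial_id}_e{j:02d}",
                        vial_id=vial_id,
                        x=ex_x,
                        y=ex_y,
                        status="existing",
                        cluster_id=cluster_id,
                    )
                )
            n_new = int(rng.integers(1, 20))
            joins = rng.random(n_new) < p_join
            for j in range(n_new):
                if joins[j]:
                    eggs.append(
                        EggRecord(
                            egg_id=f"{vial_id}_n{j:02d}",
                            vial_id=vial_id,
                            x=ex_x,
                            y=ex_y,
                            status="new",
                            cluster_id=cluster_id,
                        )
                    )
                else:
                    # positive distance: gamma keeps it bounded away from 0
                    d = float(rng.gamma(4.0, d_mean / 4.0)) + 0.5
                    theta = float(rng.uniform(0, 2 * math.pi))
                    eggs.append(
                        EggRecord(
                            egg_id=f"{vial_id}_n{j:02d}",
                            vial_id=vial_id,
                            x=ex_x + d * math.cos(theta),
                            y=ex_y + d * math.sin(theta),
                            status="new",
                            cluster_id=None,
                        )
                    )
            truth["trials"][vial_id] = {
                "existing_size": size,
                "n_new": n_new,
                "n_joined": int(joins.sum()),
            }
    return eggs, truth


def generate_maternity_experiment(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[EggRecord], dict]:
    """Simulate the mixed-maternity assay (1 focal : 3 non-focal mothers).

    Each vial holds one or more focal-containing clusters, each with exactly
    two focal eggs; a cluster is independently mixed (gains 1-3 non-focal
    eggs) with probability ``mixing_prob``, otherwise it stays focal-only.
    Because every focal-containing cluster carries the same number of focal
    eggs, the per-vial proportion of focal clustered eggs in mixed clusters
    is an unbiased estimate of ``mixing_prob``. Non-focal-only clusters and
    singletons are added for realism. With ``n_nonfocal_females == 0`` the
    output contains no non-focal eggs, so the mixing metric is undefined
    downstream.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eggs: list[EggRecord] = []
    truth: dict = {
        "seed": seed,
        "mixing_prob": config.mixing_prob,
        "n_nonfocal_females": config.n_nonfocal_females,
        "vials": {},
    }
    no_nonfocal = config.n_nonfocal_females == 0

    for v in range(config.n_vials_maternity):
        vial_id = f"mat_v{v:02d}"
        counter = 0

        def add(maternity: str, cluster_id: str | None) -> None:
            nonlocal counter
            x, y = _edge_point(rng) if cluster_id is None else (0.0, 0.0)
            eggs.append(
                EggRecord(
                    egg_id=f"{vial_id}_e{counter:03d}",
                    vial_id=vial_id,
                    x=x,
                    y=y,
                    maternity=maternity,
                    status="new",
                    cluster_id=cluster_id,
                )
            )
            counter += 1

        n_focal_clusters = 1 + int(rng.poisson(1.5))
        cluster_n = 0
        n_mixed = 0
        for _ in range(n_focal_clusters):
            cid = f"{vial_id}_c{cluster_n:02d}"
            cluster_n += 1
            add("focal", cid)
            add("focal", cid)
            if not no_nonfocal and rng.random() < config.mixing_prob:
                n_mixed += 1
                for _ in range(int(rng.integers(1, 1 + config.n_nonfocal_females))):
                    add("nonfocal", cid)

        # background eggs: non-focal clusters and singletons of both kinds
        if not no_nonfocal:
            for _ in range(int(rng.poisson(2.0))):
                cid = f"{vial_id}_c{cluster_n:02d}"
                cluster_n += 1
                for _ in range(int(rng.integers(2, 5))):
                    add("nonfocal", cid)
            for _ in range(1 + int(rng.poisson(2.0))):
                add("nonfocal", None)
        for _ in range(int(rng.poisson(1.5))):
            add("focal", None)

        truth["vials"][vial_id] = {
            "n_focal_clusters": n_focal_clusters,
            "n_mixed_clusters": n_mixed,
        }
    return eggs, truth


def observations_to_frame(observations: list[VialObservation]) -> pd.DataFrame:
    """Tidy table: one row per (vial, timepoint, cluster size); zero-egg
    observations are kept as sentinel rows with cluster_size = count = 0."""
    rows = []
    for o in observations:
        if not o.cluster_sizes:
            rows.append(
                {
                    "vial_id": o.vial_id,
                    "group_size": o.group_size,
                    "timepoint_h": o.timepoint_h,
                    "cluster_size": 0,
                    "count": 0,
                }
            )
            continue
        sizes, counts = np.unique(np.array(o.cluster_sizes), return_counts=True)
        for s, c in zip(sizes, counts):
            rows.append(
                {
                    "vial_id": o.vial_id,
                    "group_size": o.group_size,
                    "timepoint_h": o.timepoint_h,
                    "cluster_size": int(s),
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)


def eggs_to_frame(eggs: list[EggRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "egg_id": e.egg_id,
                "vial_id": e.vial_id,
                "x": e.x,
                "y": e.y,
                "maternity": e.maternity,
                "status": e.status,
                "cluster_id": "" if e.cluster_id is None else e.cluster_id,
            }
            for e in eggs
        ]
    )


def viability_to_frame(records: list[ViabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vial_id": r.vial_id,
                "n_eggs": r.n_eggs,
                "n_adults_eclosed": r.n_adults_eclosed,
                "prop_clustered_final": r.prop_clustered_final,
            }
            for r in records
        ]
    )
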