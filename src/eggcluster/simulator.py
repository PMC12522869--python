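"""Sequential stochastic egg-placement model with clustering preference K.

The laying surface of a vial is discretised into ``n_positions`` egg-sized
sites (default 5770, the vial-surface-to-egg area ratio). Eggs are laid one
at a time. The first egg lands on a uniformly random site. Every later egg
either

* joins an existing egg with probability ``k_pref`` (K): a site is chosen
  uniformly among the currently occupied sites and the egg is added there, or
* lands on a uniformly random site among all ``n_positions`` with probability
  ``1 - K`` — which may coincidentally be an occupied site, in which case the
  egg joins that cluster anyway.

All eggs sharing a site form one contact cluster; a site holding a single
egg is a singly laid egg. K = 0 is the random-laying null model, K = 1
stacks every egg onto one site.

The module also provides a closed-form occupancy oracle for the K = 0 null
(`expected_null_multisites`), used to validate the Monte-Carlo simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError

#: Number of egg-sized sites on a standard vial's laying surface.
DEFAULT_N_POSITIONS = 5770


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the sequential placement model.

    Parameters
    ----------
    k_pref:
        Clustering preference K, the probability that each egg after the
        first is placed with an already-laid egg. Must lie in [0, 1].
    n_eggs:
        Total number of eggs laid in the vial (the model's egg budget).
    n_positions:
        Number of discrete laying sites on the vial surface.
    n_reps:
        Number of independent replicate layouts for ensemble runs.
    seed:
        Root seed for reproducible ensembles; ``None`` draws fresh entropy.
    """

    k_pref: float
    n_eggs: int
    n_positions: int = DEFAULT_N_POSITIONS
    n_reps: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if math.isnan(self.k_pref) or not 0.0 <= self.k_pref <= 1.0:
            raise ParameterError(f"k_pref must be in [0, 1], got {self.k_pref!r}")
        if self.n_eggs < 0:
            raise ParameterError(f"n_eggs must be >= 0, got {self.n_eggs}")
        if self.n_positions < 1:
            raise ParameterError(f"n_positions must be >= 1, got {self.n_positions}")
        if self.n_reps < 1:
            raise ParameterError(f"n_reps must be >= 1, got {self.n_reps}")


@dataclass(frozen=True)
class EggLayout:
    """A realised placement: mapping from occupied site index to egg count."""

    occupancy: dict[int, int]
    n_eggs: int
    n_positions: int


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Multiset of per-site egg counts (sorted ascending).

    Entries of size >= 2 are clusters; size-1 entries are singly laid eggs.
    """

    sizes: tuple[int, ...]
    n_eggs: int

    @property
    def n_clusters(self) -> int:
        return sum(1 for s in self.sizes if s >= 2)

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    @property
    def largest(self) -> int:
        return max(self.sizes) if self.sizes else 0

    @property
    def eggs_in_clusters(self) -> int:
        return sum(s for s in self.sizes if s >= 2)


def simulate_positions(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Return the ordered sequence of site indices, one per egg.

    The full placement sequence is exposed (rather than only the final
    occupancy) so that prefix truncation can reconstruct the state of the
    vial at intermediate observation timepoints.
    """
    n_eggs, n_pos, k = params.n_eggs, params.n_positions, params.k_pref
    if n_eggs == 0:
        return np.empty(0, dtype=np.int64)
    # Pre-draw all randomness; the loop is then pure Python arithmetic.
    decide = rng.random(n_eggs).tolist()
    pick = rng.random(n_eggs).tolist()
    rand_pos = rng.integers(0, n_pos, size=n_eggs).tolist()

    out = [0] * n_eggs
    first = rand_pos[0]
    out[0] = first
    occupied = [first]          # unique occupied sites, insertion order
    occ_set = {first}
    for i in range(1, n_eggs):
        if decide[i] < k:
            pos = occupied[int(pick[i] * len(occupied))]
        else:
            pos = rand_pos[i]
            if pos not in occ_set:
                occ_set.add(pos)
                occupied.append(pos)
        out[i] = pos
    return np.asarray(out, dtype=np.int64)


def layout_from_positions(positions: Sequence[int], n_positions: int) -> EggLayout:
    """Aggregate a placement sequence (or any site list) into an EggLayout."""
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= n_positions):
        raise ParameterError("position index outside [0, n_positions)")
    sites, counts = np.unique(pos, return_counts=True)
    occupancy = {int(s): int(c) for s, c in zip(sites, counts)}
    return EggLayout(occupancy=occupancy, n_eggs=int(pos.size), n_positions=n_positions)


def simulate_layout(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> EggLayout:
    """Simulate one vial layout under the K-model."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    positions = simulate_positions(params, rng)
    return layout_from_positions(positions, params.n_positions)


def cluster_size_distribution(layout: EggLayout) -> ClusterSizeDistribution:
    """Read off the multiset of per-site egg counts from a layout."""
    sizes = tuple(sorted(layout.occupancy.values()))
    return ClusterSizeDistribution(sizes=sizes, n_eggs=layout.n_eggs)


def prefix_cluster_sizes(positions: np.ndarray, n_eggs: int) -> tuple[int, ...]:
    """Cluster-size multiset after the first ``n_eggs`` placements."""
    if n_eggs < 0 or n_eggs > len(positions):
        raise ParameterError("prefix length outside the placement sequence")
    _, counts = np.unique(positions[:n_eggs], return_counts=True)
    return tuple(sorted(int(c) for c in counts))


def _child_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent substream generators from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_ensemble(params: SimulationParams) -> list[ClusterSizeDistribution]:
    """Simulate ``n_reps`` independent layouts; same seed, same ensemble."""
    out = []
    for rng in _child_rngs(params.seed, params.n_reps):
        layout = simulate_layout(params, rng)
        out.append(cluster_size_distribution(layout))
    return out


def expected_null_multisites(n_eggs: int, n_positions: int) -> float:
    """Exact expected number of sites holding >= 2 eggs under random laying.

    Under K = 0 each egg independently picks a uniform site, so each site
    holds Binomial(E, 1/N) eggs and the expected count of multi-occupied
    sites is::

        N * [1 - (1 - 1/N)^E - (E/N) * (1 - 1/N)^(E-1)]

    This is the occupancy ("birthday collision") expectation used as the
    analytic oracle for the simulator's K = 0 limit.
    """
    if n_eggs < 0:
        raise ParameterError(f"n_eggs must be >= 0, got {n_eggs}")
    if n_positions < 1:
        raise ParameterError(f"n_positions must be >= 1, got {n_positions}")
    if n_eggs < 2:
        return 0.0
    n, e = float(n_positions), n_eggs
    q = 1.0 - 1.0 / n
    return n * (1.0 - q**e - (e / n) * q ** (e - 1))


def null_clustering_statistics(n_eggs: int, n_positions: int) -> dict[str, float]:
    """Closed-form summaries of how much clustering random laying produces.

    The amount of coincidental clustering at K = 0 can be quoted on several
    scales; all three are exposed because they differ by factors of a few:

    ``expected_multi_positions``
        Expected number of sites with >= 2 eggs (clusters per vial).
    ``clusters_per_egg``
        The same expectation divided by the egg count.
    ``expected_prop_eggs_clustered``
        Expected fraction of eggs sharing a site with at least one other
        egg: ``1 - (1 - 1/N)^(E-1)``.
    """
    m = expected_null_multisites(n_eggs, n_positions)
    if n_eggs == 0:
        prop = 0.0
    else:
        prop = 1.0 - (1.0 - 1.0 / n_positions) ** (n_eggs - 1)
    return {
        "expected_multi_positions": m,
        "clusters_per_egg": m / n_eggs if n_eggs else 0.0,
        "expected_prop_eggs_clustered": prop,
    }
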