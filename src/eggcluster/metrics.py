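"""Empirical response variables of the oviposition experiments.

All operations work on tidy in-memory records (dataclasses / DataFrames)
and are invariant to the row order of their inputs. Model fitting (GLM/LM/
LME, correlations) is out of scope: these functions compute the response
variables and export tidy tables for standard statistics routines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParameterError,
    SchemaError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

GROUP_SIZES = (1, 2, 4, 8)
TIMEPOINTS_H = (2, 4, 7, 10, 22, 24)

#: Vial counts per group size that equalise sampling effort by number of
#: flies (30, 30, 32, 32 flies) rather than number of vials.
REBALANCE_TARGETS: dict[int, int] = {1: 30, 2: 15, 4: 8, 8: 4}


@dataclass(frozen=True)
class VialObservation:
    """One vial x timepoint record of egg counts and cluster sizes."""

    vial_id: str
    group_size: int
    timepoint_h: float
    cluster_sizes: tuple[int, ...]
    n_eggs: int

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.n_eggs:
            raise SchemaError(
                f"vial {self.vial_id} t={self.timepoint_h}: cluster sizes sum to "
                f"{sum(self.cluster_sizes)}, n_eggs is {self.n_eggs}"
            )
        if any(s < 1 for s in self.cluster_sizes):
            raise SchemaError(f"vial {self.vial_id}: cluster sizes must be >= 1")


@dataclass(frozen=True)
class EggRecord:
    """One egg: coordinates, maternity label, new/existing status, cluster id."""

    egg_id: str
    vial_id: str
    x: float
    y: float
    maternity: str = "unknown"      # focal | nonfocal | unknown
    status: str = "new"             # existing | new
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise SchemaError(f"egg {self.egg_id}: non-finite coordinates")
        if self.maternity not in ("focal", "nonfocal", "unknown"):
            raise SchemaError(f"egg {self.egg_id}: bad maternity {self.maternity!r}")
        if self.status not in ("existing", "new"):
            raise SchemaError(f"egg {self.egg_id}: bad status {self.status!r}")


@dataclass(frozen=True)
class ViabilityRecord:
    vial_id: str
    n_eggs: int
    n_adults_eclosed: int
    prop_clustered_final: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_adults_eclosed <= self.n_eggs:
            raise SchemaError(
                f"vial {self.vial_id}: {self.n_adults_eclosed} adults from "
                f"{self.n_eggs} eggs"
            )


def proportion_clustered(cluster_sizes: Iterable[int]) -> float:
    """Fraction of eggs that sit in clusters (sites holding >= 2 eggs).

    Computed as the sum of all cluster sizes (>= 2) divided by the total
    number of eggs laid in the vial.
    """
    sizes = list(cluster_sizes)
    total = sum(sizes)
    if total <= 0:
        raise UndefinedMetricError("proportion clustered undefined with zero eggs")
    if any(s < 1 for s in sizes):
        raise ParameterError("cluster sizes must be positive integers")
    return sum(s for s in sizes if s >= 2) / total


@dataclass(frozen=True)
class VialSummary:
    table: pd.DataFrame
    latency_h: float | None  # first observation time with eggs; None if censored


def vial_summary(observations: Sequence[VialObservation]) -> VialSummary:
    """Per-timepoint summary of one vial's laying series.

    Returns eggs per female (n_eggs / group_size), number of clusters,
    largest cluster, proportion clustered (NaN while the vial is empty) and
    the latency to first egg (interval-censored at the observation grid).
    """
    if not observations:
        raise InsufficientDataError("no observations supplied")
    vial_ids = {o.vial_id for o in observations}
    if len(vial_ids) != 1:
        raise ParameterError(f"expected one vial, got {sorted(vial_ids)}")
    obs = sorted(observations, key=lambda o: o.timepoint_h)
    times = [o.timepoint_h for o in obs]
    if len(set(times)) != len(times):
        raise SchemaError(f"vial {obs[0].vial_id}: duplicate timepoints")
    counts = [o.n_eggs for o in obs]
    if any(b < a for a, b in zip(counts, counts[1:])):
        raise SchemaError(f"vial {obs[0].vial_id}: egg counts decrease over time")

    rows = []
    latency: float | None = None
    for o in obs:
        if o.n_eggs > 0 and latency is None:
            latency = o.timepoint_h
        rows.append(
            {
                "vial_id": o.vial_id,
                "group_size": o.group_size,
                "timepoint_h": o.timepoint_h,
                "n_eggs": o.n_eggs,
                "eggs_per_female": o.n_eggs / o.group_size,
                "n_clusters": sum(1 for s in o.cluster_sizes if s >= 2),
                "largest_cluster": max(o.cluster_sizes, default=0),
                "prop_clustered": (
                    proportion_clustered(o.cluster_sizes) if o.n_eggs > 0 else np.nan
                ),
            }
        )
    return VialSummary(table=pd.DataFrame(rows), latency_h=latency)


@dataclass(frozen=True)
class JoinMetrics:
    """Whether/how much newly laid eggs joined the existing treatment eggs."""

    any_joined: bool
    prop_joined: float
    distances: tuple[float, ...]   # per new egg: min distance to any existing egg
    mean_distance: float
    n_new: int
    n_existing: int


def join_metrics(
    eggs: Sequence[EggRecord],
    *,
    contact_tol: float = 0.0,
    aggregation: str = "min",
) -> JoinMetrics:
    """Join/proximity metrics for one existing-cluster trial.

    A new egg counts as joined when it shares a cluster_id with an existing
    egg (eye-scored contact takes precedence) or its nearest edge-to-edge
    distance to an existing egg is <= ``contact_tol`` (default 0: contact
    means a recorded distance of zero). Per-egg distance is the minimum
    Euclidean distance to any existing egg, forced to 0 for joined eggs.
    ``aggregation='min'`` reports the trial mean of the per-egg minima;
    ``'all-pairs'`` reports the mean over all new x existing pairs instead.
    """
    if aggregation not in ("min", "all-pairs"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    existing = sorted(
        (e for e in eggs if e.status == "existing"), key=lambda e: e.egg_id
    )
    new = sorted((e for e in eggs if e.status == "new"), key=lambda e: e.egg_id)
    if not new:
        raise InsufficientDataError("trial has no new eggs; excluded")
    if not existing:
        raise InsufficientDataError("trial has no existing eggs")

    ex_xy = np.array([[e.x, e.y] for e in existing])
    ex_ids = {e.cluster_id for e in existing if e.cluster_id is not None}

    distances = []
    joined = []
    all_pair: list[float] = []
    for egg in new:
        d = np.hypot(ex_xy[:, 0] - egg.x, ex_xy[:, 1] - egg.y)
        shares_cluster = egg.cluster_id is not None and egg.cluster_id in ex_ids
        dmin = 0.0 if shares_cluster else float(d.min())
        distances.append(dmin)
        joined.append(shares_cluster or dmin <= contact_tol)
        all_pair.extend([0.0] * len(existing) if shares_cluster else d.tolist())

    mean_distance = float(
        np.mean(distances) if aggregation == "min" else np.mean(all_pair)
    )
    return JoinMetrics(
        any_joined=any(joined),
        prop_joined=sum(joined) / len(new),
        distances=tuple(distances),
        mean_distance=mean_distance,
        n_new=len(new),
        n_existing=len(existing),
    )


def maternity_mix(eggs: Sequence[EggRecord]) -> float:
    """Proportion of focal clustered eggs that sit in mixed-maternity clusters.

    A cluster is a group of >= 2 eggs sharing a cluster_id; it is mixed when
    it contains at least one non-focal egg alongside a focal one. The
    numerator counts focal eggs in mixed clusters, the denominator focal
    eggs in any cluster.
    """
    if not any(e.maternity == "nonfocal" for e in eggs):
        raise UndefinedMetricError(
            "no non-focal eggs present; maternity mixing undefined"
        )
    clusters: dict[str, list[EggRecord]] = {}
    for e in eggs:
        if e.cluster_id is not None:
            clusters.setdefault(e.cluster_id, []).append(e)
    focal_clustered = 0
    focal_mixed = 0
    for members in clusters.values():
        if len(members) < 2:
            continue
        if any(m.maternity == "unknown" for m in members):
            raise SchemaError("clustered egg without a focal/nonfocal label")
        has_nonfocal = any(m.maternity == "nonfocal" for m in members)
        n_focal = sum(1 for m in members if m.maternity == "focal")
        focal_clustered += n_focal
        if has_nonfocal:
            focal_mixed += n_focal
    if focal_clustered == 0:
        raise UndefinedMetricError("no focal eggs in clusters; proportion undefined")
    return focal_mixed / focal_clustered


def viability_metrics(records: Sequence[ViabilityRecord]) -> pd.DataFrame:
    """Per-vial egg-to-adult viability paired with final clustering proportion.

    Emits a tidy table (vial_id, n_eggs, n_adults_eclosed, viability,
    prop_clustered_final) for downstream correlation/regression fitting.
    """
    if not records:
        raise InsufficientDataError("no viability records")
    rows = [
        {
            "vial_id": r.vial_id,
            "n_eggs": r.n_eggs,
            "n_adults_eclosed": r.n_adults_eclosed,
            "viability": r.n_adults_eclosed / r.n_eggs if r.n_eggs else np.nan,
            "prop_clustered_final": r.prop_clustered_final,
        }
        for r in sorted(records, key=lambda r: r.vial_id)
    ]
    return pd.DataFrame(rows)


def rebalance_subsample(
    vials: Mapping[str, int] | Sequence[tuple[str, int]],
    targets: Mapping[int, int] = REBALANCE_TARGETS,
    seed: int | None = None,
) -> list[str]:
    """Random vial subset equalising per-treatment sampling effort by flies.

    ``vials`` maps vial_id -> group_size. The default targets keep all
    solitary vials (30), half the pairs (15), eight four-female vials and
    four eight-female vials, i.e. 30/30/32/32 flies per treatment.
    Deterministic under ``seed``; raises listing the deficit when a
    treatment has too few vials.
    """
    items = sorted(dict(vials).items()) if not isinstance(vials, Mapping) else sorted(vials.items())
    by_group: dict[int, list[str]] = {}
    for vial_id, g in items:
        by_group.setdefault(int(g), []).append(vial_id)
    deficits = {
        g: (need, len(by_group.get(g, [])))
        for g, need in targets.items()
        if len(by_group.get(g, [])) < need
    }
    if deficits:
        msg = "; ".join(
            f"group {g}: need {need}, have {have}" for g, (need, have) in deficits.items()
        )
        raise InsufficientDataError(f"not enough vials to rebalance: {msg}")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for g in sorted(targets):
        pool = sorted(by_group[g])
        chosen = rng.choice(len(pool), size=targets[g], replace=False)
        selected.extend(pool[i] for i in sorted(chosen))
    return selected
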