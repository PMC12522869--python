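"""Hand-computed examples and invariances for the empirical metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import eggcluster as ec


def egg(egg_id, x=0.0, y=0.0, maternity="unknown", status="new", cluster_id=None):
    return ec.EggRecord(
        egg_id=egg_id, vial_id="v", x=x, y=y,
        maternity=maternity, status=status, cluster_id=cluster_id,
    )


# ------------------------------------------------- proportion clustered

@pytest.mark.parametrize(
    "sizes,expected",
    [
        ((1, 1, 1), 0.0),
        ((3, 1), 0.75),
        ((2, 2, 1, 1, 1, 1), 0.5),
        ((5,), 1.0),
    ],
)
def test_proportion_clustered_hand_examples(sizes, expected):
    assert ec.proportion_clustered(sizes) == pytest.approx(expected)


def test_proportion_clustered_zero_eggs_undefined():
    with pytest.raises(ec.UndefinedMetricError):
        ec.proportion_clustered(())


@given(st.lists(st.integers(1, 12), min_size=1, max_size=30))
def test_proportion_clustered_bounds_and_extremes(sizes):
    p = ec.proportion_clustered(sizes)
    assert 0.0 <= p <= 1.0
    assert (p == 1.0) == all(s >= 2 for s in sizes)
    assert (p == 0.0) == all(s == 1 for s in sizes)


# -------------------------------------------------------- vial summary

def obs(t, sizes, vial="v1", group=8):
    return ec.VialObservation(
        vial_id=vial, group_size=group, timepoint_h=t,
        cluster_sizes=tuple(sizes), n_eggs=sum(sizes),
    )


def test_vial_summary_eggs_per_female_and_cluster_stats():
    series = [obs(24, [5, 2, 1] * 19)]  # 152 eggs, group of 8
    s = ec.vial_summary(series)
    row = s.table.iloc[0]
    assert row["eggs_per_female"] == pytest.approx(19.0)
    assert row["n_clusters"] == 38
    assert row["largest_cluster"] == 5


def test_vial_summary_latency_first_timepoint_with_eggs():
    series = [obs(2, []), obs(4, []), obs(7, [2]), obs(10, [2, 1])]
    s = ec.vial_summary(series)
    assert s.latency_h == 7
    assert np.isnan(s.table["prop_clustered"].iloc[0])


def test_vial_summary_censored_latency_when_no_eggs():
    s = ec.vial_summary([obs(t, []) for t in (2, 4, 7)])
    assert s.latency_h is None


def test_vial_summary_row_order_invariant():
    series = [obs(2, [1]), obs(4, [2]), obs(7, [2, 1])]
    a = ec.vial_summary(series).table
    b = ec.vial_summary(series[::-1]).table
    pd.testing.assert_frame_equal(a, b)


def test_vial_summary_rejects_duplicates_and_decreasing_counts():
    with pytest.raises(ec.SchemaError):
        ec.vial_summary([obs(2, [1]), obs(2, [1, 1])])
    with pytest.raises(ec.SchemaError):
        ec.vial_summary([obs(2, [1, 1]), obs(4, [1])])


# -------------------------------------------------------- join metrics

def test_join_metrics_shared_cluster_id_is_contact():
    eggs = [
        egg("e1", 5, 5, status="existing", cluster_id="c1"),
        egg("n1", 9, 9, status="new", cluster_id="c1"),
    ]
    jm = ec.join_metrics(eggs)
    assert jm.any_joined and jm.prop_joined == 1.0
    assert jm.distances == (0.0,)


def test_join_metrics_hand_geometry():
    """New at (0,0) and (3,4); existing at (0,0) and (30,40): per-egg minima
    are 0 and 5 (the 3-4-5 triangle), so half of the new eggs joined."""
    eggs = [
        egg("x1", 0, 0, status="existing", cluster_id="cx"),
        egg("x2", 30, 40, status="existing", cluster_id="cx"),
        egg("n1", 0, 0, status="new"),
        egg("n2", 3, 4, status="new"),
    ]
    jm = ec.join_metrics(eggs)
    assert jm.distances == (0.0, 5.0)
    assert jm.prop_joined == 0.5
    assert jm.any_joined
    assert jm.mean_distance == pytest.approx(2.5)


def test_join_metrics_no_contact():
    eggs = [
        egg("x1", 0, 0, status="existing", cluster_id="cx"),
        egg("n1", 10, 0, status="new"),
        egg("n2", 0, 15, status="new"),
    ]
    jm = ec.join_metrics(eggs)
    assert not jm.any_joined
    assert jm.prop_joined == 0.0
    assert all(d > 0 for d in jm.distances)


def test_join_metrics_all_pairs_aggregation():
    eggs = [
        egg("x1", 0, 0, status="existing", cluster_id="cx"),
        egg("x2", 0, 10, status="existing", cluster_id="cx"),
        egg("n1", 0, 4, status="new"),
    ]
    jm_min = ec.join_metrics(eggs, aggregation="min")
    jm_all = ec.join_metrics(eggs, aggregation="all-pairs")
    assert jm_min.mean_distance == pytest.approx(4.0)
    assert jm_all.mean_distance == pytest.approx(5.0)  # (4 + 6) / 2


def test_join_metrics_requires_new_and_existing():
    with pytest.raises(ec.InsufficientDataError):
        ec.join_metrics([egg("x1", status="existing", cluster_id="c")])
    with pytest.raises(ec.InsufficientDataError):
        ec.join_metrics([egg("n1", status="new")])


def test_join_metrics_row_order_invariant():
    eggs = [
        egg("x1", 0, 0, status="existing", cluster_id="cx"),
        egg("n1", 3, 4, status="new"),
        egg("n2", 6, 8, status="new"),
    ]
    a = ec.join_metrics(eggs)
    b = ec.join_metrics(eggs[::-1])
    assert a == b


# ------------------------------------------------------- maternity mix

def cluster_eggs(spec):
    """spec: list of clusters given as lists of maternity labels; singletons
    allowed via 1-element lists with cluster_id None."""
    eggs = []
    i = 0
    for c, labels in enumerate(spec):
        cid = f"c{c}" if len(labels) >= 2 else None
        for label in labels:
            eggs.append(egg(f"e{i}", maternity=label, cluster_id=cid))
            i += 1
    return eggs


def test_maternity_mix_hand_examples():
    no_mix = cluster_eggs([["focal", "focal"], ["nonfocal", "nonfocal"]])
    assert ec.maternity_mix(no_mix) == 0.0

    all_mix = cluster_eggs([["focal", "nonfocal", "nonfocal"]])
    assert ec.maternity_mix(all_mix) == 1.0

    # 3 mixed focal of 5 clustered focal
    mixed = cluster_eggs(
        [["focal", "focal"], ["focal", "nonfocal"], ["focal", "nonfocal", "focal"]]
    )
    assert ec.maternity_mix(mixed) == pytest.approx(0.6)


def test_maternity_mix_ignores_nonfocal_only_clusters():
    base = cluster_eggs([["focal", "nonfocal"]])
    extra = cluster_eggs([["focal", "nonfocal"], ["nonfocal", "nonfocal", "nonfocal"]])
    assert ec.maternity_mix(base) == ec.maternity_mix(extra)


def test_maternity_mix_undefined_without_nonfocals_or_clustered_focals():
    with pytest.raises(ec.UndefinedMetricError):
        ec.maternity_mix(cluster_eggs([["focal", "focal"]]))  # no nonfocals at all
    with pytest.raises(ec.UndefinedMetricError):
        ec.maternity_mix(
            cluster_eggs([["nonfocal", "nonfocal"], ["focal"]])
        )  # nonfocals present, but no focal egg in any cluster


def test_maternity_mix_unlabelled_clustered_egg_errors():
    eggs = cluster_eggs([["focal", "nonfocal"]])
    eggs.append(egg("u1", maternity="unknown", cluster_id="c0"))
    with pytest.raises(ec.SchemaError):
        ec.maternity_mix(eggs)


# ---------------------------------------------------------- viability

def test_viability_metrics_table():
    records = [
        ec.ViabilityRecord("v1", 100, 80, 0.5),
        ec.ViabilityRecord("v2", 50, 0, 0.2),
    ]
    df = ec.viability_metrics(records)
    assert df.set_index("vial_id").loc["v1", "viability"] == pytest.approx(0.8)
    assert df.set_index("vial_id").loc["v2", "viability"] == 0.0


def test_viability_more_adults_than_eggs_rejected():
    with pytest.raises(ec.SchemaError):
        ec.ViabilityRecord("v1", 10, 11, 0.0)


def test_viability_independent_of_clustering_in_large_synthetic_cohort():
    """With viability generated independently of clustering, the sample
    correlation between the two shrinks toward zero."""
    rng = np.random.default_rng(8)
    records = []
    for i in range(4000):
        n = int(rng.integers(20, 200))
        prop = float(rng.uniform(0, 1))
        adults = int(rng.binomial(n, 0.77))
        records.append(ec.ViabilityRecord(f"v{i}", n, adults, prop))
    df = ec.viability_metrics(records)
    r = np.corrcoef(df["viability"], df["prop_clustered_final"])[0, 1]
    assert abs(r) < 0.05


# ---------------------------------------------------------- rebalance

def make_roster(counts={1: 30, 2: 30, 4: 30, 8: 30}):
    roster = {}
    for g, n in counts.items():
        for i in range(n):
            roster[f"g{g}_v{i:02d}"] = g
    return roster


def test_rebalance_counts_and_fly_totals():
    roster = make_roster()
    chosen = ec.rebalance_subsample(roster, seed=5)
    by_group = {}
    for vid in chosen:
        by_group.setdefault(roster[vid], []).append(vid)
    assert {g: len(v) for g, v in by_group.items()} == {1: 30, 2: 15, 4: 8, 8: 4}
    flies = {g: len(v) * g for g, v in by_group.items()}
    assert flies == {1: 30, 2: 30, 4: 32, 8: 32}
    assert len(set(chosen)) == len(chosen)


def test_rebalance_deterministic_and_order_invariant():
    roster = make_roster()
    a = ec.rebalance_subsample(roster, seed=9)
    b = ec.rebalance_subsample(dict(reversed(list(roster.items()))), seed=9)
    assert a == b
    assert a != ec.rebalance_subsample(roster, seed=10)


def test_rebalance_insufficient_vials_lists_deficit():
    roster = make_roster({1: 30, 2: 30, 4: 30, 8: 3})
    with pytest.raises(ec.InsufficientDataError, match="group 8"):
        ec.rebalance_subsample(roster, seed=1)
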