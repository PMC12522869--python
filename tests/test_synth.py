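"""Generator self-checks: reproducibility, truth-ledger round trips, and
recovery of the configured parameters by the downstream metrics."""

import numpy as np
import pytest

import eggcluster as ec
from eggcluster.synth import eggs_to_frame, observations_to_frame, viability_to_frame


@pytest.fixture(scope="module")
def social():
    config = ec.SyntheticConfig()
    return config, ec.generate_social_density_experiment(config, seed=101)


def test_social_reproducible_byte_identical(social):
    config, (obs, via, truth) = social
    obs2, via2, truth2 = ec.generate_social_density_experiment(config, seed=101)
    assert observations_to_frame(obs).equals(observations_to_frame(obs2))
    assert viability_to_frame(via).equals(viability_to_frame(via2))
    assert truth == truth2


def test_social_shape_and_monotone_counts(social):
    config, (obs, via, truth) = social
    vials = {o.vial_id for o in obs}
    assert len(vials) == 120  # 4 treatments x 30 vials
    assert len(via) == 120
    by_vial = {}
    for o in obs:
        by_vial.setdefault(o.vial_id, []).append(o)
    for series in by_vial.values():
        series.sort(key=lambda o: o.timepoint_h)
        assert [o.timepoint_h for o in series] == [2, 4, 7, 10, 22, 24]
        counts = [o.n_eggs for o in series]
        assert counts == sorted(counts)  # prefixes of one placement sequence


def test_social_eggs_per_female_match_configured_means():
    """Across several seeds, per-treatment mean eggs per female sit within
    2 SE of the configured means (7, 9, 18, 19)."""
    config = ec.SyntheticConfig()
    per_female = {g: [] for g in config.treatments}
    for seed in range(6):
        obs, _, _ = ec.generate_social_density_experiment(config, seed=200 + seed)
        for o in obs:
            if o.timepoint_h == 24:
                per_female[o.group_size].append(o.n_eggs / o.group_size)
    for g in config.treatments:
        vals = np.array(per_female[g])
        # unconditional mean: laying likelihood scales the conditional mean
        target = config.mean_eggs_per_female[g] * config.laying_prob[g]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) <= max(2 * se, 0.02 * target), (g, vals.mean(), target)


def test_social_laying_likelihood_matches_config():
    config = ec.SyntheticConfig()
    laid = {g: [] for g in config.treatments}
    for seed in range(8):
        _, via, truth = ec.generate_social_density_experiment(config, seed=300 + seed)
        for vial_id, info in truth["vials"].items():
            laid[info["group_size"]].append(info["laid"])
    for g in config.treatments:
        frac = np.mean(laid[g])
        p = config.laying_prob[g]
        se = np.sqrt(p * (1 - p) / len(laid[g])) if 0 < p < 1 else 0.0
        assert abs(frac - p) <= max(3 * se, 1e-9)


def test_social_solitary_vials_scan_near_null():
    """Solitary vials are generated at K=0; their best-fit K concentrates
    at the bottom of the grid."""
    config = ec.SyntheticConfig()
    obs, _, truth = ec.generate_social_density_experiment(config, seed=11)
    final = [
        o for o in obs
        if o.timepoint_h == 24 and o.group_size == 1 and o.n_eggs >= 5
    ]
    pairs = [
        (o.vial_id, ec.ClusterSizeDistribution(o.cluster_sizes, o.n_eggs))
        for o in final
    ]
    curves = ec.scan_vials(pairs, seed=12)
    best = [c.best_k for c in curves]
    assert np.median(best) <= 0.1


def test_zero_viability_yields_zero_adults():
    config = ec.SyntheticConfig(viability=0.0)
    _, via, _ = ec.generate_social_density_experiment(config, seed=1)
    assert all(v.n_adults_eclosed == 0 for v in via)


# ------------------------------------------------- existing-cluster assay

def test_existing_join_probability_extremes():
    ones = {1: 1.0, 4: 1.0, 7: 1.0, 10: 1.0}
    eggs, _ = ec.generate_existing_cluster_trials(
        ec.SyntheticConfig(join_prob=ones), seed=2
    )
    by_trial = {}
    for e in eggs:
        by_trial.setdefault(e.vial_id, []).append(e)
    for trial in by_trial.values():
        jm = ec.join_metrics(trial)
        assert jm.any_joined and jm.prop_joined == 1.0

    zeros = {1: 0.0, 4: 0.0, 7: 0.0, 10: 0.0}
    eggs, _ = ec.generate_existing_cluster_trials(
        ec.SyntheticConfig(join_prob=zeros), seed=3
    )
    by_trial = {}
    for e in eggs:
        by_trial.setdefault(e.vial_id, []).append(e)
    for trial in by_trial.values():
        jm = ec.join_metrics(trial)
        assert not jm.any_joined
        assert all(d > 0 for d in jm.distances)


def test_existing_join_ordering_recovered():
    """With join probabilities increasing from single eggs to clusters, the
    measured prop_joined means reproduce that ordering."""
    config = ec.SyntheticConfig()
    means = {s: [] for s in config.existing_sizes}
    for seed in range(5):
        eggs, truth = ec.generate_existing_cluster_trials(config, seed=400 + seed)
        by_trial = {}
        for e in eggs:
            by_trial.setdefault(e.vial_id, []).append(e)
        for vial_id, trial in by_trial.items():
            s = truth["trials"][vial_id]["existing_size"]
            means[s].append(ec.join_metrics(trial).prop_joined)
    avg = {s: np.mean(v) for s, v in means.items()}
    assert avg[1] < min(avg[4], avg[7], avg[10])


def test_existing_truth_ledger_consistent_with_metrics():
    eggs, truth = ec.generate_existing_cluster_trials(ec.SyntheticConfig(), seed=7)
    by_trial = {}
    for e in eggs:
        by_trial.setdefault(e.vial_id, []).append(e)
    for vial_id, trial in by_trial.items():
        jm = ec.join_metrics(trial)
        info = truth["trials"][vial_id]
        assert jm.n_new == info["n_new"]
        assert round(jm.prop_joined * jm.n_new) == info["n_joined"]


# ------------------------------------------------------- maternity assay

def test_maternity_mixing_recovered_within_2se():
    config = ec.SyntheticConfig()
    vals = []
    for seed in range(12):
        eggs, _ = ec.generate_maternity_experiment(config, seed=500 + seed)
        by_vial = {}
        for e in eggs:
            by_vial.setdefault(e.vial_id, []).append(e)
        for vial_eggs in by_vial.values():
            vals.append(ec.maternity_mix(vial_eggs))
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - config.mixing_prob) <= 2 * se


def test_maternity_mixing_zero_probability():
    eggs, _ = ec.generate_maternity_experiment(
        ec.SyntheticConfig(mixing_prob=0.0), seed=6
    )
    by_vial = {}
    for e in eggs:
        by_vial.setdefault(e.vial_id, []).append(e)
    for vial_eggs in by_vial.values():
        try:
            assert ec.maternity_mix(vial_eggs) == 0.0
        except ec.UndefinedMetricError:
            pass  # vials whose focal eggs all ended up singletons


def test_maternity_single_female_generation_undefined():
    eggs, _ = ec.generate_maternity_experiment(
        ec.SyntheticConfig(n_nonfocal_females=0), seed=6
    )
    assert all(e.maternity == "focal" for e in eggs)
    with pytest.raises(ec.UndefinedMetricError):
        ec.maternity_mix(eggs)


def test_generated_tables_validate_against_io_schemas(tmp_path):
    """Every generated table survives a write -> read round trip through the
    validating readers with zero warnings."""
    import warnings

    config = ec.SyntheticConfig()
    obs, via, _ = ec.generate_social_density_experiment(config, seed=21)
    eggs_ex, _ = ec.generate_existing_cluster_trials(config, seed=22)
    eggs_mat, _ = ec.generate_maternity_experiment(config, seed=23)

    ec.write_vial_table(obs, tmp_path / "vials.csv")
    ec.write_egg_table(eggs_ex + eggs_mat, tmp_path / "eggs.csv")
    ec.write_viability_table(via, tmp_path / "viability.csv")

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        obs2 = ec.read_vial_table(tmp_path / "vials.csv")
        eggs2 = ec.read_egg_table(tmp_path / "eggs.csv")
        via2 = ec.read_viability_table(tmp_path / "viability.csv")
    assert {(o.vial_id, o.timepoint_h): o.cluster_sizes for o in obs2} == {
        (o.vial_id, o.timepoint_h): o.cluster_sizes for o in obs
    }
    assert len(eggs2) == len(eggs_ex) + len(eggs_mat)
    assert len(via2) == len(via)
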