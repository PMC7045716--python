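"""ABC machinery: normalization, rejection vs sort oracle, model
choice contracts, PODs validation, robustness, estimation."""

import numpy as np
import pandas as pd
import pytest

from abcoal import LocusConfig, PriorSet
from abcoal.abc import (ABCConfig, ABCModelChoice, StatNormalizer,
                        classify_pods, compare_heterogeneity,
                        estimate_parameters, model_choice_nnet,
                        model_choice_rejection, normalize_stats, reject,
                        robustness_threshold, run_pods_validation)
from abcoal.simulate import simulate_table
from abcoal.sumstats import STAT_NAMES


def _random_table(rng, n, p=39):
    return pd.DataFrame(rng.normal(size=(n, p)), columns=list(STAT_NAMES[:p]))


# --- normalization ------------------------------------------------------

def test_reference_self_normalizes_to_zero_mean_unit_sd():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(200, 10)) * rng.uniform(0.1, 9, 10)
    refn = normalize_stats(ref)
    assert np.allclose(refn.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(refn.std(axis=0, ddof=1), 1, atol=1e-12)


def test_zero_variance_column_dropped_from_distance():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(100, 5))
    ref[:, 2] = 7.0
    norm = StatNormalizer(ref)
    assert norm.transform(ref).shape[1] == 4


def test_mad_normalization_option():
    rng = np.random.default_rng(20)
    ref = rng.normal(size=(200, 6))
    norm = StatNormalizer(ref, scale="mad")
    out = norm.transform(ref)
    assert np.allclose(np.median(out, axis=0), 0, atol=1e-12)
    assert np.allclose(np.median(np.abs(out), axis=0), 1, atol=1e-12)
    with pytest.raises(ValueError, match="'sd' or 'mad'"):
        StatNormalizer(ref, scale="robust")


def test_distance_ranking_invariant_to_affine_rescaling():
    rng = np.random.default_rng(2)
    tab = _random_table(rng, 500)
    obs = rng.normal(size=39)
    acc0, _ = reject(obs, tab, 0.05)
    scaled = tab.copy()
    obs2 = obs.copy()
    for j in rng.integers(0, 39, size=5):
        a, b = rng.uniform(0.1, 10), rng.normal()
        scaled.iloc[:, j] = scaled.iloc[:, j] * a + b
        obs2[j] = obs2[j] * a + b
    acc1, _ = reject(obs2, scaled, 0.05)
    assert np.array_equal(acc0, acc1)


# --- rejection ----------------------------------------------------------

def test_rejection_count_is_ceiling_of_fraction():
    rng = np.random.default_rng(3)
    tab = _random_table(rng, 1000)
    acc, _ = reject(rng.normal(size=39), tab, 0.01)
    assert len(acc) == 10


def test_observation_equal_to_a_row_is_accepted_first():
    rng = np.random.default_rng(4)
    tab = _random_table(rng, 300)
    acc, dist = reject(tab.iloc[123], tab, 1 / 300)
    assert acc[0] == 123
    assert dist[123] == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_rejection_equals_full_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    tab = _random_table(rng, 400)
    obs = rng.normal(size=39)
    acc, dist = reject(obs, tab, 0.05)
    oracle = np.lexsort((np.arange(dist.size), dist))[:len(acc)]
    assert np.array_equal(acc, oracle)


# --- model choice -------------------------------------------------------

def test_identical_tables_split_probability_evenly():
    rng = np.random.default_rng(5)
    tab = _random_table(rng, 500)
    res = model_choice_rejection(rng.normal(size=39),
                                 {"a": tab, "b": tab.copy()}, 0.02)
    assert res.probabilities["a"] == pytest.approx(0.5)
    assert res.probabilities.sum() == pytest.approx(1.0)


def test_all_accepted_from_one_model_gives_probability_one():
    rng = np.random.default_rng(6)
    near = _random_table(rng, 200)
    far = _random_table(rng, 200) + 50.0
    obs = np.zeros(39)
    for method in ("rejection", "neuralnet"):
        res = ABCModelChoice(obs, {"near": near, "far": far}).fit(
            ABCConfig(tolerance=0.05, method=method),
            rng=np.random.default_rng(0))
        assert res.best_model == "near"
        assert res.probabilities["near"] > 0.99
        assert res.probabilities.sum() == pytest.approx(1.0)
    # all-one-label accepted set triggers the documented nnet fallback
    res = ABCModelChoice(obs, {"near": near, "far": far}).fit(
        ABCConfig(tolerance=0.05, method="neuralnet"))
    assert res.fallback


def test_rejection_probabilities_invariant_to_table_order():
    rng = np.random.default_rng(7)
    t1, t2 = _random_table(rng, 300), _random_table(rng, 300)
    obs = rng.normal(size=39)
    r1 = model_choice_rejection(obs, {"a": t1, "b": t2}, 0.05)
    r2 = model_choice_rejection(obs, {"b": t2, "a": t1}, 0.05)
    assert r1.probabilities["a"] == pytest.approx(r2.probabilities["a"])


@pytest.fixture(scope="module")
def separable_problem():
    """pan vs deep div: cleanly separated statistic distributions."""
    rng = np.random.default_rng(11)
    cfg = LocusConfig(nA=8, nB=8)
    priors_pan = PriorSet()
    priors_div = PriorSet(Tdiv_range=(8e5, 1e6))
    tables = {"pan": simulate_table("pan", priors_pan, 1000, 25, cfg, rng),
              "div": simulate_table("div", priors_div, 1000, 25, cfg, rng)}
    pods = pd.concat([
        simulate_table("pan", priors_pan, 50, 25, cfg, rng),
        simulate_table("div", priors_div, 50, 25, cfg, rng),
    ], ignore_index=True)
    return tables, pods


def test_nnet_concordant_with_rejection_when_separated(separable_problem):
    tables, pods = separable_problem
    rng = np.random.default_rng(0)
    agree = 0
    for i in range(100):
        obs = pods.iloc[i]
        rej = model_choice_rejection(obs, tables, 0.01)
        nn = model_choice_nnet(obs, tables, 0.01,
                               ABCConfig(n_net_replicates=3), rng)
        assert nn.probabilities.sum() == pytest.approx(1.0)
        agree += rej.best_model == nn.best_model
    assert agree >= 95


def test_pods_validation_on_separable_models(separable_problem):
    tables, pods = separable_problem
    res = classify_pods(pods, tables,
                        ABCConfig(tolerance=0.01, method="rejection"))
    assert res.confusion.to_numpy().sum(axis=1).tolist() == [50, 50]
    assert (res.precision >= 0.95).all()
    assert ((res.precision >= 0) & (res.precision <= 1)).all()


def test_isolation_data_rejects_migration_models():
    """Datasets generated under strict divergence should not hand the
    ongoing-migration model high posterior probability."""
    from abcoal.synth import generate_observed
    rng = np.random.default_rng(15)
    cfg = LocusConfig(nA=8, nB=8)
    priors = PriorSet(Tdiv_range=(2e5, 1e6))
    tables = {m: simulate_table(m, priors, 1500, 30, cfg, rng)
              for m in ("div", "im")}
    im_probs = []
    for seed in range(15):
        _, obs, _ = generate_observed("div", priors, 30, cfg, seed=seed)
        res = model_choice_rejection(obs, tables, 0.01)
        im_probs.append(res.probabilities["im"])
    assert np.mean(im_probs) < 0.5
    assert np.median(im_probs) < 0.35


def test_zero_pods_yield_empty_confusion(locus_cfg):
    res = run_pods_validation(["pan", "div"], PriorSet(), 0, 5, locus_cfg,
                              np.random.default_rng(0), n_sims=10)
    assert res.confusion.to_numpy().sum() == 0
    assert len(res.records) == 0


# --- robustness threshold ----------------------------------------------

def _records(rows, called="X"):
    df = pd.DataFrame(rows, columns=["true_model", "prob_X"])
    # every record here represents a POD called as the focal model
    df["selected"] = called
    return df


def test_perfect_classification_gives_zero_threshold():
    rec = pd.DataFrame({"true_model": ["X"] * 20 + ["Y"] * 20,
                        "prob_X": [1.0] * 20 + [0.0] * 20,
                        "selected": ["X"] * 20 + ["Y"] * 20})
    assert robustness_threshold(rec, "X", 0.95) == 0.0


def test_threshold_lands_just_above_the_impostors():
    # impostor PODs (true Y) are also called X, at probability 0.6
    rec = _records([("X", 0.9)] * 50 + [("Y", 0.6)] * 50)
    thr = robustness_threshold(rec, "X", 0.95)
    assert 0.60 < thr <= 0.9
    assert thr == pytest.approx(0.61)


def test_threshold_nondecreasing_in_target():
    rng = np.random.default_rng(8)
    rows = [("X", p) for p in rng.uniform(0.5, 1.0, 200)] + \
           [("Y", p) for p in rng.uniform(0.0, 0.9, 200)]
    rec = _records(rows)
    last = 0.0
    for target in (0.5, 0.7, 0.9, 0.95):
        thr = robustness_threshold(rec, "X", target)
        if thr is None:
            break
        assert thr >= last
        last = thr


def test_unattainable_target_returns_none():
    rec = _records([("Y", 0.99)] * 10 + [("X", 0.01)] * 10)
    assert robustness_threshold(rec, "X", 0.95) is None


# --- heterogeneity comparison ------------------------------------------

def test_identical_variant_tables_give_uniform_probabilities():
    rng = np.random.default_rng(9)
    tab = _random_table(rng, 300)
    tabs = {f"v{i}": tab.copy() for i in range(4)}
    res = compare_heterogeneity(rng.normal(size=39), tabs,
                                ABCConfig(tolerance=0.05,
                                          method="rejection"))
    assert np.allclose(res.probabilities, 0.25, atol=0.15)
    assert res.cumulative(["v0", "v1"]) == pytest.approx(
        res.probabilities["v0"] + res.probabilities["v1"])


def test_hetero_variants_builds_the_full_grid():
    from abcoal.abc import hetero_variants
    variants = hetero_variants(PriorSet())
    assert len(variants) == 9
    assert variants["Ne-hetero2_m-homo"].heterogeneity_Ne == "hetero2"
    assert variants["Ne-hetero2_m-homo"].heterogeneity_m == "homo"


def test_homogeneous_data_prefers_homogeneous_variant():
    """Self-consistency: data simulated without among-locus
    heterogeneity should mostly pick an Ne-homogeneous variant."""
    rng = np.random.default_rng(10)
    cfg = LocusConfig(nA=8, nB=8)
    base = PriorSet(Tdiv_range=(2e5, 1e6))
    variants = {
        "Ne-homo_m-homo": base,
        "Ne-hetero1_m-homo": PriorSet(Tdiv_range=(2e5, 1e6),
                                      heterogeneity_Ne="hetero1"),
        "Ne-hetero2_m-homo": PriorSet(Tdiv_range=(2e5, 1e6),
                                      heterogeneity_Ne="hetero2"),
    }
    tabs = {name: simulate_table("div", pri, 1500, 40, cfg, rng)
            for name, pri in variants.items()}
    obs_tab = simulate_table("div", base, 50, 40, cfg, rng)
    wins = 0
    for i in range(50):
        res = compare_heterogeneity(obs_tab.iloc[i], tabs,
                                    ABCConfig(tolerance=0.02,
                                              method="rejection"))
        wins += res.best_model == "Ne-homo_m-homo"
    assert wins >= 30  # plurality in >= 60% of trials


# --- parameter estimation ----------------------------------------------

def test_constant_parameter_collapses_posterior():
    rng = np.random.default_rng(12)
    tab = _random_table(rng, 300)
    tab["Tdiv"] = 42.0
    res = estimate_parameters(rng.normal(size=39), tab, 0.1, "none",
                              params=["Tdiv"])
    post = res["Tdiv"]
    assert post.mode == 42.0
    assert post.ci95 == (42.0, 42.0)
    assert post.mode_years() == 84.0


def test_adjustment_falls_back_when_accepted_set_too_small():
    rng = np.random.default_rng(13)
    tab = _random_table(rng, 300)
    tab["Tdiv"] = rng.uniform(1e4, 1e6, 300)
    res = estimate_parameters(rng.normal(size=39), tab, 0.05, "loclinear",
                              params=["Tdiv"])
    # 15 accepted < 39 statistics: regression would interpolate
    assert res.adjustment == "none"
    assert not res["Tdiv"].adjusted
    lo, hi = res["Tdiv"].ci95
    assert lo < res["Tdiv"].mode < hi


def test_loclinear_adjusts_with_enough_accepted_rows():
    rng = np.random.default_rng(14)
    tab = _random_table(rng, 2000)
    # parameter linearly tied to the statistics plus noise
    tab["Tdiv"] = np.exp(8 + 0.3 * tab["mean_piA"] +
                         0.05 * rng.normal(size=2000))
    obs = rng.normal(size=39)
    res = estimate_parameters(obs, tab, 0.1, "loclinear", params=["Tdiv"])
    assert res.adjustment == "loclinear"
    assert res["Tdiv"].adjusted
    # adjustment sharpens the posterior around the regression prediction
    raw = estimate_parameters(obs, tab, 0.1, "none", params=["Tdiv"])
    width_adj = res["Tdiv"].ci95[1] - res["Tdiv"].ci95[0]
    width_raw = raw["Tdiv"].ci95[1] - raw["Tdiv"].ci95[0]
    assert width_adj < width_raw
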