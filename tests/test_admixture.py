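"""f3 admixture statistic, block jackknife, NJ trees and topology
weighting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from abcoal.admixture import (F3Test, SnpFrequencyTable, block_jackknife,
                              distance_matrix, f3, f3_values, nj_tree,
                              topology_weights, tree_length)
from abcoal.synth import AdmixtureScenario, generate_admixture_scenario


def _table(freqs: dict, n=20):
    freq = pd.DataFrame(freqs)
    size = pd.DataFrame(n, index=freq.index, columns=freq.columns)
    return SnpFrequencyTable(freq, size)


# --- f3 -----------------------------------------------------------------

def test_f3_zero_when_target_equals_a_source():
    rng = np.random.default_rng(0)
    a = rng.uniform(0.1, 0.9, 300)
    tab = _table({"a": a, "b": rng.uniform(0.1, 0.9, 300), "c": a})
    res = f3(tab, target="c", source1="a", source2="b")
    assert res.f3 == pytest.approx(0.0, abs=1e-15)


def test_f3_fixture_minus_quarter():
    n = 250
    tab = _table({"a": np.ones(n), "b": np.zeros(n), "c": np.full(n, 0.5)})
    res = f3(tab, "c", "a", "b")
    assert res.f3 == pytest.approx(-0.25)


def test_f3_symmetric_in_sources_and_linear_in_snps():
    rng = np.random.default_rng(1)
    tab = _table({p: rng.uniform(0, 1, 400) for p in ("a", "b", "c")})
    v1 = f3_values(tab, "c", "a", "b")
    v2 = f3_values(tab, "c", "b", "a")
    assert np.allclose(v1, v2)
    assert f3(tab, "c", "a", "b").f3 == pytest.approx(v1.mean())


def test_f3_correction_subtracts_target_heterozygosity_term():
    rng = np.random.default_rng(2)
    tab = _table({p: rng.uniform(0.1, 0.9, 200) for p in ("a", "b", "c")},
                 n=10)
    raw = f3_values(tab, "c", "a", "b", corrected=False)
    cor = f3_values(tab, "c", "a", "b", corrected=True)
    c = tab.freq["c"].to_numpy()
    assert np.allclose(raw - cor, c * (1 - c) / 9)


def test_f3_missing_population_raises():
    tab = _table({"a": [0.5] * 200, "b": [0.5] * 200, "c": [0.5] * 200})
    with pytest.raises(ValueError, match="not in table"):
        f3(tab, "z", "a", "b")


# --- block jackknife ----------------------------------------------------

def test_jackknife_estimate_is_plain_mean_for_any_block_size():
    rng = np.random.default_rng(3)
    x = rng.normal(size=537)
    for B in (50, 100, 150):
        est, se, _ = block_jackknife(x, B)
        assert est == pytest.approx(x.mean())
        assert se >= 0


def test_jackknife_constant_values_flag_infinite_z():
    est, se, z = block_jackknife(np.full(300, 2.5), 100)
    assert se == 0.0
    assert z == np.inf
    est, se, z = block_jackknife(np.zeros(300), 100)
    assert z == 0.0


def test_jackknife_needs_two_blocks():
    with pytest.raises(ValueError, match="2 complete blocks"):
        block_jackknife(np.ones(150), 100)


def test_jackknife_se_tracks_sampling_theory():
    """For i.i.d. values the jackknife SE approximates s/sqrt(n)."""
    rng = np.random.default_rng(4)
    ratios = []
    for _ in range(1000):
        x = rng.normal(size=500)
        _, se, _ = block_jackknife(x, 100)
        ratios.append(se / (x.std(ddof=1) / np.sqrt(500)))
    assert abs(np.mean(ratios) - 1) < 0.3


# --- synthetic admixture scenarios -------------------------------------

def test_synthetic_alpha_half_admixture_is_detected():
    tab, truth = generate_admixture_scenario(
        AdmixtureScenario(alpha=0.5, F=0.05, n_snps=10_000), seed=5)
    res = F3Test(tab, "target", "src1", "src2").fit()
    assert res.f3 < 0
    assert res.z <= -3.8
    assert res.significant


@pytest.mark.parametrize("alpha", [0.2, 0.8])
def test_intermediate_admixture_fractions_detected(alpha):
    tab, _ = generate_admixture_scenario(
        AdmixtureScenario(alpha=alpha, F=0.05, n_snps=10_000), seed=6)
    assert F3Test(tab, "target", "src1", "src2").fit().significant


@pytest.mark.parametrize("alpha,seed", [(0.0, s) for s in range(5)]
                         + [(1.0, s) for s in range(5)])
def test_unadmixed_targets_not_called_significant(alpha, seed):
    tab, _ = generate_admixture_scenario(
        AdmixtureScenario(alpha=alpha, F=0.05, n_snps=5_000), seed=seed)
    res = F3Test(tab, "target", "src1", "src2").fit()
    assert res.f3 >= 0 or res.z > -3.8
    assert not res.significant


def test_frequencies_always_in_unit_interval():
    tab, _ = generate_admixture_scenario(
        AdmixtureScenario(alpha=0.3, F=0.3, n_snps=2_000), seed=7)
    f = tab.freq.to_numpy()
    assert np.all((f >= 0) & (f <= 1))


# --- distances and NJ ---------------------------------------------------

# reference distances computed with ape::dist.dna on the same sequences
_APE_SEQS = {"a": "ACGTACGTAATTGGCCAAGGTTCCAAGT",
             "b": "ACGAACGTATTTGGACAAGGATCCAAGA",
             "c": "TCGAACGACCTTGACCAAGCTTCCTAGT"}
_APE_F84 = {("a", "b"): 0.209120328769, ("a", "c"): 0.368004118774,
            ("b", "c"): 0.493058070949}
_APE_JC69 = {("a", "b"): 0.203950286613, ("a", "c"): 0.359679810196,
             ("b", "c"): 0.484970373694}


@pytest.mark.parametrize("model,expected", [("F84", _APE_F84),
                                            ("JC69", _APE_JC69)])
def test_distances_match_ape(model, expected):
    dm = distance_matrix(_APE_SEQS, model)
    for (i, j), d in expected.items():
        assert dm[i, j] == pytest.approx(d, abs=1e-9)


def test_three_taxon_tree_solves_three_point_equations():
    tree = nj_tree(_APE_SEQS, model="F84")
    dist = {}
    for i, j in itertools.combinations("abc", 2):
        dist[(i, j)] = tree.find(i).distance(tree.find(j))
    for pair, d in _APE_F84.items():
        assert dist[pair] == pytest.approx(d, abs=1e-9)


def test_nj_recovers_additive_five_taxon_matrix():
    """NJ is exact on additive distances: the tree's path lengths must
    reproduce the input matrix."""
    nwk = "((a:0.10,b:0.20):0.05,(c:0.15,d:0.25):0.10,e:0.30);"
    src = TreeNode.read([nwk])
    ids = ["a", "b", "c", "d", "e"]
    m = np.zeros((5, 5))
    for i, j in itertools.combinations(range(5), 2):
        d = src.find(ids[i]).distance(src.find(ids[j]))
        m[i, j] = m[j, i] = d
    from skbio.tree import nj as sk_nj
    tree = sk_nj(DistanceMatrix(m, ids))
    for i, j in itertools.combinations(range(5), 2):
        got = tree.find(ids[i]).distance(tree.find(ids[j]))
        assert got == pytest.approx(m[i, j], abs=1e-9)


def test_identical_sequences_give_zero_length_star():
    seqs = {f"t{i}": "ACGTACGTACGT" for i in range(4)}
    tree = nj_tree(seqs, model="JC69")
    assert tree_length(tree) == pytest.approx(0.0, abs=1e-12)


def test_saturated_distance_raises():
    with pytest.raises(ValueError, match="saturated"):
        distance_matrix({"a": "AAAA", "b": "CCCC", "c": "AAAA"},
                        model="JC69")


# --- topology weighting -------------------------------------------------

def _sorted_tree():
    return TreeNode.read([
        "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,((c1:1,c2:1):1,(d1:1,d2:1):1):1);"
    ])


GROUPS = {f"{g}{i}": g.upper() for g in "abcd" for i in (1, 2)}


def test_reciprocally_monophyletic_groups_weight_one():
    tw = topology_weights(_sorted_tree(), GROUPS, min_tree_length=0.0)
    assert tw.weights["(A,B|C,D)"] == pytest.approx(1.0)
    assert sum(tw.weights.values()) == pytest.approx(1.0)
    assert tw.retained


def test_tree_length_filter_marks_short_trees():
    tw = topology_weights(_sorted_tree(), GROUPS, min_tree_length=1e6)
    assert not tw.retained


def _brute_force_weights(tree, group_map):
    """Independent oracle: shear each quartet and read its bipartition."""
    groups = sorted(set(group_map.values()))
    tips = {g: [t.name for t in tree.tips() if group_map[t.name] == g]
            for g in groups}
    counts = dict.fromkeys(range(3), 0)
    total = 0
    for combo in itertools.product(*(tips[g] for g in groups)):
        sub = tree.shear(list(combo))
        a, b, c, d = combo
        # find the pairing: which of b, c, d shares a cherry with a?
        pair = None
        for node in sub.non_tips(include_self=True):
            names = {t.name for t in node.tips()}
            if len(names) == 2:
                pair = names
                break
        assert pair is not None
        if pair in ({a, b}, {c, d}):
            counts[0] += 1
        elif pair in ({a, c}, {b, d}):
            counts[1] += 1
        else:
            counts[2] += 1
        total += 1
    return np.array([counts[i] / total for i in range(3)])


@pytest.mark.parametrize("seed", range(3))
def test_weights_match_exhaustive_shear_oracle(seed):
    rng = np.random.default_rng(seed)
    names = [f"{g}{i}" for g in "abcd" for i in range(1, 4)]
    rng.shuffle(names)
    # random binary tree over 12 tips
    nodes = [TreeNode(name=n, length=float(rng.uniform(0.1, 1)))
             for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))[::-1]
        a, b = nodes.pop(i), nodes.pop(j)
        parent = TreeNode(length=float(rng.uniform(0.1, 1)), children=[a, b])
        nodes.append(parent)
    tree = TreeNode(children=nodes)
    gm = {n: n[0].upper() for n in names}
    tw = topology_weights(tree, gm, min_tree_length=0.0)
    got = np.array(list(tw.weights.values()))
    assert got == pytest.approx(_brute_force_weights(tree, gm))


def test_weights_invariant_to_relabeling_within_group():
    tree = _sorted_tree()
    tw1 = topology_weights(tree, GROUPS, min_tree_length=0.0)
    swapped = dict(GROUPS)
    # swapping tips within a group must not change anything
    swapped["a1"], swapped["a2"] = swapped["a2"], swapped["a1"]
    tw2 = topology_weights(tree, swapped, min_tree_length=0.0)
    assert tw1.weights == tw2.weights


def test_missing_group_raises():
    gm = dict(GROUPS)
    for k in list(gm):
        if gm[k] == "D":
            gm[k] = "C"
    with pytest.raises(ValueError, match="4 groups"):
        topology_weights(_sorted_tree(), gm)
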