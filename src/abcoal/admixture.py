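"""Three-population f3 admixture test and gene-tree topology weighting.

The f3 statistic for a target population C and sources A, B is the
mean over SNPs of ``(c - a)(c - b)`` where a, b, c are sample allele
frequencies.  Without admixture its expectation is non-negative
(genetic drift along C's own branch); a significantly negative value
indicates C is a mixture of sources related to A and B.  Significance
uses a block jackknife over consecutive 100-SNP windows, calling
admixture when z <= -3.8 (p < 1e-4).  An optional finite-sample
correction subtracts ``c(1-c)/(n_c - 1)`` per SNP; it is OFF by
default, matching the common threepop convention.

Topology weighting quantifies, per locus, how much of the gene tree
supports each of the three unrooted topologies of four taxon groups:
every combination of one tip per group induces a four-tip subtree
matching exactly one topology, and the weight is the matching
fraction.  Locus trees are built by neighbour joining on JC69 or F84
distances; poorly resolved trees (total length below 0.025, i.e. less
than ~5 substitutions per 200 bp) are flagged as not retained.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

Z_SIGNIFICANCE = -3.8
DEFAULT_BLOCK = 100
MIN_TREE_LENGTH = 0.025


@dataclass
class SnpFrequencyTable:
    """Derived-allele sample frequencies and haploid counts per SNP.

    ``freq`` and ``size`` are (n_snps x populations) DataFrames with a
    shared column set; SNP (row) order defines the jackknife blocks.
    """

    freq: pd.DataFrame
    size: pd.DataFrame

    def __post_init__(self):
        if list(self.freq.columns) != list(self.size.columns):
            raise ValueError("freq and size must share the same populations")
        if self.freq.shape != self.size.shape:
            raise ValueError("freq and size must have the same shape")
        f = self.freq.to_numpy(dtype=float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.size.to_numpy(dtype=float) < 1):
            raise ValueError("haploid counts must be >= 1")

    @property
    def populations(self):
        return list(self.freq.columns)

    @property
    def n_snps(self) -> int:
        return self.freq.shape[0]


def block_jackknife(values: np.ndarray, B: int = DEFAULT_BLOCK):
    """Delete-one-block jackknife of the mean over consecutive blocks.

    SNPs are partitioned into consecutive blocks of ``B``; a final
    partial block is merged into the previous one.  Returns
    ``(estimate, SE, z)`` where the estimate is the plain mean.  With
    zero jackknife variance the z-score is an infinite sentinel
    (sign of the estimate).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if B < 1:
        raise ValueError("block size must be >= 1")
    n_blocks = n // B
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks")
    bounds = [i * B for i in range(n_blocks)] + [n]  # last block absorbs rest
    total = x.sum()
    est = total / n
    loo = np.empty(n_blocks)
    for i in range(n_blocks):
        lo, hi = bounds[i], bounds[i + 1]
        loo[i] = (total - x[lo:hi].sum()) / (n - (hi - lo))
    se = math.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum())
    if se > 0:
        z = est / se
    else:
        z = math.copysign(math.inf, est) if est != 0 else 0.0
    return est, se, z


@dataclass
class F3Result:
    """f3 estimate with block-jackknife uncertainty."""

    f3: float
    se: float
    z: float
    n_snps: int
    n_blocks: int
    target: str
    sources: tuple
    corrected: bool

    @property
    def significant(self) -> bool:
        """Admixture call: negative f3 with z <= -3.8."""
        return self.f3 < 0 and self.z <= Z_SIGNIFICANCE

    def summary(self) -> str:
        return (f"f3({self.target}; {self.sources[0]}, {self.sources[1]})"
                f" = {self.f3:.6g}   SE = {self.se:.3g}   z = {self.z:.2f}\n"
                f"  {self.n_snps} SNPs in {self.n_blocks} jackknife blocks"
                f"{'   (finite-sample corrected)' if self.corrected else ''}\n"
                f"  admixture {'DETECTED' if self.significant else 'not detected'}"
                f" (rule: f3 < 0 and z <= {Z_SIGNIFICANCE})")


def f3_values(table: SnpFrequencyTable, target: str, source1: str,
              source2: str, corrected: bool = False) -> np.ndarray:
    """Per-SNP contributions (c-a)(c-b), optionally bias-corrected."""
    for pop in (target, source1, source2):
        if pop not in table.freq.columns:
            raise ValueError(f"population {pop!r} not in table")
    c = table.freq[target].to_numpy(dtype=float)
    a = table.freq[source1].to_numpy(dtype=float)
    b = table.freq[source2].to_numpy(dtype=float)
    vals = (c - a) * (c - b)
    if corrected:
        nc = table.size[target].to_numpy(dtype=float)
        if np.any(nc < 2):
            raise ValueError("finite-sample correction needs n_target >= 2")
        vals = vals - c * (1.0 - c) / (nc - 1.0)
    return vals


def f3(table: SnpFrequencyTable, target: str, source1: str, source2: str,
       corrected: bool = False, block_size: int = DEFAULT_BLOCK) -> F3Result:
    """Three-population test of admixture with block-jackknife SE."""
    vals = f3_values(table, target, source1, source2, corrected)
    if vals.size == 0:
        raise ValueError("no SNPs in table")
    est, se, z = block_jackknife(vals, block_size)
    return F3Result(est, se, z, vals.size, vals.size // block_size,
                    target, (source1, source2), corrected)


class F3Test:
    """Model-style wrapper: build from a table, ``fit`` runs the test."""

    def __init__(self, table: SnpFrequencyTable, target: str,
                 source1: str, source2: str):
        self.table = table
        self.target = target
        self.sources = (source1, source2)

    def fit(self, block_size: int = DEFAULT_BLOCK,
            corrected: bool = False) -> F3Result:
        return f3(self.table, self.target, *self.sources,
                  corrected=corrected, block_size=block_size)


# ---------------------------------------------------------------------------
# locus trees: pairwise distances and neighbour joining

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pair_counts(s1: np.ndarray, s2: np.ndarray):
    """(#compared, P transitions, Q transversions) between two sequences."""
    valid = (s1 >= 0) & (s2 >= 0)
    n = int(valid.sum())
    d = valid & (s1 != s2)
    # transitions: A<->G (0,2), C<->T (1,3): same parity
    ts = int((d & ((s1 % 2) == (s2 % 2))).sum())
    return n, ts, int(d.sum()) - ts


def _encode(seqs: Mapping[str, str]):
    names = list(seqs.keys())
    L = len(next(iter(seqs.values())))
    enc = np.full((len(names), L), -1, dtype=np.int8)
    for i, name in enumerate(names):
        s = seqs[name].upper()
        if len(s) != L:
            raise ValueError("sequences must have equal length")
        for j, ch in enumerate(s):
            enc[i, j] = _BASES.get(ch, -1)
    return names, enc


def jc69_distance(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise ValueError("saturated distance (JC69 undefined)")
    return -0.75 * math.log(arg)


def f84_distance(P: float, Q: float, freqs: np.ndarray) -> float:
    """Felsenstein (1984) distance from transition/transversion
    proportions and base frequencies (A, C, G, T)."""
    pa, pc, pg, pt = freqs
    pr = pa + pg
    py = pc + pt
    A = pa * pg / pr + pc * pt / py
    B = pa * pg + pc * pt
    C = pr * py
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        raise ValueError("saturated distance (F84 undefined)")
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


def distance_matrix(seqs: Mapping[str, str],
                    model: str = "F84") -> DistanceMatrix:
    """Pairwise JC69 or F84 distances; F84 base frequencies are taken
    from the pooled alignment.  Raises on saturated pairs."""
    if model not in ("JC69", "F84"):
        raise ValueError("model must be 'JC69' or 'F84'")
    names, enc = _encode(seqs)
    if model == "F84":
        counts = np.array([(enc == b).sum() for b in range(4)], dtype=float)
        if counts.sum() == 0:
            raise ValueError("alignment has no unambiguous bases")
        freqs = counts / counts.sum()
        if np.any(freqs == 0):
            # degenerate composition: fall back to uniform frequencies
            freqs = np.full(4, 0.25)
    m = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        n, ts, tv = _pair_counts(enc[i], enc[j])
        if n == 0:
            raise ValueError(f"no comparable sites between {names[i]} "
                             f"and {names[j]}")
        if model == "JC69":
            d = jc69_distance((ts + tv) / n)
        else:
            d = f84_distance(ts / n, tv / n, freqs)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids=names)


def nj_tree(seqs: Mapping[str, str], model: str = "F84") -> TreeNode:
    """Neighbour-joining locus tree with negative lengths clamped to 0.

    Three taxa yield the unique unrooted topology with lengths solving
    the three-point equations; >= 4 taxa use Saitou-Nei NJ on the
    pairwise distance matrix.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    dm = distance_matrix(seqs, model)
    if len(seqs) == 3:
        a, b, c = dm.ids
        d_ab, d_ac, d_bc = dm[a, b], dm[a, c], dm[b, c]
        la = max(0.0, (d_ab + d_ac - d_bc) / 2)
        lb = max(0.0, (d_ab + d_bc - d_ac) / 2)
        lc = max(0.0, (d_ac + d_bc - d_ab) / 2)
        return TreeNode.read(
            [f"({a}:{la:.10g},{b}:{lb:.10g},{c}:{lc:.10g});"])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_length(tree: TreeNode) -> float:
    """Sum of branch lengths."""
    return sum(n.length or 0.0 for n in tree.traverse() if not n.is_root())


# ---------------------------------------------------------------------------
# topology weighting

@dataclass
class TopologyWeights:
    """Per-locus weights of the three unrooted 4-group topologies."""

    weights: Dict[str, float]
    tree_length: float
    retained: bool
    locus_id: str = "locus"

    def as_dict(self) -> Dict[str, float]:
        return dict(self.weights)


def _topology_labels(groups: Sequence[str]):
    g1, g2, g3, g4 = groups
    return (f"({g1},{g2}|{g3},{g4})",
            f"({g1},{g3}|{g2},{g4})",
            f"({g1},{g4}|{g2},{g3})")


def topology_weights(tree: TreeNode, group_map: Mapping[str, str],
                     min_tree_length: float = MIN_TREE_LENGTH,
                     locus_id: str = "locus",
                     max_combinations: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None
                     ) -> TopologyWeights:
    """Exhaustive topology weighting of one locus tree.

    Every one-tip-per-group combination induces a four-tip unrooted
    subtree; on a binary tree the induced quartet matches exactly one
    of the three topologies, identified by the smallest of the three
    topological distance sums (four-point condition on edge counts).
    ``max_combinations`` switches to seeded random sampling of
    combinations for very large trees.
    """
    groups = sorted(set(group_map.values()))
    if len(groups) != 4:
        raise ValueError("topology weighting needs exactly 4 groups")
    tips = {g: [] for g in groups}
    tip_names = []
    for tip in tree.tips():
        if tip.name not in group_map:
            raise ValueError(f"tip {tip.name!r} missing from group map")
        tips[group_map[tip.name]].append(tip.name)
        tip_names.append(tip.name)
    for g, members in tips.items():
        if not members:
            raise ValueError(f"group {g!r} has no tips in the tree")
    # topological (edge-count) distances between all tips
    topo = tree.copy()
    for node in topo.traverse():
        node.length = 1.0
    D = topo.tip_tip_distances()
    idx = {name: i for i, name in enumerate(D.ids)}
    dmat = D.data

    labels = _topology_labels(groups)
    counts = np.zeros(3)
    combos = itertools.product(*(tips[g] for g in groups))
    n_total = int(np.prod([len(tips[g]) for g in groups]))
    if max_combinations is not None and n_total > max_combinations:
        rng = np.random.default_rng(0) if rng is None else rng
        combos = ((tips[g][rng.integers(len(tips[g]))] for g in groups)
                  for _ in range(max_combinations))
        n_total = max_combinations
    for combo in combos:
        a, b, c, d = (idx[t] for t in combo)
        s = (dmat[a, b] + dmat[c, d],
             dmat[a, c] + dmat[b, d],
             dmat[a, d] + dmat[b, c])
        counts[int(np.argmin(s))] += 1
    weights = dict(zip(labels, counts / n_total))
    tl = tree_length(tree)
    return TopologyWeights(weights, tl, tl >= min_tree_length, locus_id)


class TopologyWeighting:
    """Weight many locus trees against one 4-group assignment."""

    def __init__(self, trees: Mapping[str, TreeNode],
                 group_map: Mapping[str, str]):
        self.trees = dict(trees)
        self.group_map = dict(group_map)

    def fit(self, min_tree_length: float = MIN_TREE_LENGTH,
            max_combinations: Optional[int] = None,
            rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
        rows = []
        for locus_id, tree in self.trees.items():
            tw = topology_weights(tree, self.group_map, min_tree_length,
                                  locus_id, max_combinations, rng)
            row = {"locus": locus_id, "tree_length": tw.tree_length,
                   "retained": tw.retained}
            row.update(tw.weights)
            rows.append(row)
        return pd.DataFrame(rows).set_index("locus")
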