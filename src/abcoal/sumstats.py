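"""Per-locus polymorphism/divergence statistics and the 39-element
summary vector used for ABC.

Per locus, 16 statistics are computed from the binary haplotype matrix:
site-class counts (biallelic sites, fixed differences, private
polymorphisms per population, shared polymorphisms), Tajima's pi and
Watterson's theta per population, Tajima's D per population, absolute
divergence dxy and net divergence Da = dxy - (piA+piB)/2, the min and
max cross-population pairwise difference counts, and Hudson's
FST = 1 - mean-within / between.  pi and dxy are per-locus sums over
sites (a per-bp toggle is available for reporting).

Across loci the summary vector is the mean and SD of each of the 16
(32 values) plus 7 across-locus Pearson correlations, for 39 values in
a fixed name order.  Undefined quantities (FST with dxy = 0, Tajima's D
with S = 0, correlations with zero variance) are recorded as 0; the
rule is applied identically to simulated and observed data so that ABC
distances remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import _engine
from ._engine import N_LOCUS_STATS, N_SUMSTATS
from .containers import HaplotypeMatrix

LOCUS_STAT_NAMES = (
    "bialsites", "sf", "sxA", "sxB", "ss",
    "piA", "piB", "thetaWA", "thetaWB", "DtajA", "DtajB",
    "divAB", "netdivAB", "minDivAB", "maxDivAB", "FST",
)

_CORR_NAMES = (
    "cor_piA_piB", "cor_thetaWA_thetaWB", "cor_DtajA_DtajB",
    "cor_divAB_netdivAB", "cor_FST_divAB", "cor_piA_divAB", "cor_piB_divAB",
)

#: fixed name order of the 39-element summary-statistic vector
STAT_NAMES = tuple(f"mean_{s}" for s in LOCUS_STAT_NAMES) + \
    tuple(f"sd_{s}" for s in LOCUS_STAT_NAMES) + _CORR_NAMES

assert len(STAT_NAMES) == N_SUMSTATS


@dataclass(frozen=True)
class LocusStats:
    bialsites: float
    sf: float
    sxA: float
    sxB: float
    ss: float
    piA: float
    piB: float
    thetaWA: float
    thetaWB: float
    DtajA: float
    DtajB: float
    divAB: float
    netdivAB: float
    minDivAB: float
    maxDivAB: float
    FST: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, arr) -> "LocusStats":
        return cls(*(float(x) for x in arr))


def locus_stats(H: HaplotypeMatrix) -> LocusStats:
    """All 16 per-locus statistics from one haplotype matrix."""
    if H.nA < 2 or H.nB < 2:
        raise ValueError("need >= 2 haplotypes per population")
    out = np.empty(N_LOCUS_STATS)
    _engine._stats16(H.site_masks(), H.nA, H.nB, out)
    return LocusStats.from_array(out)


def tajimas_D(S: int, pi: float, n: int) -> float:
    """Tajima's D from the segregating-site count, mean pairwise
    difference and haploid sample size; 0 when undefined (S = 0)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (pi - S / a1) / math.sqrt(var)


def _stack(loci) -> np.ndarray:
    rows = []
    for ls in loci:
        rows.append(ls.as_array() if isinstance(ls, LocusStats)
                    else np.asarray(ls, dtype=float))
    return np.vstack(rows)


def aggregate_stats(loci) -> pd.Series:
    """Aggregate per-locus statistics into the named 39-vector.

    ``loci`` is a sequence of :class:`LocusStats` (or 16-element
    arrays); at least two loci are required for the SDs/correlations.
    """
    st = _stack(loci)
    if st.shape[0] < 2:
        raise ValueError("aggregation needs at least 2 loci")
    if st.shape[1] != N_LOCUS_STATS:
        raise ValueError("each locus must provide 16 statistics")
    out = np.empty(N_SUMSTATS)
    _engine._aggregate39(np.ascontiguousarray(st), out)
    return pd.Series(out, index=list(STAT_NAMES))


def stats_from_loci(loci_matrices) -> pd.Series:
    """39-vector straight from a list of :class:`HaplotypeMatrix`."""
    return aggregate_stats([locus_stats(H) for H in loci_matrices])


#: statistics that scale with locus length (sums over sites)
_PER_SITE_SCALABLE = ("piA", "piB", "thetaWA", "thetaWB", "divAB",
                      "netdivAB", "minDivAB", "maxDivAB")


def per_locus_table(loci_matrices, per_bp_length: int = 0) -> pd.DataFrame:
    """Per-locus statistics as a tidy table (one row per locus).

    ``per_bp_length`` > 0 divides the site-sum statistics (pi, theta_W,
    dxy, Da, min/max divergence) by the locus length in bp, for
    per-site reporting; the ABC pipeline always uses the per-locus
    sums.
    """
    rows = [locus_stats(H).as_array() for H in loci_matrices]
    ids = [H.locus_id for H in loci_matrices]
    df = pd.DataFrame(rows, columns=list(LOCUS_STAT_NAMES), index=ids)
    if per_bp_length:
        df[list(_PER_SITE_SCALABLE)] /= float(per_bp_length)
    return df
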