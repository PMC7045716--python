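"""Two-population divergence scenarios and their priors.

Six demographic histories for a pair of populations (pop 1 = the focal
"native" deme, pop 2 = the divergent reference deme) that split from a
panmictic ancestor ``Tdiv`` generations ago:

``pan``
    Both samples come from a single panmictic deme; no split.
``div``
    Strict divergence in isolation: no gene flow after the split.
``im``
    Isolation with migration: bidirectional gene flow over the whole
    interval ``[0, Tdiv]``.
``divAGF``
    Ancient gene flow only: migration on ``[Tnc, Tdiv]`` (early stages
    of divergence), isolation since ``Tnc``.
``divSC``
    Recent secondary contact only: isolation on ``[Tsc, Tdiv]``,
    migration on ``[0, Tsc]``.
``divAGFSC``
    Both: migration on ``[0, Tsc]`` and ``[Tnc, Tdiv]``, isolation in
    between.

Times are in generations before present.  ``Tsc`` is capped at 300
generations (600 years at 2 years/generation, the earliest plausible
human-mediated contact) and ``Tnc`` is at least 10,000 generations
(20,000 years, the last glacial maximum).  Migration rates are scaled,
``M = 4*Nref*m``, with the forward-time convention that ``M12`` is the
rate into pop 1 from pop 2 (backwards in time, a lineage in deme 1
jumps to deme 2 at rate ``M12/2`` in coalescent units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

MODEL_NAMES = ("pan", "div", "im", "divAGF", "divSC", "divAGFSC")
MODEL_CODES = {name: i for i, name in enumerate(MODEL_NAMES)}

#: maximum onset of recent secondary contact, generations (600 y at 2 y/gen)
TSC_MAX = 300.0
#: minimum end of ancient gene flow, generations (20,000 y at 2 y/gen)
TNC_MIN = 10_000.0

GENERATION_TIME_YEARS = 2.0

#: scenarios whose migration epochs reference Tsc / Tnc
_USES_TSC = frozenset({"divSC", "divAGFSC"})
_USES_TNC = frozenset({"divAGF", "divAGFSC"})

PARAM_NAMES = ("N1", "N2", "Nanc", "Tdiv", "Tnc", "Tsc", "M12", "M21",
               "rho12", "rho21")


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for one divergence scenario.

    Sizes are diploid effective sizes; times in generations before
    present; M12/M21 are 4*Nref*m scaled migration rates for the
    ancient/ongoing gene-flow epochs (im, divAGF, divAGFSC).

    Recent secondary contact models a human-mediated invasion, so its
    intensity is parameterized by the cumulative introgression
    proportion ``rho12``/``rho21`` — the fraction of the recipient
    population replaced by migrants since contact (introduced
    populations in this system show tens of percent foreign ancestry
    within a few hundred generations).  The per-generation migration
    rate during ``[0, Tsc]`` is ``m = rho / Tsc``.
    """

    model_name: str
    N1: float
    N2: float = 0.0
    Nanc: float = 0.0
    Tdiv: float = 0.0
    Tnc: float = 0.0
    Tsc: float = 0.0
    M12: float = 0.0
    M21: float = 0.0
    rho12: float = 0.0
    rho21: float = 0.0
    Nref: float = 1e5

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown scenario {self.model_name!r}; "
                             f"expected one of {MODEL_NAMES}")
        if self.N1 <= 0 or self.Nref <= 0:
            raise ValueError("effective sizes must be positive")
        if self.model_name != "pan":
            if self.N2 <= 0 or self.Nanc <= 0:
                raise ValueError("two-deme scenarios need N2 > 0 and Nanc > 0")
            if self.Tdiv <= 0:
                raise ValueError("Tdiv must be positive")
        if self.M12 < 0 or self.M21 < 0:
            raise ValueError("migration rates must be non-negative")
        if not (0.0 <= self.rho12 < 1.0 and 0.0 <= self.rho21 < 1.0):
            raise ValueError("introgression proportions must lie in [0, 1)")
        name = self.model_name
        if name in _USES_TSC:
            if not (0 < self.Tsc < self.Tdiv):
                raise ValueError("need 0 < Tsc < Tdiv")
            if self.Tsc > TSC_MAX:
                raise ValueError(f"Tsc must be <= {TSC_MAX:g} generations")
        if name in _USES_TNC:
            if not (0 < self.Tnc < self.Tdiv):
                raise ValueError("need 0 < Tnc < Tdiv")
            if self.Tnc < TNC_MIN:
                raise ValueError(f"Tnc must be >= {TNC_MIN:g} generations")
        if name == "divAGFSC" and not (self.Tsc < self.Tnc):
            raise ValueError("need Tsc < Tnc")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class Epoch:
    """One backwards-in-time interval of constant demography.

    Times are in coalescent units (generations / (2*Nref)); ``nu`` are
    deme sizes relative to Nref; ``mig`` is the 2x2 backwards migration
    rate matrix (``mig[d, e]`` = per-lineage rate of jumping from deme d
    to deme e, i.e. ``M_into_d / 2``).  ``n_demes`` is 1 after (looking
    backwards) the two demes have merged into the ancestor.
    """

    t_start: float
    t_end: float
    nu: tuple
    mig: tuple
    n_demes: int


@dataclass(frozen=True)
class ModelInstance:
    """A scenario compiled to an epoch list usable by the simulator."""

    params: ModelParams
    epochs: tuple

    @property
    def model_name(self) -> str:
        return self.params.model_name


def _two_deme_epoch(t0, t1, nu1, nu2, m12, m21):
    return Epoch(t0, t1, (nu1, nu2), ((0.0, m12 / 2.0), (m21 / 2.0, 0.0)), 2)


def build_model(name: str, params: ModelParams) -> ModelInstance:
    """Compile a named scenario into its epoch list.

    Backwards in time from the present: two demes with the scenario's
    migration schedule until ``Tdiv``, then a single ancestral deme of
    size ``Nanc``.  ``div`` has zero migration in every epoch regardless
    of the M values carried by ``params``.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown scenario {name!r}")
    if params.model_name != name:
        params = replace(params, model_name=name)
    Nref = params.Nref
    scale = 1.0 / (2.0 * Nref)  # generations -> coalescent units
    nu1, nu2 = params.N1 / Nref, params.N2 / Nref

    if name == "pan":
        return ModelInstance(params, (Epoch(0.0, math.inf, (nu1,), ((0.0,),), 1),))

    nuanc = params.Nanc / Nref
    tdiv = params.Tdiv * scale
    tnc = params.Tnc * scale
    tsc = params.Tsc * scale
    m12, m21 = params.M12, params.M21
    # secondary contact: scaled rate from the introgression proportion
    msc12 = 4.0 * Nref * params.rho12 / params.Tsc if params.Tsc > 0 else 0.0
    msc21 = 4.0 * Nref * params.rho21 / params.Tsc if params.Tsc > 0 else 0.0
    anc = Epoch(tdiv, math.inf, (nuanc,), ((0.0,),), 1)

    if name == "div":
        eps = (_two_deme_epoch(0.0, tdiv, nu1, nu2, 0.0, 0.0), anc)
    elif name == "im":
        eps = (_two_deme_epoch(0.0, tdiv, nu1, nu2, m12, m21), anc)
    elif name == "divAGF":
        eps = (_two_deme_epoch(0.0, tnc, nu1, nu2, 0.0, 0.0),
               _two_deme_epoch(tnc, tdiv, nu1, nu2, m12, m21), anc)
    elif name == "divSC":
        eps = (_two_deme_epoch(0.0, tsc, nu1, nu2, msc12, msc21),
               _two_deme_epoch(tsc, tdiv, nu1, nu2, 0.0, 0.0), anc)
    else:  # divAGFSC
        eps = (_two_deme_epoch(0.0, tsc, nu1, nu2, msc12, msc21),
               _two_deme_epoch(tsc, tnc, nu1, nu2, 0.0, 0.0),
               _two_deme_epoch(tnc, tdiv, nu1, nu2, m12, m21), anc)
    return ModelInstance(params, eps)


HETEROGENEITY_MODES = ("homo", "hetero1", "hetero2")


@dataclass(frozen=True)
class PriorSet:
    """Uniform priors over the scenario parameters.

    Defaults bracket plausible histories for recently diverged marine
    taxa: sizes up to a couple of million diploids, split times up to a
    million generations, and scaled migration up to 40.  ``Tnc`` is
    drawn uniformly on [tnc_min, Tdiv] conditional on the drawn Tdiv;
    draws violating the ordering 0 < Tsc < Tnc < Tdiv are rejected and
    redrawn.

    heterogeneity_Ne / heterogeneity_m select the among-locus model:
    ``homo`` (all loci share the genome-wide draw), ``hetero1`` (an
    affected fraction of loci gets a uniformly reduced value) or
    ``hetero2`` (affected loci may be below or above the genome-wide
    draw).  The affected fraction P_het is itself drawn Uniform(0,1)
    per simulation unless fixed here.
    """

    N_range: tuple = (1e3, 2e6)
    Nanc_range: tuple = (1e3, 2e6)
    Tdiv_range: tuple = (1e4, 1e6)
    Tnc_min: float = TNC_MIN
    Tsc_range: tuple = (1.0, TSC_MAX)
    M_range: tuple = (0.0, 40.0)
    #: cumulative introgression proportion during recent contact, per
    #: direction (anchored by the tens-of-percent introduced ancestry
    #: observed in recently admixed populations of this system)
    rho_range: tuple = (0.0, 0.8)
    heterogeneity_Ne: str = "homo"
    heterogeneity_m: str = "homo"
    P_het_Ne: Optional[float] = None
    P_het_m: Optional[float] = None
    mutation_rate_per_bp: float = 2.8e-9
    generation_time_years: float = GENERATION_TIME_YEARS
    Nref: float = 1e5

    def __post_init__(self):
        for rng_ in (self.N_range, self.Nanc_range, self.Tdiv_range,
                     self.Tsc_range, self.M_range, self.rho_range):
            if not rng_[0] < rng_[1]:
                raise ValueError(f"prior range {rng_} must have lower < upper")
        if not (0.0 <= self.rho_range[0] and self.rho_range[1] < 1.0):
            raise ValueError("rho_range must lie within [0, 1)")
        for mode in (self.heterogeneity_Ne, self.heterogeneity_m):
            if mode not in HETEROGENEITY_MODES:
                raise ValueError(f"unknown heterogeneity mode {mode!r}")
        for p in (self.P_het_Ne, self.P_het_m):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError("P_het must lie in [0, 1]")


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus sampling setup: length, haploid sample sizes, theta."""

    L: int = 500
    nA: int = 16
    nB: int = 16
    theta_locus: float = field(default=-1.0)  # <0: derive from Nref * mu * L
    rho_locus: float = 0.0

    def __post_init__(self):
        if self.nA < 2 or (self.nB not in (0,) and self.nB < 2):
            raise ValueError("need at least 2 haploid samples per population")
        if self.theta_locus == -1.0 and self.L <= 0:
            raise ValueError("locus length must be positive")

    def theta(self, Nref: float, mu: float) -> float:
        if self.theta_locus >= 0:
            return self.theta_locus
        return 4.0 * Nref * mu * self.L


@dataclass(frozen=True)
class ParameterDraw:
    """One draw from the prior plus its per-locus multipliers."""

    params: ModelParams
    fNe: np.ndarray  # (n_loci,) multipliers on N1, N2, Nanc
    fm: np.ndarray   # (n_loci,) multipliers on M12, M21
    P_het_Ne: float
    P_het_m: float


MAX_REDRAWS = 10_000


def _draw_multipliers(mode: str, p_het: float, n_loci: int,
                      rng: np.random.Generator) -> np.ndarray:
    f = np.ones(n_loci)
    if mode == "homo" or p_het == 0.0:
        return f
    hit = rng.random(n_loci) < p_het
    k = int(hit.sum())
    if mode == "hetero1":
        f[hit] = rng.uniform(0.0, 1.0, k)
    else:  # hetero2: below or above the genome-wide draw
        f[hit] = rng.uniform(0.0, 2.0, k)
    # guard against a multiplier of exactly zero (degenerate deme size)
    np.clip(f, 1e-6, None, out=f)
    return f


def draw_parameters(priors: PriorSet, model_name: str, n_loci: int,
                    rng: np.random.Generator) -> ParameterDraw:
    """Draw one scenario parameter set and its per-locus multipliers.

    Time-order constraints (Tsc < Tnc < Tdiv, Tnc >= Tnc_min) are
    enforced by rejection; a draw region made empty by the configured
    ranges raises after ``MAX_REDRAWS`` attempts.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown scenario {model_name!r}")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    for _ in range(MAX_REDRAWS):
        n1 = rng.uniform(*priors.N_range)
        n2 = rng.uniform(*priors.N_range)
        nanc = rng.uniform(*priors.Nanc_range)
        tdiv = rng.uniform(*priors.Tdiv_range)
        tnc = tsc = 0.0
        if model_name in _USES_TNC:
            if tdiv <= priors.Tnc_min:
                continue
            tnc = rng.uniform(priors.Tnc_min, tdiv)
        if model_name in _USES_TSC:
            tsc = rng.uniform(*priors.Tsc_range)
            if tsc >= tdiv or (model_name == "divAGFSC" and tsc >= tnc):
                continue
        uses_M = model_name in ("im", "divAGF", "divAGFSC")
        m12 = rng.uniform(*priors.M_range) if uses_M else 0.0
        m21 = rng.uniform(*priors.M_range) if uses_M else 0.0
        rho12 = rng.uniform(*priors.rho_range) if model_name in _USES_TSC \
            else 0.0
        rho21 = rng.uniform(*priors.rho_range) if model_name in _USES_TSC \
            else 0.0
        if model_name == "pan":
            params = ModelParams("pan", N1=n1, Nref=priors.Nref)
        else:
            params = ModelParams(model_name, N1=n1, N2=n2, Nanc=nanc,
                                 Tdiv=tdiv, Tnc=tnc, Tsc=tsc,
                                 M12=m12, M21=m21, rho12=rho12,
                                 rho21=rho21, Nref=priors.Nref)
        break
    else:
        raise RuntimeError(
            f"could not draw valid parameters for {model_name} in "
            f"{MAX_REDRAWS} attempts; check the prior ranges")

    p_ne = priors.P_het_Ne
    if p_ne is None:
        p_ne = rng.uniform() if priors.heterogeneity_Ne != "homo" else 0.0
    p_m = priors.P_het_m
    if p_m is None:
        p_m = rng.uniform() if priors.heterogeneity_m != "homo" else 0.0
    fne = _draw_multipliers(priors.heterogeneity_Ne, p_ne, n_loci, rng)
    fm = _draw_multipliers(priors.heterogeneity_m, p_m, n_loci, rng)
    return ParameterDraw(params, fne, fm, p_ne, p_m)
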