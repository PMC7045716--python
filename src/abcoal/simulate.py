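"""Coalescent simulation of multilocus datasets and simulation tables.

The sampler is a standard two-deme structured coalescent with epochs:
within deme ``d`` each pair of the ``k_d`` lineages coalesces at rate
``k_d (k_d - 1)/2 / nu_d``; each lineage in deme ``d`` migrates to the
other deme at rate ``M_into_d / 2`` during migration epochs; at the
(scaled) split time all lineages move into the ancestral deme.
Mutations fall on branches as a Poisson process with rate
``theta_locus / 2`` per unit branch length with infinite-sites
placement on [0, 1).  With these rates, time is measured in units of
2*Nref generations while theta and M keep their 4*Nref definitions, so
E[S] = theta * a_{n-1} and E[pi] = theta in a single Nref-sized deme.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .containers import HaplotypeMatrix
from .demography import (MODEL_CODES, LocusConfig, ModelInstance, ModelParams,
                         ParameterDraw, PriorSet, build_model, draw_parameters)
from .sumstats import N_SUMSTATS, STAT_NAMES

PARAM_COLUMNS = ("N1", "N2", "Nanc", "Tdiv", "Tnc", "Tsc", "M12", "M21",
                 "rho12", "rho21", "P_het_Ne", "P_het_m")
TABLE_COLUMNS = ("model",) + PARAM_COLUMNS + STAT_NAMES

_MAX_SEED = 2**31 - 1


def _epoch_arrays(model: ModelInstance):
    eps = model.epochs
    ne = len(eps)
    t_end = np.empty(ne)
    nu1 = np.empty(ne)
    nu2 = np.ones(ne)
    m1 = np.zeros(ne)
    m2 = np.zeros(ne)
    ndem = np.empty(ne, dtype=np.int64)
    for i, ep in enumerate(eps):
        t_end[i] = ep.t_end
        nu1[i] = ep.nu[0]
        ndem[i] = ep.n_demes
        if ep.n_demes == 2:
            nu2[i] = ep.nu[1]
            m1[i] = ep.mig[0][1]
            m2[i] = ep.mig[1][0]
    return ne, t_end, nu1, nu2, m1, m2, ndem


def simulate_locus(model: ModelInstance, cfg: LocusConfig,
                   rng: np.random.Generator, *, mu: float = 2.8e-9,
                   fNe: float = 1.0, fm: float = 1.0,
                   locus_id: str = "locus") -> HaplotypeMatrix:
    """Simulate one locus under a compiled scenario.

    ``cfg.nB`` may be 0 for the single-deme ``pan`` scenario (all
    haplotypes sampled from deme 1); otherwise nA haplotypes come from
    deme 1 and nB from deme 2.
    """
    theta = cfg.theta(model.params.Nref, mu)
    ne, t_end, nu1, nu2, m1, m2, ndem = _epoch_arrays(model)
    n1, n2 = cfg.nA, cfg.nB
    if model.model_name == "pan" and n2 > 0:
        # a panmictic deme: both "populations" are arbitrary labels
        n1, n2 = cfg.nA + cfg.nB, 0
    seed = int(rng.integers(0, _MAX_SEED))
    masks, pos = _engine._sim_locus_seeded(
        seed, n1, n2, ne, t_end, nu1, nu2, m1, m2, ndem,
        float(fNe), float(fm), theta)
    # infinite-sites positions are a.s. distinct; drop ties defensively
    keep = np.ones(pos.size, dtype=bool)
    if pos.size > 1:
        keep[1:] = np.diff(pos) > 0
    return HaplotypeMatrix.from_site_masks(masks[keep], pos[keep],
                                           cfg.nA, cfg.nB, locus_id)


def _scaled_params(params: ModelParams) -> np.ndarray:
    """[nu1, nu2, nuanc, tsc, tnc, tdiv, M12/2, M21/2, Msc12/2,
    Msc21/2] for the kernels (Msc = 4*Nref*rho/Tsc)."""
    Nref = params.Nref
    s = 1.0 / (2.0 * Nref)
    if params.Tsc > 0:
        mhsc1 = 2.0 * Nref * params.rho12 / params.Tsc
        mhsc2 = 2.0 * Nref * params.rho21 / params.Tsc
    else:
        mhsc1 = mhsc2 = 0.0
    return np.array([
        params.N1 / Nref, max(params.N2, 1.0) / Nref,
        max(params.Nanc, 1.0) / Nref,
        params.Tsc * s, params.Tnc * s, params.Tdiv * s,
        params.M12 / 2.0, params.M21 / 2.0, mhsc1, mhsc2,
    ])


def stats_for_draw(draw: ParameterDraw, cfg: LocusConfig, n_loci: int,
                   rng: np.random.Generator, *, mu: float = 2.8e-9) -> np.ndarray:
    """39-statistic vector for one parameter draw (one dataset)."""
    params = draw.params
    theta = np.full(n_loci, cfg.theta(params.Nref, mu))
    seeds = rng.integers(0, _MAX_SEED, size=1)
    sp = _scaled_params(params)[None, :]
    out = np.empty((1, N_SUMSTATS))
    _engine._bulk_tables(seeds, MODEL_CODES[params.model_name], sp,
                         draw.fNe[None, :], draw.fm[None, :], theta,
                         cfg.nA, cfg.nB, out)
    return out[0]


def simulate_table(model_name: str, priors: PriorSet, n_sims: int,
                   n_loci: int, cfg: LocusConfig,
                   rng: np.random.Generator, *,
                   mu: Optional[float] = None,
                   label: Optional[str] = None) -> pd.DataFrame:
    """Simulate a reference table: parameter draws + 39 statistics.

    One row per simulation; rows are independent given the generator
    state, and re-running with an identically seeded generator yields a
    bitwise-identical table.
    """
    if n_sims < 0:
        raise ValueError("n_sims must be >= 0")
    label = label if label is not None else model_name
    if n_sims == 0:
        return pd.DataFrame(columns=list(TABLE_COLUMNS))
    mu = priors.mutation_rate_per_bp if mu is None else mu
    code = MODEL_CODES[model_name]
    theta = np.full(n_loci, cfg.theta(priors.Nref, mu))

    sp = np.empty((n_sims, 10))
    fne = np.empty((n_sims, n_loci))
    fm = np.empty((n_sims, n_loci))
    pcols = np.empty((n_sims, len(PARAM_COLUMNS)))
    for s in range(n_sims):
        draw = draw_parameters(priors, model_name, n_loci, rng)
        p = draw.params
        sp[s] = _scaled_params(p)
        fne[s] = draw.fNe
        fm[s] = draw.fm
        pcols[s] = [p.N1, p.N2, p.Nanc, p.Tdiv, p.Tnc, p.Tsc, p.M12, p.M21,
                    p.rho12, p.rho21, draw.P_het_Ne, draw.P_het_m]
    seeds = rng.integers(0, _MAX_SEED, size=n_sims)
    out = np.empty((n_sims, N_SUMSTATS))
    _engine._bulk_tables(seeds, code, sp, fne, fm, theta, cfg.nA, cfg.nB, out)

    df = pd.DataFrame(pcols, columns=list(PARAM_COLUMNS))
    df.insert(0, "model", label)
    for j, name in enumerate(STAT_NAMES):
        df[name] = out[:, j]
    return df


def simulate_dataset(params: ModelParams, cfg: LocusConfig, n_loci: int,
                     rng: np.random.Generator, *, mu: float = 2.8e-9,
                     fNe: Optional[np.ndarray] = None,
                     fm: Optional[np.ndarray] = None) -> list:
    """Simulate ``n_loci`` haplotype matrices under fixed parameters."""
    model = build_model(params.model_name, params)
    fNe = np.ones(n_loci) if fNe is None else fNe
    fm = np.ones(n_loci) if fm is None else fm
    return [simulate_locus(model, cfg, rng, mu=mu, fNe=fNe[i], fm=fm[i],
                           locus_id=f"locus_{i}")
            for i in range(n_loci)]
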