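"""Synthetic "observed" datasets with known ground truth.

Two generators cover the pipeline's inputs: multilocus haplotype
datasets under any of the six divergence scenarios (for ABC and the
summary statistics), and three-population SNP frequency tables with a
known admixture fraction (for the f3 test).  Every dataset carries a
:class:`TruthRecord` sufficient to regenerate it bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import io as aio
from .admixture import SnpFrequencyTable
from .demography import (LocusConfig, ModelParams, PriorSet,
                         draw_parameters)
from .simulate import simulate_dataset
from .sumstats import stats_from_loci


@dataclass
class TruthRecord:
    """Ground truth for a synthetic dataset (regenerates it bit-exactly)."""

    kind: str                 # "multilocus" or "admixture"
    seed: int
    params: Dict[str, float]
    config: Dict[str, float]

    def to_json(self, dest) -> None:
        aio.write_json(asdict(self), dest)

    @classmethod
    def from_json(cls, src) -> "TruthRecord":
        import json
        fh, close = aio._opened(src, "r")
        try:
            d = json.load(fh)
        finally:
            if close:
                fh.close()
        return cls(**d)


def generate_observed(model_name: str,
                      params_or_priors: Union[ModelParams, PriorSet],
                      n_loci: int, cfg: LocusConfig, seed: int,
                      outdir: Optional[Union[str, Path]] = None,
                      mu: float = 2.8e-9):
    """Simulate one observed multilocus dataset with known truth.

    With a :class:`PriorSet` the parameters are first drawn from the
    prior (as for a POD); with explicit :class:`ModelParams` they are
    used as-is.  Returns ``(loci, stats, truth)`` and, when ``outdir``
    is given, writes ms text, FASTA, the 39-statistic vector and the
    truth record there.
    """
    rng = np.random.default_rng(seed)
    if isinstance(params_or_priors, PriorSet):
        draw = draw_parameters(params_or_priors, model_name, n_loci, rng)
        params, fNe, fm = draw.params, draw.fNe, draw.fm
        het = {"P_het_Ne": draw.P_het_Ne, "P_het_m": draw.P_het_m}
    else:
        params = params_or_priors
        fNe = fm = np.ones(n_loci)
        het = {"P_het_Ne": 0.0, "P_het_m": 0.0}
    loci = simulate_dataset(params, cfg, n_loci, rng, mu=mu, fNe=fNe, fm=fm)
    stats = stats_from_loci(loci)
    pd_ = {k: getattr(params, k) for k in
           ("model_name", "N1", "N2", "Nanc", "Tdiv", "Tnc", "Tsc",
            "M12", "M21", "rho12", "rho21", "Nref")}
    pd_.update(het)
    truth = TruthRecord("multilocus", seed, pd_,
                        {"n_loci": n_loci, "nA": cfg.nA, "nB": cfg.nB,
                         "L": cfg.L, "theta_locus": cfg.theta_locus,
                         "mu": mu})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aio.write_ms(loci, outdir / "loci.ms")
        aio.write_fasta(loci, outdir / "loci.fasta")
        stats.rename("value").to_frame().to_csv(outdir / "stats.tsv",
                                                sep="\t")
        truth.to_json(outdir / "truth.json")
    return loci, stats, truth


def regenerate_observed(truth: TruthRecord):
    """Rebuild the dataset described by a multilocus truth record."""
    if truth.kind != "multilocus":
        raise ValueError("not a multilocus truth record")
    p = truth.params
    c = truth.config
    if p["P_het_Ne"] or p["P_het_m"]:
        raise ValueError("heterogeneous datasets regenerate from the prior "
                         "draw; store and reuse the PriorSet seed instead")
    params = ModelParams(p["model_name"], N1=p["N1"], N2=p["N2"],
                         Nanc=p["Nanc"], Tdiv=p["Tdiv"], Tnc=p["Tnc"],
                         Tsc=p["Tsc"], M12=p["M12"], M21=p["M21"],
                         rho12=p.get("rho12", 0.0),
                         rho21=p.get("rho21", 0.0), Nref=p["Nref"])
    cfg = LocusConfig(L=int(c["L"]), nA=int(c["nA"]), nB=int(c["nB"]),
                      theta_locus=c["theta_locus"])
    return generate_observed(params.model_name, params, int(c["n_loci"]),
                             cfg, truth.seed, mu=c["mu"])


@dataclass(frozen=True)
class AdmixtureScenario:
    """Three-population scenario with a known admixture fraction.

    An ancestral allele frequency per SNP is drawn uniformly on
    ``anc_range``; each source population drifts away from it under the
    Balding-Nichols model with divergence parameter ``F`` (variance
    ``F p (1-p)``); the target's true frequency is the ``alpha`` /
    ``1 - alpha`` mixture of the source true frequencies; sample
    frequencies add binomial noise at the given haploid sample sizes.
    An undrifted outgroup column is included as a drift reference.

    The default panels (200 haplotypes) keep the uncorrected f3's
    finite-sample bias, +E[c(1-c)]/n_target, an order of magnitude
    below the admixture signal -alpha(1-alpha)*E[(p1-p2)^2] at the
    default drift F = 0.05; for small panels use the corrected
    statistic instead.
    """

    alpha: float = 0.5
    F: float = 0.05
    n_snps: int = 10_000
    n_hap_target: int = 200
    n_hap_source: int = 200
    anc_range: tuple = (0.05, 0.95)

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.F < 0:
            raise ValueError("F must be >= 0")


def _balding_nichols(p: np.ndarray, F: float,
                     rng: np.random.Generator) -> np.ndarray:
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def generate_admixture_scenario(scn: AdmixtureScenario, seed: int):
    """Synthetic SNP table for the f3 test; returns (table, truth).

    Populations: ``src1``, ``src2`` (independently drifted sources),
    ``target`` (alpha : 1-alpha mixture of the sources' true
    frequencies, binomially resampled), ``outgroup`` (the undrifted
    ancestral frequency, binomially resampled).
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*scn.anc_range, scn.n_snps)
    p1 = _balding_nichols(p, scn.F, rng)
    p2 = _balding_nichols(p, scn.F, rng)
    pt = scn.alpha * p1 + (1.0 - scn.alpha) * p2
    ns, nt = scn.n_hap_source, scn.n_hap_target
    freq = pd.DataFrame({
        "outgroup": rng.binomial(ns, p) / ns,
        "src1": rng.binomial(ns, p1) / ns,
        "src2": rng.binomial(ns, p2) / ns,
        "target": rng.binomial(nt, pt) / nt,
    })
    size = pd.DataFrame({"outgroup": ns, "src1": ns, "src2": ns,
                         "target": nt}, index=freq.index)
    truth = TruthRecord("admixture", seed,
                        {"alpha": scn.alpha, "F": scn.F},
                        {"n_snps": scn.n_snps, "n_hap_target": nt,
                         "n_hap_source": ns,
                         "anc_low": scn.anc_range[0],
                         "anc_high": scn.anc_range[1]})
    return SnpFrequencyTable(freq, size), truth
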