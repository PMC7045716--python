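"""ABC model choice, PODs cross-validation and parameter estimation.

Model choice follows the rejection/neural-net scheme standard in
likelihood-free demographic inference: simulations from all candidate
models are pooled, statistics are centred and scaled by the pooled SD,
and the ``ceil(eps * N)`` simulations closest to the observation in
Euclidean distance are accepted.  Under plain rejection the posterior
probability of a model is the fraction of accepted rows carrying its
label; the neural-net method refines this by a categorical regression
(single-hidden-layer multinomial classifier) fitted to the accepted
rows with Epanechnikov-kernel weights and evaluated at the observation.

Validation simulates pseudo-observed datasets (PODs) from each model's
prior, runs the same model choice on each, and summarises precision and
misclassification in a confusion matrix; the robustness threshold is
the smallest posterior-probability cutoff at which calls for a focal
model reach a target positive predictive value.

Parameter posteriors are approximated by the accepted draws under the
chosen model, optionally adjusted by weighted local-linear regression,
with the mode taken from a Gaussian kernel density estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .demography import GENERATION_TIME_YEARS, PriorSet
from .simulate import PARAM_COLUMNS
from .sumstats import STAT_NAMES

TIME_PARAMS = ("Tdiv", "Tnc", "Tsc")


@dataclass(frozen=True)
class ABCConfig:
    """Tuning knobs for ABC model choice and estimation."""

    tolerance: float = 0.001
    method: str = "neuralnet"
    n_hidden: int = 4
    n_net_replicates: int = 10
    l2: float = 1e-4
    max_iter: int = 150

    def __post_init__(self):
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must be in (0, 1]")
        if self.method not in ("rejection", "neuralnet"):
            raise ValueError("method must be 'rejection' or 'neuralnet'")


class StatNormalizer:
    """Center/scale statistics by a pooled reference table.

    ``scale='sd'`` (default) centres on the mean and scales by the SD;
    ``scale='mad'`` centres on the median and scales by the median
    absolute deviation.  Columns with zero scale carry no distance
    information and are dropped from the transformed space.
    """

    def __init__(self, reference: np.ndarray, scale: str = "sd"):
        ref = np.asarray(reference, dtype=float)
        if ref.ndim != 2 or ref.shape[0] < 2:
            raise ValueError("reference must be 2-D with >= 2 rows")
        if scale == "sd":
            self.mean_ = ref.mean(axis=0)
            self.sd_ = ref.std(axis=0, ddof=1)
        elif scale == "mad":
            self.mean_ = np.median(ref, axis=0)
            self.sd_ = np.median(np.abs(ref - self.mean_), axis=0)
        else:
            raise ValueError("scale must be 'sd' or 'mad'")
        self.keep_ = self.sd_ > 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]


def normalize_stats(reference, *vectors):
    """Normalize the reference by itself plus any extra vectors."""
    norm = StatNormalizer(_stat_matrix(reference))
    out = [norm.transform(_stat_matrix(reference))]
    out.extend(norm.transform(np.atleast_2d(np.asarray(v, dtype=float)))
               for v in vectors)
    return out[0] if not vectors else tuple(out)


def _stat_matrix(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        cols = [c for c in STAT_NAMES if c in table.columns]
        if len(cols) == len(STAT_NAMES):
            return table[list(STAT_NAMES)].to_numpy(dtype=float)
        return table.to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def _obs_vector(obs) -> np.ndarray:
    if isinstance(obs, pd.Series):
        if all(c in obs.index for c in STAT_NAMES):
            return obs[list(STAT_NAMES)].to_numpy(dtype=float)
        return obs.to_numpy(dtype=float)
    return np.asarray(obs, dtype=float).ravel()


def _accept(dist: np.ndarray, eps: float) -> np.ndarray:
    """Indices of the ceil(eps*N) smallest distances, ties by index."""
    n = dist.size
    m = int(math.ceil(eps * n))
    if m < 1:
        raise ValueError("tolerance accepts no simulations")
    if m >= n:
        return np.arange(n)
    part = np.argpartition(dist, m)[:m + min(n - m, m)]
    part = part[np.lexsort((part, dist[part]))][:m]
    return part


def reject(obs, pooled, eps: float):
    """Plain ABC rejection on normalized Euclidean distance.

    Returns ``(accepted_index, distances)`` where ``accepted_index``
    are positional row indices of the pooled table sorted by distance
    (ties broken by row index) and ``distances`` covers every row.
    """
    ref = _stat_matrix(pooled)
    if ref.shape[0] == 0:
        raise ValueError("empty simulation table")
    norm = StatNormalizer(ref)
    refn = norm.transform(ref)
    obsn = norm.transform(_obs_vector(obs))
    dist = np.sqrt(((refn - obsn) ** 2).sum(axis=1))
    return _accept(dist, eps), dist


@dataclass
class ModelChoiceResult:
    """Posterior model probabilities from one ABC comparison."""

    probabilities: pd.Series
    method: str
    tolerance: float
    n_accepted: pd.Series
    fallback: bool = False

    @property
    def best_model(self) -> str:
        return str(self.probabilities.idxmax())

    def cumulative(self, models: Iterable[str]) -> float:
        """Summed posterior probability of a named subset of models."""
        return float(self.probabilities.reindex(list(models)).fillna(0).sum())

    def summary(self) -> str:
        lines = ["ABC model choice",
                 f"  method: {self.method}   tolerance: {self.tolerance:g}"
                 + ("   (rejection fallback)" if self.fallback else ""),
                 f"  accepted simulations: {int(self.n_accepted.sum())}",
                 "  model      P(model|obs)  n_accepted"]
        for m in self.probabilities.index:
            lines.append(f"  {m:<10} {self.probabilities[m]:>10.4f}  "
                         f"{int(self.n_accepted.get(m, 0)):>10d}")
        lines.append(f"  best model: {self.best_model}")
        return "\n".join(lines)


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max()
    if dmax <= 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / dmax) ** 2
    return np.maximum(w, 1e-8)


class ABCModelChoice:
    """Model-choice problem: an observed 39-vector vs per-model tables.

    Pools the per-model reference tables, then ``fit`` runs rejection
    or neural-net categorical regression at a given tolerance (the
    accepted fraction of the pooled reference).
    """

    def __init__(self, obs, tables: Mapping[str, pd.DataFrame]):
        if len(tables) < 2:
            raise ValueError("model choice needs >= 2 candidate models")
        self.model_names = list(tables.keys())
        mats = [_stat_matrix(t) for t in tables.values()]
        self.labels = np.concatenate([
            np.full(m.shape[0], i) for i, m in enumerate(mats)])
        self.pooled = np.vstack(mats)
        self.obs = _obs_vector(obs)
        self.norm = StatNormalizer(self.pooled)
        self._pooled_n = self.norm.transform(self.pooled)
        self._obs_n = self.norm.transform(self.obs)

    def fit(self, config: Optional[ABCConfig] = None, *,
            rng: Optional[np.random.Generator] = None) -> ModelChoiceResult:
        config = ABCConfig() if config is None else config
        dist = np.sqrt(((self._pooled_n - self._obs_n) ** 2).sum(axis=1))
        acc = _accept(dist, config.tolerance)
        return self._result_from_accept(acc, dist, config, rng)

    def _result_from_accept(self, acc, dist, config, rng) -> ModelChoiceResult:
        labels = self.labels[acc]
        counts = np.bincount(labels, minlength=len(self.model_names))
        n_acc = pd.Series(counts, index=self.model_names)
        rej_probs = pd.Series(counts / counts.sum(), index=self.model_names)
        if config.method == "rejection":
            return ModelChoiceResult(rej_probs, "rejection",
                                     config.tolerance, n_acc)
        if np.unique(labels).size < 2:
            # degenerate accepted set: categorical regression undefined,
            # report the plain rejection proportions
            return ModelChoiceResult(rej_probs, "neuralnet",
                                     config.tolerance, n_acc, fallback=True)
        from ._nnet import WeightedNNet
        rng = np.random.default_rng(0) if rng is None else rng
        X = self._pooled_n[acc]
        w = _epanechnikov(dist[acc])
        probs = np.zeros(len(self.model_names))
        for _ in range(config.n_net_replicates):
            net = WeightedNNet(config.n_hidden, config.l2,
                               config.max_iter).fit(X, labels, w, rng)
            p = net.predict_proba(self._obs_n)[0]
            full = np.zeros(len(self.model_names))
            full[net.classes_] = p
            probs += full
        probs /= probs.sum()
        return ModelChoiceResult(pd.Series(probs, index=self.model_names),
                                 "neuralnet", config.tolerance, n_acc)


def model_choice_rejection(obs, tables, eps: float) -> ModelChoiceResult:
    return ABCModelChoice(obs, tables).fit(
        ABCConfig(tolerance=eps, method="rejection"))


def model_choice_nnet(obs, tables, eps: float,
                      config: Optional[ABCConfig] = None,
                      rng: Optional[np.random.Generator] = None
                      ) -> ModelChoiceResult:
    cfg = ABCConfig(tolerance=eps, method="neuralnet") if config is None \
        else ABCConfig(tolerance=eps, method="neuralnet",
                       n_hidden=config.n_hidden,
                       n_net_replicates=config.n_net_replicates,
                       l2=config.l2, max_iter=config.max_iter)
    return ABCModelChoice(obs, tables).fit(cfg, rng=rng)


@dataclass
class PODsValidationResult:
    """Confusion matrix + per-POD posterior records from validation."""

    confusion: pd.DataFrame      # rows = true model, cols = selected
    records: pd.DataFrame        # true_model + prob_<model> + selected

    @property
    def precision(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion),
                         index=self.confusion.index, dtype=float)
        return diag / self.confusion.sum(axis=1)

    def misclassified_to(self, true_model: str) -> pd.Series:
        """Off-diagonal fractions for PODs generated under true_model."""
        row = self.confusion.loc[true_model].astype(float).copy()
        row[true_model] = 0.0
        total = row.sum()
        return row / total if total > 0 else row

    def summary(self) -> str:
        lines = ["PODs cross-validation",
                 self.confusion.to_string(),
                 "per-model precision:"]
        for m, p in self.precision.items():
            lines.append(f"  {m:<10} {p:.3f}")
        return "\n".join(lines)


def classify_pods(pods: pd.DataFrame, tables: Mapping[str, pd.DataFrame],
                  config: Optional[ABCConfig] = None,
                  rng: Optional[np.random.Generator] = None
                  ) -> PODsValidationResult:
    """Run model choice on every POD against shared reference tables.

    ``pods`` carries a ``model`` column (the true generating model) and
    the 39 statistic columns.  The pooled reference is normalized once;
    each POD is then classified independently.
    """
    config = ABCConfig() if config is None else config
    rng = np.random.default_rng(0) if rng is None else rng
    model_names = list(tables.keys())
    mc = ABCModelChoice(np.zeros(len(STAT_NAMES)), tables)
    pods_stats = _stat_matrix(pods)
    pods_n = mc.norm.transform(pods_stats)
    truth = pods["model"].to_numpy()
    rows = []
    for i in range(pods_n.shape[0]):
        dist = np.sqrt(((mc._pooled_n - pods_n[i]) ** 2).sum(axis=1))
        acc = _accept(dist, config.tolerance)
        mc._obs_n = pods_n[i:i + 1]
        res = mc._result_from_accept(acc, dist, config, rng)
        rows.append([truth[i], res.best_model, res.fallback]
                    + list(res.probabilities.to_numpy()))
    records = pd.DataFrame(
        rows, columns=["true_model", "selected", "fallback"]
        + [f"prob_{m}" for m in model_names])
    confusion = pd.crosstab(records["true_model"], records["selected"]) \
        .reindex(index=model_names, columns=model_names, fill_value=0)
    confusion.index.name = "true"
    confusion.columns.name = "selected"
    return PODsValidationResult(confusion, records)


def run_pods_validation(model_names: Sequence[str], priors: PriorSet,
                        n_pods: int, n_loci: int, cfg, rng,
                        tables: Optional[Mapping[str, pd.DataFrame]] = None,
                        config: Optional[ABCConfig] = None,
                        n_sims: int = 10_000) -> PODsValidationResult:
    """Full PODs cross-validation, simulating what is not supplied.

    For each candidate model, simulates ``n_pods`` pseudo-observed
    datasets from the prior (and, unless ``tables`` is given,
    ``n_sims`` reference simulations), then classifies every POD.
    """
    from .simulate import simulate_table
    if tables is None:
        tables = {m: simulate_table(m, priors, n_sims, n_loci, cfg, rng)
                  for m in model_names}
    if n_pods == 0:
        empty = pd.DataFrame(0, index=list(model_names),
                             columns=list(model_names))
        return PODsValidationResult(
            empty, pd.DataFrame(columns=["true_model", "selected", "fallback"]
                                + [f"prob_{m}" for m in model_names]))
    pods = pd.concat([simulate_table(m, priors, n_pods, n_loci, cfg, rng)
                      for m in model_names], ignore_index=True)
    return classify_pods(pods, tables, config, rng)


def robustness_threshold(records: pd.DataFrame, focal: str,
                         target: float = 0.95,
                         step: float = 0.01) -> Optional[float]:
    """Smallest probability cutoff giving the target predictive value.

    Scans cutoffs on a grid; among PODs *called* as the focal model
    (argmax posterior, when the records carry a ``selected`` column)
    with focal-model probability >= cutoff, the fraction truly
    generated under the focal model must reach ``target``.  Returns
    None when no cutoff attains the target.
    """
    col = f"prob_{focal}"
    if col not in records.columns:
        raise ValueError(f"records lack column {col}")
    probs = records[col].to_numpy(dtype=float)
    truth = (records["true_model"] == focal).to_numpy()
    called = (records["selected"] == focal).to_numpy() \
        if "selected" in records.columns else np.ones(len(records), bool)
    for x in np.arange(0.0, 1.0 + step / 2, step):
        sel = called & (probs >= x)
        if not sel.any():
            continue
        if truth[sel].mean() >= target:
            return float(round(x, 10))
    return None


def hetero_variants(priors: PriorSet) -> Dict[str, PriorSet]:
    """The 3x3 grid of among-locus heterogeneity variants of a prior."""
    from dataclasses import replace
    out = {}
    for hn in ("homo", "hetero1", "hetero2"):
        for hm in ("homo", "hetero1", "hetero2"):
            out[f"Ne-{hn}_m-{hm}"] = replace(priors, heterogeneity_Ne=hn,
                                             heterogeneity_m=hm)
    return out


def compare_heterogeneity(obs, tables: Mapping[str, pd.DataFrame],
                          config: Optional[ABCConfig] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> ModelChoiceResult:
    """Model choice across heterogeneity variants of one scenario.

    ``tables`` maps variant names (e.g. "Ne-hetero2_m-homo") to
    simulation tables under the fixed best demographic scenario; the
    machinery is identical to model choice with variants as labels.
    Use ``result.cumulative([...])`` for e.g. all hetero2-Ne variants.
    """
    return ABCModelChoice(obs, tables).fit(
        ABCConfig() if config is None else config, rng=rng)


@dataclass
class Posterior:
    """Marginal posterior for one parameter."""

    name: str
    samples: np.ndarray
    weights: np.ndarray
    mode: float
    ci95: tuple
    adjusted: bool

    def mode_years(self, generation_time: float = GENERATION_TIME_YEARS):
        return self.mode * generation_time


def _kde_mode(x: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return float(lo)
    kde = gaussian_kde(x, bw_method="silverman", weights=weights)
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class PosteriorResult:
    """Posteriors for all requested parameters of one model fit."""

    posteriors: Dict[str, Posterior]
    tolerance: float
    adjustment: str
    n_accepted: int

    def __getitem__(self, name: str) -> Posterior:
        return self.posteriors[name]

    def summary(self, generation_time: float = GENERATION_TIME_YEARS) -> str:
        lines = ["ABC parameter estimation",
                 f"  tolerance: {self.tolerance:g}   adjustment: "
                 f"{self.adjustment}   accepted: {self.n_accepted}",
                 "  parameter        mode          CI95"]
        for name, p in self.posteriors.items():
            lines.append(f"  {name:<10} {p.mode:>12.6g}  "
                         f"[{p.ci95[0]:.6g}, {p.ci95[1]:.6g}]")
            if name in TIME_PARAMS:
                lines.append(f"  {name + ' (years)':<10} "
                             f"{p.mode * generation_time:>12.6g}  "
                             f"[{p.ci95[0] * generation_time:.6g}, "
                             f"{p.ci95[1] * generation_time:.6g}]")
        return "\n".join(lines)


class ParameterEstimator:
    """Posterior parameter estimation under one (best) model.

    ``fit`` accepts the closest fraction ``tolerance`` of the table,
    optionally applies weighted local-linear regression adjustment
    (on log scale for strictly positive parameters), and summarises
    each marginal by its KDE mode and [2.5%, 97.5%] quantiles.
    """

    def __init__(self, obs, table: pd.DataFrame,
                 params: Optional[Sequence[str]] = None):
        self.table = table
        self.params = [p for p in (params or PARAM_COLUMNS)
                       if p in table.columns]
        if not self.params:
            raise ValueError("no parameter columns found in table")
        self.obs = _obs_vector(obs)

    def fit(self, tolerance: float = 0.01,
            adjustment: str = "loclinear") -> PosteriorResult:
        if adjustment not in ("none", "loclinear"):
            raise ValueError("adjustment must be 'none' or 'loclinear'")
        acc, dist = reject(self.obs, self.table, tolerance)
        norm = StatNormalizer(_stat_matrix(self.table))
        Xn = norm.transform(_stat_matrix(self.table))[acc]
        obs_n = norm.transform(self.obs)[0]
        w = _epanechnikov(dist[acc])
        posteriors = {}
        any_adjusted = False
        for name in self.params:
            vals = self.table[name].to_numpy(dtype=float)[acc]
            adjusted = False
            out_vals = vals
            if adjustment == "loclinear" and np.ptp(vals) > 0:
                out_vals, adjusted = self._loclinear(vals, Xn, obs_n, w)
                any_adjusted = any_adjusted or adjusted
            mode = _kde_mode(out_vals, w) if np.ptp(out_vals) > 0 \
                else float(out_vals[0])
            lo, hi = np.quantile(out_vals, [0.025, 0.975])
            posteriors[name] = Posterior(name, out_vals, w, mode,
                                         (float(lo), float(hi)), adjusted)
        used = "loclinear" if any_adjusted else "none"
        return PosteriorResult(posteriors, tolerance, used, len(acc))

    @staticmethod
    def _loclinear(vals, Xn, obs_n, w):
        """Weighted local-linear adjustment; falls back to the raw
        accepted draws on singularity or when the regression would
        interpolate (accepted rows not exceeding the statistic count)."""
        if Xn.shape[0] <= Xn.shape[1] + 2:
            return vals, False
        positive = vals.min() > 0
        y = np.log(vals) if positive else vals
        A = np.hstack([np.ones((Xn.shape[0], 1)), Xn])
        sw = np.sqrt(w)
        try:
            coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        except np.linalg.LinAlgError:
            return vals, False
        if not np.all(np.isfinite(coef)):
            return vals, False
        fitted = A @ coef
        at_obs = coef[0] + obs_n @ coef[1:]
        adj = y - fitted + at_obs
        return (np.exp(adj) if positive else adj), True


def estimate_parameters(obs, table: pd.DataFrame, eps: float = 0.01,
                        adjustment: str = "loclinear",
                        params: Optional[Sequence[str]] = None
                        ) -> PosteriorResult:
    return ParameterEstimator(obs, table, params).fit(eps, adjustment)
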