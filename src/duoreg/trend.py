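"""Trends and cooperativity statistics.

* A Gaussian-process regression of (z-scored) binding fold change against
  a per-region motif-composition statistic, reporting the posterior mean
  and +/- 1 s.d. band of the latent function (RBF kernel plus independent
  noise, hyperparameters by marginal-likelihood maximisation).
* Selection of single-site regions (exactly one recognisable half-site),
  where the two receptors act at the very same base pairs.
* A one-sided test of greater-than-additive loss: the double-depletion
  log2 fold change versus the sum of the single depletions.
* Pearson correlation of fold changes between contrasts over a shared
  differentially-expressed gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .motifs import MotifHit


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gaussian-process trend


@dataclass
class TrendFit:
    x: np.ndarray
    y: np.ndarray
    x_pred: np.ndarray
    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    kernel_params: dict  # length_scale, signal_var, noise_var
    log_marginal: float
    jitter: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x_pred, "mean": self.posterior_mean,
                             "sd": self.posterior_sd})


def _rbf(xa: np.ndarray, xb: np.ndarray, ls: float, sig: float) -> np.ndarray:
    d2 = (xa[:, None] - xb[None, :]) ** 2
    return sig * np.exp(-0.5 * d2 / ls**2)


def _gp_solve(x, y, ls, sig, noise, x_pred, max_jitter=1e-4):
    """Exact GP posterior of the latent function; returns mean, sd, jitter
    used and the Cholesky factor pieces for the marginal likelihood."""
    n = len(x)
    K = _rbf(x, x, ls, sig)
    jitter = 0.0
    while True:
        try:
            L = np.linalg.cholesky(K + (noise + jitter) * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 10
            if jitter > max_jitter:
                raise ParameterError("kernel matrix remains ill-conditioned "
                                     f"at jitter {jitter:g}")
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Ks = _rbf(x_pred, x, ls, sig)
    mean = Ks @ alpha
    v = np.linalg.solve(L, Ks.T)
    var = sig - np.sum(v**2, axis=0)
    var = np.clip(var, 0.0, None)
    nll = 0.5 * y @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)
    return mean, np.sqrt(var), jitter, nll


def gp_trend(x: Sequence[float], y: Sequence[float],
             x_pred: Sequence[float] | None = None, optimise: bool = True,
             init: dict | None = None, n_restarts: int = 3, seed: int = 0,
             centre: bool = True) -> TrendFit:
    """Exact GP regression with an RBF + independent-noise kernel.

    Initial hyperparameters: length-scale = x-range / 5, signal variance =
    var(y), noise variance = var(y) / 10; optimised by L-BFGS on the log
    marginal likelihood (in log-parameter space) with seeded restarts when
    ``optimise`` is set, else held fixed. ``y`` is mean-centred for the
    fit and the posterior mean is shifted back.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be aligned 1-d arrays")
    if len(x) < 5:
        raise ParameterError("need at least 5 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("non-finite values in input")
    x_pred = np.linspace(x.min(), x.max(), 100) if x_pred is None else np.asarray(x_pred, float)

    ymean = y.mean() if centre else 0.0
    yc = y - ymean
    xrange_ = max(x.max() - x.min(), 1e-12)
    vy = max(yc.var(), 1e-12)
    defaults = {"length_scale": xrange_ / 5, "signal_var": vy, "noise_var": vy / 10}
    if init:
        defaults.update(init)
    theta0 = np.log([defaults["length_scale"], defaults["signal_var"],
                     defaults["noise_var"]])

    def nll_of(theta: np.ndarray) -> float:
        ls, sig, noise = np.exp(theta)
        try:
            *_, nll = _gp_solve(x, yc, ls, sig, noise, x_pred[:1])
        except ParameterError:
            return 1e10
        return nll

    best_theta = theta0
    if optimise:
        rng = np.random.default_rng(seed)
        starts = [theta0] + [theta0 + rng.normal(0, 0.7, 3) for _ in range(n_restarts - 1)]
        best_val = np.inf
        for t0 in starts:
            res = optimize.minimize(nll_of, t0, method="L-BFGS-B",
                                    bounds=[(-12, 12)] * 3)
            if res.fun < best_val:
                best_val, best_theta = res.fun, res.x
    ls, sig, noise = np.exp(best_theta)
    mean, sd, jitter, nll = _gp_solve(x, yc, ls, sig, noise, x_pred)
    return TrendFit(x=x, y=y, x_pred=x_pred, posterior_mean=mean + ymean,
                    posterior_sd=sd,
                    kernel_params={"length_scale": float(ls),
                                   "signal_var": float(sig),
                                   "noise_var": float(noise)},
                    log_marginal=float(-nll), jitter=jitter)


# ---------------------------------------------------------------------------
# Single-site cooperativity


def single_site_regions(hits_by_region: Mapping[str, Sequence[MotifHit]],
                        region_ids: Sequence[str]) -> list[str]:
    """Regions harbouring exactly one recognisable half-site hit."""
    return [rid for rid in region_ids if len(hits_by_region.get(rid, ())) == 1]


@dataclass
class AdditivityResult:
    deltas: np.ndarray
    statistic: float
    pvalue: float
    computable: bool

    @property
    def median_delta(self) -> float:
        return float(np.median(self.deltas)) if len(self.deltas) else float("nan")


def additivity_test(fc_e: Sequence[float], fc_n: Sequence[float],
                    fc_en: Sequence[float]) -> AdditivityResult:
    """One-sided test of greater-than-additive loss on the log2 scale.

    delta = fc_double - (fc_single_E + fc_single_N); the one-sided
    Wilcoxon signed-rank test asks whether the deltas are shifted below
    zero (the double depletion removes more binding than the singles
    predict). Exact additivity everywhere gives p ~ 0.5. Fewer than 6
    regions is reported as not computable.
    """
    fc_e, fc_n, fc_en = (np.asarray(v, float) for v in (fc_e, fc_n, fc_en))
    if not (fc_e.shape == fc_n.shape == fc_en.shape):
        raise ParameterError("fold-change vectors must be aligned")
    deltas = fc_en - (fc_e + fc_n)
    if len(deltas) < 6:
        return AdditivityResult(deltas, float("nan"), float("nan"), False)
    stat, p = stats.wilcoxon(deltas, alternative="less", zero_method="zsplit",
                             method="approx")
    return AdditivityResult(deltas, float(stat), float(p), True)


# ---------------------------------------------------------------------------
# Fold-change correlation


def foldchange_correlation(fc_self: Mapping[str, float],
                           fc_external: Mapping[str, float],
                           de_self: Iterable[str] = (),
                           de_external: Iterable[str] = (),
                           rule: str = "union") -> tuple[float, int]:
    """Pearson r of per-gene fold changes between two contrasts.

    The gene set is the intersection of genes present in both mappings,
    restricted (when DE calls are given) to genes called differentially
    expressed in either contrast (``union``, default) or in both
    (``intersection``). Returns (r, n); fewer than 3 shared genes gives
    (nan, n).
    """
    if rule not in ("union", "intersection"):
        raise ParameterError("rule must be 'union' or 'intersection'")
    shared = set(fc_self) & set(fc_external)
    de_self, de_external = set(de_self), set(de_external)
    if de_self or de_external:
        de = de_self | de_external if rule == "union" else de_self & de_external
        shared &= de
    genes = sorted(shared)
    n = len(genes)
    if n < 3:
        return float("nan"), n
    a = np.array([fc_self[g] for g in genes])
    b = np.array([fc_external[g] for g in genes])
    r, _ = stats.pearsonr(a, b)
    return float(r), n
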