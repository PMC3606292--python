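"""Convergence assessment and posterior predictive checking.

Gelman-Rubin potential scale reduction factor (classic multi-chain
form, no chain splitting): with C chains of N draws, chain means
m_c and within-chain variances s_c^2,

    W = mean_c s_c^2
    B = N * var_c(m_c)            (both variances with n-1 denominators)
    var_plus = (N - 1)/N * W + B/N
    rhat = sqrt(max(var_plus / W, 1))

Posterior predictive checks replicate the detection data from each
retained draw and compare a Freeman-Tukey discrepancy on species x site
detection counts between observed and replicated data; the Bayesian
p-value is the fraction of draws whose replicate discrepancy is at
least the observed one. The discrepancy statistic is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_rng
from .data import DetectionData
from .families import SpeciesParams
from .model import detection_prob_array


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor of one scalar parameter.

    ``chains`` is (n_chains, n_draws). Returns nan (flagged undefined)
    when the within-chain variance is zero.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    n = x.shape[1]
    within = x.var(axis=1, ddof=1).mean()
    between = n * x.mean(axis=1).var(ddof=1)
    if within == 0:
        return np.nan
    var_plus = (n - 1) / n * within + between / n
    # var_plus/W < 1 can only arise from finite-sample noise (e.g. B = 0
    # for duplicated chains); floor the ratio so rhat >= 1 always.
    return float(np.sqrt(max(var_plus / within, 1.0)))


def effective_sample_size(chains) -> float:
    """Autocorrelation-based effective sample size of pooled chains.

    Uses Geyer's initial-positive-sequence truncation on the
    chain-averaged autocorrelation function.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None]
    C, n = x.shape
    if n < 4:
        return float(C * n)
    xc = x - x.mean(axis=1, keepdims=True)
    var = xc.var(axis=1).mean()
    if var == 0:
        return np.nan
    max_lag = n - 1
    rho = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        rho[lag - 1] = (xc[:, :-lag] * xc[:, lag:]).mean() / var
    # sum consecutive-lag pairs while they stay positive
    tau = 1.0
    for k in range(0, max_lag - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(C * n / tau)


def rhat_table(draws, include_species: bool = False) -> pd.DataFrame:
    """Gelman-Rubin statistic and effective sample size for every scalar
    parameter in the draws.

    Hyper-parameters only by default; ``include_species`` adds all
    species-level coefficients.
    """
    rows = []
    for name, ch in draws.scalar_chains().items():
        if not include_species and "[" in name and not name.startswith(("mu[", "sigma[")):
            continue
        rows.append({"parameter": name, "rhat": gelman_rubin(ch),
                     "ess": effective_sample_size(ch)})
    return pd.DataFrame(rows)


def freeman_tukey(observed: np.ndarray, expected: np.ndarray) -> float:
    """Freeman-Tukey discrepancy: sum of (sqrt(obs) - sqrt(exp))^2."""
    return float(((np.sqrt(observed) - np.sqrt(expected)) ** 2).sum())


@dataclass
class PpcResult:
    """Observed/replicated discrepancies per draw and the Bayesian p-value."""

    d_obs: np.ndarray
    d_rep: np.ndarray
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d_obs": self.d_obs, "d_rep": self.d_rep})


def posterior_predictive_check(data: DetectionData, draws, rng,
                               max_draws: int = 500,
                               statistic=freeman_tukey) -> PpcResult:
    """Posterior predictive check of the detection layer.

    For each retained draw (thinned to at most ``max_draws``): simulate
    replicate detections from the draw's (z, parameters), reduce
    observed and replicate data to species x site detection counts, and
    evaluate the discrepancy of each against its expectation under the
    draw. p-value = fraction of draws with d_rep >= d_obs.
    """
    rng = as_rng(rng)
    layout = draws.layout
    z_all = draws.z_flat()
    sp_all = draws.species.reshape((-1,) + draws.species.shape[2:])
    n_total = z_all.shape[0]
    idx = np.arange(n_total)
    if n_total > max_draws:
        step = n_total / max_draws
        idx = np.unique((np.arange(max_draws) * step).astype(int))
    y_obs = (data.y & data.obs_mask).astype(float)
    obs_counts = y_obs.sum(axis=(2, 3))  # species x site
    d_obs = np.empty(idx.size)
    d_rep = np.empty(idx.size)
    for j, n in enumerate(idx):
        params = SpeciesParams(layout, sp_all[n])
        z = z_all[n]
        p = detection_prob_array(params, data.design)
        p_eff = p * z[:, :, :, None] * data.obs_mask
        expected = p_eff.sum(axis=(2, 3))
        y_rep = (rng.random(p.shape) < p_eff).astype(float)
        rep_counts = y_rep.sum(axis=(2, 3))
        d_obs[j] = statistic(obs_counts, expected)
        d_rep[j] = statistic(rep_counts, expected)
    return PpcResult(d_obs=d_obs, d_rep=d_rep,
                     p_value=float((d_rep >= d_obs).mean()))


def diagnostic_report(data: DetectionData, draws, rng,
                      include_species: bool = False) -> dict:
    """Convergence table plus PPC summary in one structure."""
    rt = rhat_table(draws, include_species=include_species)
    ppc = posterior_predictive_check(data, draws, rng)
    finite = rt["rhat"].dropna()
    return {
        "rhat": rt,
        "max_rhat": float(finite.max()) if len(finite) else np.nan,
        "ppc_p_value": ppc.p_value,
        "ppc": ppc,
    }
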