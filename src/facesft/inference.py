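"""Simulation-based likelihoods and posterior sampling.

The logical-rule models have no tractable likelihood, so the likelihood of
a parameter vector is approximated by simulation (probability density
approximation, PDA): a large synthetic sample is drawn from the model for
each stimulus, split by response, and kernel-smoothed into defective
densities (class probability times the class-conditional RT density).  The
log-likelihood of the data is the sum of log defective densities at the
observed (response, RT) pairs.

Posteriors are sampled with differential-evolution MCMC (DE-MCMC):
proposals are formed from scaled differences of two other chains' states
plus a small uniform jitter, giving scale-free moves well suited to the
correlated posteriors of accumulator models.  Because the PDA likelihood
is re-estimated with fresh simulation noise at every evaluation, the
sampler is pseudo-marginal in character.

Model comparison uses the deviance information criterion
DIC = D-bar + 2 * p_D with p_D = D-bar - D(theta-bar), and Akaike-style
weights exp(-delta_i / 2) normalized over the candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .rule_models import ModelSpec, simulate_model

__all__ = [
    "pda_loglik",
    "defective_densities",
    "de_mcmc",
    "PosteriorFit",
    "dic",
    "dic_weights",
]

DENSITY_FLOOR = 1e-10
_N_BINS = 512


def _silverman_bw(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * x.size ** (-0.2)


def _binned_kde(samples: np.ndarray, eval_at: np.ndarray) -> np.ndarray:
    """Gaussian KDE with Silverman bandwidth via a binned pipeline.

    Histogram the simulants, convolve with a Gaussian kernel whose sigma
    is the bandwidth in bin units, and linearly interpolate at the
    evaluation points.  The grid is padded by four bandwidths so no mass
    is clipped.  The inner loops are compiled (see ``_kernels.kde_eval``).
    """
    from ._kernels import kde_eval

    bw = _silverman_bw(samples)
    return kde_eval(np.ascontiguousarray(samples, dtype=np.float64),
                    np.ascontiguousarray(eval_at, dtype=np.float64),
                    float(bw), _N_BINS)


def defective_densities(responses: np.ndarray, rts: np.ndarray,
                        eval_rts: dict[str, np.ndarray]
                        ) -> dict[str, np.ndarray]:
    """Defective density of each response class at the requested RTs.

    The defective density of class ``r`` is P(response = r) times the
    kernel-density estimate of that class's RT distribution, so the two
    classes jointly integrate to one.
    """
    out = {}
    n = rts.size
    for resp, at in eval_rts.items():
        mask = responses == resp
        k = int(mask.sum())
        if k < 2 or at.size == 0:
            out[resp] = np.zeros(at.size)
            continue
        out[resp] = (k / n) * _binned_kde(rts[mask], at)
    return out


def pda_loglik(spec: ModelSpec, trials, n_sim: int,
               seed: int | np.random.Generator,
               floor: float = DENSITY_FLOOR) -> float:
    """Probability-density-approximation log-likelihood of a trial table.

    ``trials`` holds one participant/condition's rows with columns
    ``x_level, y_level, response, rt_ms`` (or the pre-grouped structure
    from :func:`group_trials`).  For every stimulus present,
    ``n_sim`` (response, RT) pairs are simulated from ``spec`` and turned
    into defective densities; the log-likelihood is the sum over trials of
    the log density at the observed RT, floored at ``floor``.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_stim = trials if isinstance(trials, dict) else group_trials(trials)
    spec = _with_contaminant_range(spec, by_stim)
    total = 0.0
    for (x, y), eval_rts in by_stim.items():
        responses, rts = simulate_model(spec, int(x), int(y), n_sim, rng)
        dens = defective_densities(responses, rts, eval_rts)
        for resp, d in dens.items():
            total += float(np.log(np.maximum(d, floor)).sum())
    return total


def group_trials(trials: pd.DataFrame
                 ) -> dict[tuple[int, int], dict[str, np.ndarray]]:
    """Pre-split a trial table into per-stimulus, per-response RT arrays.

    The PDA likelihood accepts this structure directly, which avoids
    re-grouping the data on every one of the sampler's evaluations.
    """
    out = {}
    for (x, y), cell in trials.groupby(["x_level", "y_level"]):
        out[(int(x), int(y))] = {
            resp: cell.loc[cell["response"] == resp, "rt_ms"].to_numpy()
            for resp in ("target", "contrast")}
    return out


def _with_contaminant_range(spec: ModelSpec, by_stim: dict) -> ModelSpec:
    """Fill the contaminant RT range from the data when not configured.

    Contaminant trials are uniform over the observed RT range of the
    experimental condition being fit.
    """
    from dataclasses import replace

    if spec.architecture in ("mixed_serial_contaminant",
                             "mixed_parallel_contaminant") \
            and spec.contaminant_range is None:
        lo = min(a.min() for d in by_stim.values() for a in d.values() if a.size)
        hi = max(a.max() for d in by_stim.values() for a in d.values() if a.size)
        return replace(spec, contaminant_range=(float(lo), float(hi)))
    return spec


# ---------------------------------------------------------------------------
# DE-MCMC


@dataclass
class PosteriorFit:
    """Retained DE-MCMC samples plus the traces DIC needs.

    ``chains`` has shape (n_chains, n_kept, n_params); ``loglik`` the
    matching log-likelihood trace.  ``deviance_at_mean`` is D evaluated at
    the posterior-mean parameter vector.
    """

    param_names: list[str]
    chains: np.ndarray
    loglik: np.ndarray
    deviance_at_mean: float
    acceptance_rate: float
    seed: int
    n_sim: int = 0

    @property
    def deviance(self) -> np.ndarray:
        return -2.0 * self.loglik

    def posterior_mean(self) -> dict[str, float]:
        flat = self.chains.reshape(-1, self.chains.shape[-1])
        return dict(zip(self.param_names, flat.mean(axis=0)))

    def summary(self) -> pd.DataFrame:
        flat = self.chains.reshape(-1, self.chains.shape[-1])
        q = np.percentile(flat, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame({
            "mean": flat.mean(axis=0), "sd": flat.std(ddof=1, axis=0),
            "q2.5": q[0], "median": q[1], "q97.5": q[2],
        }, index=self.param_names)


def de_mcmc(loglik_fn, priors: dict[str, tuple[float, float]],
            n_chains: int | None = None, n_iter: int = 500,
            burn_in: int | None = None, seed: int = 0,
            gamma: float | None = None, jitter: float = 0.001,
            init: np.ndarray | None = None,
            refresh: bool = False) -> PosteriorFit:
    """Differential-evolution MCMC with uniform priors.

    ``loglik_fn(theta, rng)`` returns the log-likelihood of parameter
    vector ``theta`` (fresh simulation noise may be drawn from ``rng``).
    ``priors`` maps parameter names to uniform support bounds.  Proposals
    are ``theta_i + gamma * (theta_j - theta_k) + eps`` with distinct
    chains ``j, k != i`` and ``eps ~ Uniform(-jitter, jitter)``; the
    default ``gamma = 2.38 / sqrt(2 d)``.  Burn-in defaults to half the
    iterations; chains default to ``3 d`` (at least d + 2).

    With a stochastic likelihood estimate (PDA), ``refresh=True``
    re-estimates the current chain's log-likelihood alongside each
    proposal, preventing chains from sticking to lucky overestimates at
    the cost of doubling the evaluations per iteration.
    """
    names = list(priors)
    d = len(names)
    lo = np.array([priors[k][0] for k in names])
    hi = np.array([priors[k][1] for k in names])
    if np.any(hi <= lo):
        raise ValueError("empty prior support")
    if n_chains is None:
        n_chains = 3 * d
    n_chains = max(n_chains, max(3, d + 1))
    if burn_in is None:
        burn_in = n_iter // 2
    if gamma is None:
        gamma = 2.38 / math.sqrt(2 * d)
    rng = np.random.default_rng(seed)

    if init is None:
        theta = rng.uniform(lo, hi, size=(n_chains, d))
    else:
        theta = np.array(init, dtype=float)
        if theta.shape != (n_chains, d):
            raise ValueError("init must have shape (n_chains, n_params)")
        if np.any(theta < lo) or np.any(theta > hi):
            raise ValueError("initial points outside prior support")
    ll = np.array([loglik_fn(theta[i], rng) for i in range(n_chains)])
    if not np.all(np.isfinite(ll)):
        # re-draw chains that start in a region of floored likelihood
        for i in np.flatnonzero(~np.isfinite(ll)):
            for _ in range(50):
                theta[i] = rng.uniform(lo, hi)
                ll[i] = loglik_fn(theta[i], rng)
                if np.isfinite(ll[i]):
                    break
            else:
                raise RuntimeError("could not find a feasible initial point")

    kept_theta = np.empty((n_chains, n_iter - burn_in, d))
    kept_ll = np.empty((n_chains, n_iter - burn_in))
    n_accept = 0
    for it in range(n_iter):
        for i in range(n_chains):
            j, k = _pick_pair(rng, n_chains, i)
            prop = theta[i] + gamma * (theta[j] - theta[k]) \
                + rng.uniform(-jitter, jitter, d)
            if np.any(prop < lo) or np.any(prop > hi):
                continue  # zero prior density
            ll_prop = loglik_fn(prop, rng)
            if refresh:
                ll[i] = loglik_fn(theta[i], rng)
            if math.log(rng.random() + 1e-300) < ll_prop - ll[i]:
                theta[i] = prop
                ll[i] = ll_prop
                n_accept += 1
        if it >= burn_in:
            kept_theta[:, it - burn_in] = theta
            kept_ll[:, it - burn_in] = ll

    theta_bar = kept_theta.reshape(-1, d).mean(axis=0)
    dev_at_mean = -2.0 * loglik_fn(theta_bar, rng)
    return PosteriorFit(param_names=names, chains=kept_theta, loglik=kept_ll,
                        deviance_at_mean=float(dev_at_mean),
                        acceptance_rate=n_accept / (n_iter * n_chains),
                        seed=seed)


def _pick_pair(rng: np.random.Generator, n: int, i: int) -> tuple[int, int]:
    while True:
        j, k = rng.integers(0, n, 2)
        if j != k and j != i and k != i:
            return int(j), int(k)


def dic(fit: PosteriorFit) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    p_D = D-bar - D(theta-bar); DIC = D-bar + 2 * p_D.
    """
    dev = fit.deviance
    if not np.all(np.isfinite(dev)):
        bad = np.argwhere(~np.isfinite(dev))
        raise ValueError(f"non-finite deviances at (chain, iter) {bad[:10].tolist()}")
    d_bar = float(dev.mean())
    p_d = d_bar - fit.deviance_at_mean
    return d_bar + 2.0 * p_d, p_d


def dic_weights(dics: dict[str, float] | list[float]) -> dict[str, float] | np.ndarray:
    """Akaike-style model weights from DIC values.

    w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2) with
    delta_i = DIC_i - min DIC; invariant to adding a constant to all DICs.
    """
    if isinstance(dics, dict):
        keys = list(dics)
        vals = np.array([dics[k] for k in keys], dtype=float)
    else:
        keys = None
        vals = np.asarray(dics, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("need at least two finite DICs")
    delta = vals - vals[finite].min()
    w = np.where(finite, np.exp(-delta / 2.0), 0.0)
    w = w / w.sum()
    if keys is None:
        return w
    return dict(zip(keys, w))
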