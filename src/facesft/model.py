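"""Fitting interface for the logical-rule architecture models.

:class:`LogicalRuleModel` binds one participant/condition's trial data to
an architecture and a prior, exposing ``fit()`` which runs DE-MCMC over
the PDA likelihood and returns a :class:`LogicalRuleResults` carrying the
chains, DIC, posterior summaries and posterior-predictive simulation.

Typical use::

    model = LogicalRuleModel(table, architecture="mixed_serial_parallel")
    res = model.fit(n_iter=400, seed=1)
    res.summary()          # posterior table
    res.dic, res.p_d       # model comparison inputs
    res.posterior_predictive()

``compare_fits`` turns a set of results into a DIC table with weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StimulusDesign, assign_role, default_design
from .inference import PosteriorFit, de_mcmc, dic, dic_weights, pda_loglik
from .io import TrialTable
from .rule_models import (ARCHITECTURES, GRTPerception, LBAParams, ModelSpec,
                          model_predictions)

__all__ = ["LogicalRuleModel", "LogicalRuleResults", "compare_fits",
           "default_priors"]

_FREE_DRIFT_ROLES = ("HH", "HL", "LH", "LL", "Ex", "Ix", "Ey", "Iy", "R")

#: shared accumulator parameters every architecture estimates
_SHARED_LBA = ("A", "b_target", "b_contrast", "s", "t0")
_SHARED_GRT = ("sigma_x", "sigma_y", "bound_x", "bound_y")

_EXTRA_PARAMS = {
    "serial_st": ("p_x",),
    "parallel_st": (),
    "coactive": (),
    "mixed_serial_parallel": ("p_x", "p_serial", "m", "A_parallel"),
    "mixed_serial_contaminant": ("p_x", "p0"),
    "mixed_parallel_contaminant": ("p0",),
    "free_drift": tuple(f"nu_{r}" for r in _FREE_DRIFT_ROLES),
}


def param_names(architecture: str) -> list[str]:
    """Ordered free-parameter names of an architecture."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if architecture == "free_drift":
        return list(_EXTRA_PARAMS["free_drift"]) + list(_SHARED_LBA)
    return list(_SHARED_GRT) + list(_SHARED_LBA) \
        + list(_EXTRA_PARAMS[architecture])


def default_priors(architecture: str, design: StimulusDesign
                   ) -> dict[str, tuple[float, float]]:
    """Uniform prior supports for an architecture's parameters.

    Perceptual SDs cover (0.01, 5) coordinate units; decision bounds span
    the coordinate range widened by 2 units on each side; start ranges and
    thresholds cover the millisecond scales human RTs imply; probabilities
    and free drifts are uniform on (0, 1).
    """
    span = (min(design.x_coords + design.y_coords) - 2.0,
            max(design.x_coords + design.y_coords) + 2.0)
    base = {
        "sigma_x": (0.01, 5.0), "sigma_y": (0.01, 5.0),
        "bound_x": span, "bound_y": span,
        "A": (0.0, 3000.0), "b_target": (1.0, 5000.0),
        "b_contrast": (1.0, 5000.0), "s": (0.05, 1.0), "t0": (50.0, 1000.0),
        "p_x": (0.0, 1.0), "p_serial": (0.0, 1.0), "m": (0.1, 10.0),
        "A_parallel": (0.0, 3000.0), "p0": (0.0, 1.0),
    }
    base.update({f"nu_{r}": (0.0, 1.0) for r in _FREE_DRIFT_ROLES})
    return {name: base[name] for name in param_names(architecture)}


def spec_from_params(architecture: str, params: dict[str, float],
                     design: StimulusDesign) -> ModelSpec:
    """Assemble a ModelSpec from a named parameter vector."""
    lba = LBAParams(A=params["A"], b_target=params["b_target"],
                    b_contrast=params["b_contrast"], s=params["s"],
                    t0=params["t0"])
    if architecture == "free_drift":
        nu = {r: params[f"nu_{r}"] for r in _FREE_DRIFT_ROLES}
        return ModelSpec(architecture=architecture, lba=lba, nu=nu)
    grt = GRTPerception.from_design(design, sigma_x=params["sigma_x"],
                                    sigma_y=params["sigma_y"],
                                    bound_x=params["bound_x"],
                                    bound_y=params["bound_y"])
    kwargs = {}
    for extra in _EXTRA_PARAMS[architecture]:
        kwargs[extra] = params[extra]
    return ModelSpec(architecture=architecture, lba=lba, grt=grt, **kwargs)


class LogicalRuleModel:
    """One participant's logical-rule model, ready to fit.

    Parameters
    ----------
    data
        A :class:`~facesft.io.TrialTable` or a trial DataFrame for a single
        participant and condition (columns ``x_level, y_level, response,
        rt_ms``).
    architecture
        One of the seven architecture tags.
    design
        Stimulus design providing the fixed perceptual coordinates.
    priors
        Uniform prior supports; defaults to :func:`default_priors`.
    n_sim
        Simulated trials per stimulus per PDA likelihood evaluation.
    """

    def __init__(self, data: TrialTable | pd.DataFrame, architecture: str,
                 design: StimulusDesign | None = None,
                 priors: dict[str, tuple[float, float]] | None = None,
                 n_sim: int = 50_000):
        if isinstance(data, TrialTable):
            if design is None:
                design = data.design
            data = data.df
        if design is None:
            design = default_design()
        if "participant" in data.columns and data["participant"].nunique() > 1:
            raise ValueError("fit one participant at a time")
        self.data = data.reset_index(drop=True)
        from .inference import group_trials
        self._by_stim = group_trials(self.data)
        self.architecture = architecture
        self.design = design
        self.param_names = param_names(architecture)
        self.priors = priors or default_priors(architecture, design)
        if list(self.priors) != self.param_names:
            raise ValueError("priors must cover exactly the architecture's "
                             f"parameters {self.param_names}")
        self.n_sim = int(n_sim)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, architecture: str,
                       **kwargs) -> "LogicalRuleModel":
        return cls(df, architecture, **kwargs)

    def spec(self, theta: np.ndarray | dict[str, float]) -> ModelSpec:
        if not isinstance(theta, dict):
            theta = dict(zip(self.param_names, np.asarray(theta, float)))
        return spec_from_params(self.architecture, theta, self.design)

    def loglik(self, theta: np.ndarray, rng: np.random.Generator,
               n_sim: int | None = None) -> float:
        """PDA log-likelihood of a parameter vector (fresh simulation noise)."""
        try:
            spec = self.spec(theta)
        except ValueError:
            return -np.inf
        try:
            return pda_loglik(spec, self._by_stim, n_sim or self.n_sim, rng)
        except RuntimeError:
            # pathological corner of the prior (e.g. all drifts negative)
            return -np.inf

    # -- maximum-likelihood search used to initialize the sampler --------
    #
    # The PDA surface with a frozen simulation seed is deterministic, so
    # local optimizers apply.  The perceptual parameters are searched in
    # standardized-distance coordinates (z1 = (mu1 - D) / sigma and the
    # log level spacing), which straightens the strong (sigma, D) ridge of
    # the natural parameterization; the remaining parameters are searched
    # on their prior box, normalized to [0, 1].

    _GRT_KEYS = ("sigma_x", "sigma_y", "bound_x", "bound_y")

    @property
    def _has_grt(self) -> bool:
        return self.architecture != "free_drift"

    def _other_keys(self) -> list[str]:
        if not self._has_grt:
            return list(self.param_names)
        return [k for k in self.param_names if k not in self._GRT_KEYS]

    def _z_to_theta(self, z: np.ndarray) -> np.ndarray:
        names = self.param_names
        lo = np.array([self.priors[k][0] for k in names])
        hi = np.array([self.priors[k][1] for k in names])
        th = np.empty(len(names))
        idx = {k: i for i, k in enumerate(names)}
        off = 0
        if self._has_grt:
            x1, x2 = self.design.x_coords[1], self.design.x_coords[2]
            y1, y2 = self.design.y_coords[1], self.design.y_coords[2]
            sx = (x2 - x1) / np.exp(z[1])
            sy = (y2 - y1) / np.exp(z[3])
            th[idx["sigma_x"]], th[idx["sigma_y"]] = sx, sy
            th[idx["bound_x"]] = x1 - sx * z[0]
            th[idx["bound_y"]] = y1 - sy * z[2]
            off = 4
        for r, k in zip(z[off:], self._other_keys()):
            th[idx[k]] = lo[idx[k]] + r * (hi[idx[k]] - lo[idx[k]])
        return th

    def _z_bounds(self) -> list[tuple[float, float]]:
        zb = [(-3.0, 4.0), (-1.2, 1.5), (-3.0, 4.0), (-1.2, 1.5)] \
            if self._has_grt else []
        return zb + [(0.0, 1.0)] * len(self._other_keys())

    def _informed_start(self, rng: np.random.Generator) -> np.ndarray:
        """Moment-based random starting point.

        Non-decision time starts below the fastest RT, thresholds near the
        implied mean decision time, standardized distances in the range a
        threshold-calibrated design produces, and free drifts near each
        stimulus's observed target-response proportion.
        """
        rt = self.data["rt_ms"].to_numpy()
        rt_min, rt_mean = float(rt.min()), float(rt.mean())
        vals: dict[str, float] = {"t0": rng.uniform(0.4, 0.9) * rt_min}
        dt = max(rt_mean - vals["t0"], 100.0)
        vals["b_target"] = rng.uniform(0.5, 0.95) * dt
        vals["b_contrast"] = vals["b_target"] * rng.uniform(0.8, 1.6)
        vals["A"] = rng.uniform(0.05, 0.8) * vals["b_target"]
        vals["A_parallel"] = rng.uniform(0.05, 0.8) * vals["b_target"]
        vals["s"] = rng.uniform(0.05, 0.3)
        vals["p_x"] = rng.uniform(0.1, 0.9)
        vals["p_serial"] = rng.uniform(0.2, 0.8)
        vals["m"] = rng.uniform(0.6, 2.0)
        vals["p0"] = rng.uniform(0.01, 0.2)
        for (x, y), cell in self._by_stim.items():
            n_t = cell["target"].size
            n_c = cell["contrast"].size
            p = n_t / max(n_t + n_c, 1)
            role = f"nu_{assign_role(x, y).value}"
            vals[role] = float(np.clip(p * rng.uniform(0.8, 1.2), 0.05, 0.95))
        z = []
        if self._has_grt:
            z += [rng.uniform(0.2, 1.5), np.log(rng.uniform(0.75, 2.25)),
                  rng.uniform(0.2, 1.5), np.log(rng.uniform(0.75, 2.25))]
        lo = {k: self.priors[k][0] for k in self.param_names}
        hi = {k: self.priors[k][1] for k in self.param_names}
        for k in self._other_keys():
            v = np.clip(vals.get(k, rng.uniform(lo[k], hi[k])), lo[k], hi[k])
            z.append((v - lo[k]) / (hi[k] - lo[k]))
        return np.array(z)

    def fit_map(self, n_starts: int = 10, n_polish: int = 2, seed: int = 0,
                n_sim: int | None = None, frozen_seed: int = 777,
                maxfun: int = 500, maxfev: int = 1500
                ) -> tuple[dict[str, float], float]:
        """Approximate maximum-likelihood point on a frozen PDA surface.

        Runs ``n_starts`` L-BFGS-B searches from moment-informed starting
        points (common random numbers make the objective deterministic),
        polishes the best ``n_polish`` with Powell, and returns the best
        named parameter vector with its log-likelihood.
        """
        from scipy import optimize

        n_sim = n_sim or self.n_sim
        names = self.param_names
        lo = np.array([self.priors[k][0] for k in names])
        hi = np.array([self.priors[k][1] for k in names])

        def negll(z: np.ndarray) -> float:
            th = self._z_to_theta(z)
            if np.any(th < lo) or np.any(th > hi):
                return 1e10
            return -self.loglik(th, np.random.default_rng(frozen_seed),
                                n_sim=n_sim)

        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA7)))
        zb = self._z_bounds()
        stage1 = []
        for _ in range(n_starts):
            res = optimize.minimize(negll, self._informed_start(rng),
                                    method="L-BFGS-B", bounds=zb,
                                    options={"maxfun": maxfun, "eps": 8e-3})
            stage1.append(res)
        stage1.sort(key=lambda r: r.fun)
        best = stage1[0]
        for r0 in stage1[:n_polish]:
            res = optimize.minimize(negll, r0.x, method="Powell",
                                    options={"maxfev": maxfev, "xtol": 1e-4,
                                             "ftol": 1e-5})
            if res.fun < best.fun:
                best = res
        theta = self._z_to_theta(best.x)
        return dict(zip(names, theta)), float(-best.fun)

    def fit(self, n_chains: int | None = None, n_iter: int = 200,
            burn_in: int | None = None, seed: int = 0,
            n_sim: int | None = None, init: str | np.ndarray = "map",
            n_starts: int = 10, refresh: bool = True,
            init_spread: float = 0.08,
            map_options: dict | None = None) -> "LogicalRuleResults":
        """Sample the posterior by DE-MCMC over the PDA likelihood.

        ``init="map"`` (default) first locates the likelihood mode with
        :meth:`fit_map` and starts the chains from a log-normal cloud
        around it; ``init="prior"`` starts from prior draws (requires many
        more iterations to converge).  ``refresh`` re-estimates the
        current likelihood alongside each proposal (see :func:`de_mcmc`).
        """
        n_sim = n_sim or self.n_sim
        d = len(self.param_names)
        if n_chains is None:
            n_chains = 2 * d
        lo = np.array([self.priors[k][0] for k in self.param_names])
        hi = np.array([self.priors[k][1] for k in self.param_names])
        if isinstance(init, str) and init == "map":
            theta0, _ = self.fit_map(n_starts=n_starts, seed=seed,
                                     n_sim=n_sim, **(map_options or {}))
            x0 = np.array([theta0[k] for k in self.param_names])
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC1)))
            cloud = x0 * np.exp(rng.normal(0.0, init_spread,
                                           (n_chains, d)))
            cloud += rng.normal(0.0, 1e-3, (n_chains, d))  # zero-safe jitter
            init_arr = np.clip(cloud, lo, hi)
        elif isinstance(init, str) and init == "prior":
            init_arr = None
        else:
            init_arr = np.asarray(init)
        fit = de_mcmc(lambda th, rg: self.loglik(th, rg, n_sim=n_sim),
                      self.priors, n_chains=n_chains, n_iter=n_iter,
                      burn_in=burn_in, seed=seed, init=init_arr,
                      refresh=refresh)
        fit.n_sim = n_sim
        return LogicalRuleResults(model=self, posterior=fit)


@dataclass
class LogicalRuleResults:
    """Posterior fit of one architecture to one participant's data."""

    model: LogicalRuleModel
    posterior: PosteriorFit

    def __post_init__(self) -> None:
        self.dic, self.p_d = dic(self.posterior)

    def posterior_mean(self) -> dict[str, float]:
        return self.posterior.posterior_mean()

    def posterior_mean_spec(self) -> ModelSpec:
        return self.model.spec(self.posterior_mean())

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD/quantiles per parameter, plus DIC footer."""
        table = self.posterior.summary()
        table.attrs["architecture"] = self.model.architecture
        table.attrs["dic"] = self.dic
        table.attrs["p_d"] = self.p_d
        table.attrs["acceptance_rate"] = self.posterior.acceptance_rate
        return table

    def posterior_predictive(self, n_sim: int = 10_000,
                             seed: int = 0) -> pd.DataFrame:
        """Response probabilities and RT quartiles at the posterior mean."""
        return model_predictions(self.posterior_mean_spec(), self.model.design,
                                 n_sim=n_sim, seed=seed)

    def plot_posterior_predictive(self, ax=None, n_sim: int = 10_000,
                                  seed: int = 0):
        """Observed vs predicted correct-RT quartiles per stimulus."""
        import matplotlib.pyplot as plt

        pred = self.posterior_predictive(n_sim=n_sim, seed=seed)
        data = self.model.data
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        roles, obs_q, pred_q = [], [], []
        for (x, y), cell in data.groupby(["x_level", "y_level"]):
            from .design import assign_role
            role = assign_role(int(x), int(y)).value
            rt = cell["rt_ms"].to_numpy()
            row = pred[(pred["x_level"] == x) & (pred["y_level"] == y)]
            maj = row.loc[row["p"].idxmax()]
            roles.append(role)
            obs_q.append(np.percentile(rt, [25, 50, 75]))
            pred_q.append([maj["q25"], maj["q50"], maj["q75"]])
        xpos = np.arange(len(roles))
        obs_q, pred_q = np.array(obs_q), np.array(pred_q)
        for qi, marker in zip(range(3), ("v", "o", "^")):
            ax.plot(xpos, obs_q[:, qi], marker + "-", color="k",
                    label=f"observed q{(25, 50, 75)[qi]}" if qi == 1 else None)
            ax.plot(xpos, pred_q[:, qi], marker + "--", color="r",
                    label="predicted" if qi == 1 else None)
        ax.set_xticks(xpos, roles)
        ax.set_ylabel("RT (ms)")
        ax.legend()
        return ax


def compare_fits(results: dict[str, "LogicalRuleResults | float"]
                 ) -> pd.DataFrame:
    """DIC comparison table across fitted architectures.

    Accepts results objects or raw DIC floats; returns DIC, p_D (where
    known), DIC weight and a flag on the preferred (smallest-DIC) model.
    """
    dics = {}
    pds = {}
    for name, res in results.items():
        if isinstance(res, LogicalRuleResults):
            dics[name] = res.dic
            pds[name] = res.p_d
        else:
            dics[name] = float(res)
            pds[name] = np.nan
    weights = dic_weights(dics)
    table = pd.DataFrame({
        "dic": pd.Series(dics), "p_d": pd.Series(pds),
        "weight": pd.Series(weights),
    })
    table["best"] = table["dic"] == table["dic"].min()
    return table.sort_values("dic")
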