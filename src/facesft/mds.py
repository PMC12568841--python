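"""Confirmatory multidimensional scaling of the 9-stimulus similarity data.

The similarity study yields 1-8 ratings for all 36 unordered pairs of the
nine composite faces.  Ratings are mapped to dissimilarities (9 - rating)
and fit by a weighted-Minkowski distance model in which all participants
share one stimulus configuration and each participant contributes a single
positive scale weight (an INDSCAL-style individual-differences model):

    d_ij^(p) = w_p * (|x_i - x_j|^r + |y_i - y_j|^r)^(1/r)

Two coordinate models are compared: a *free-monotone* configuration (16
coordinate parameters; each stimulus has its own coordinates, constrained
to increase with the physical level separately within every row and
column, with the first stimulus anchored at the origin) and a
*constrained-grid* configuration (4 parameters; all stimuli lie on a grid
whose level values are shared across rows/columns).  Each is fit with a
city-block metric (r = 1), a Euclidean metric (r = 2), or a free exponent
r in [1, 5], by minimizing the sum of squared deviations (SSD) between
model distances and dissimilarities.  Models are compared with a BIC built
from a Gaussian likelihood whose variance is concentrated out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MdsModelSpec",
    "MdsModel",
    "MdsResults",
    "model_distance",
    "screen_participants",
    "fit_mds",
    "bic_from_ssd",
    "compare_mds_specs",
    "STANDARD_SPECS",
]

MAX_RATING = 8
_R_MIN, _R_MAX = 1.0, 5.0


@dataclass(frozen=True)
class MdsModelSpec:
    """Which coordinate model and metric family to fit.

    ``coordinate_mode`` is "free_monotone" (16 coordinate parameters) or
    "constrained_grid" (4); ``metric`` is "cityblock" (r = 1), "euclidean"
    (r = 2) or "free" (r estimated in [1, 5]).
    """

    coordinate_mode: str
    metric: str

    def __post_init__(self) -> None:
        if self.coordinate_mode not in ("free_monotone", "constrained_grid"):
            raise ValueError(f"unknown coordinate_mode {self.coordinate_mode!r}")
        if self.metric not in ("cityblock", "euclidean", "free"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_coord_params(self) -> int:
        return 16 if self.coordinate_mode == "free_monotone" else 4

    @property
    def fixed_r(self) -> float | None:
        return {"cityblock": 1.0, "euclidean": 2.0, "free": None}[self.metric]


#: the six specs the confirmatory comparison runs over
STANDARD_SPECS = tuple(
    MdsModelSpec(mode, metric)
    for mode in ("free_monotone", "constrained_grid")
    for metric in ("cityblock", "euclidean", "free")
)


def model_distance(coord_i, coord_j, w_p: float, r: float) -> float:
    """Participant-weighted Minkowski distance between two stimuli."""
    if r < 1:
        raise ValueError("Minkowski exponent r must be >= 1")
    if w_p <= 0:
        raise ValueError("participant weight must be positive")
    diff = np.abs(np.asarray(coord_i, float) - np.asarray(coord_j, float))
    return float(w_p * (diff ** r).sum() ** (1.0 / r))


def screen_participants(ratings: pd.DataFrame,
                        dominance_threshold: float = 0.6
                        ) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Remove participants with degenerate response-scale use.

    A participant is removed if any of the eight rating options is unused,
    or if their two most-used options account for more than
    ``dominance_threshold`` of their responses.  Returns the kept rows,
    the removed participant ids, and a per-participant histogram report.
    """
    if len(ratings) == 0:
        raise ValueError("no ratings to screen")
    rows, removed = [], []
    for pid, grp in ratings.groupby("participant"):
        counts = grp["rating"].value_counts().reindex(range(1, MAX_RATING + 1),
                                                      fill_value=0)
        top2 = counts.nlargest(2).sum() / counts.sum()
        uses_all = bool((counts > 0).all())
        keep = uses_all and top2 <= dominance_threshold
        if not keep:
            removed.append(pid)
        row = {"participant": pid, "uses_full_scale": uses_all,
               "top2_fraction": float(top2), "kept": keep}
        row.update({f"n_{v}": int(counts[v]) for v in range(1, MAX_RATING + 1)})
        rows.append(row)
    report = pd.DataFrame(rows)
    kept = ratings[~ratings["participant"].isin(removed)].reset_index(drop=True)
    return kept, removed, report


def bic_from_ssd(ssd: float, k: int, n: int) -> float:
    """BIC of a Gaussian model with variance concentrated at ssd / n.

    -2 log L = n log(ssd / n) + n (1 + log 2 pi), so
    BIC = n log(ssd / n) + n (1 + log 2 pi) + k log n.  Comparable only
    across models fit to the same data.
    """
    if n <= k:
        raise ValueError("need more data points than parameters")
    if ssd < 0:
        raise ValueError("ssd must be non-negative")
    if ssd == 0:
        warnings.warn("perfect fit: BIC degenerates to -inf")
        return -np.inf
    return float(n * np.log(ssd / n) + n * (1.0 + np.log(2.0 * np.pi))
                 + k * np.log(n))


# ---------------------------------------------------------------------------
# fitting machinery

# stimulus index s corresponds to levels (ix, iy) = (s // 3, s % 3)
_IX = np.arange(9) // 3
_IY = np.arange(9) % 3


def _coords_constrained(params: np.ndarray) -> np.ndarray:
    """4 log-increment parameters -> (9, 2) grid coordinates."""
    dx1, dx2, dy1, dy2 = np.exp(params)
    xs = np.array([0.0, dx1, dx1 + dx2])
    ys = np.array([0.0, dy1, dy1 + dy2])
    return np.column_stack([xs[_IX], ys[_IY]])


def _coords_free(params: np.ndarray) -> np.ndarray:
    """16 parameters -> (9, 2) coordinates, monotone within rows/columns.

    X layout: for each y-level, X at x-level 0 (free, except the anchored
    stimulus) followed by two positive log-increments; symmetrically for Y.
    """
    x = np.zeros((3, 3))  # x[iy, ix]
    y = np.zeros((3, 3))  # y[ix, iy]
    p = iter(params)
    for iy in range(3):
        base = 0.0 if iy == 0 else next(p)
        x[iy, 0] = base
        x[iy, 1] = base + np.exp(next(p))
        x[iy, 2] = x[iy, 1] + np.exp(next(p))
    for ix in range(3):
        base = 0.0 if ix == 0 else next(p)
        y[ix, 0] = base
        y[ix, 1] = base + np.exp(next(p))
        y[ix, 2] = y[ix, 1] + np.exp(next(p))
    return np.column_stack([x[_IY, _IX], y[_IX, _IY]])


class MdsModel:
    """INDSCAL-style confirmatory MDS model bound to a ratings table.

    Parameters
    ----------
    ratings
        Long-format frame with columns ``participant, stim_i, stim_j,
        rating`` (already screened).
    spec
        Coordinate-mode / metric combination to fit.
    """

    def __init__(self, ratings: pd.DataFrame, spec: MdsModelSpec):
        if ratings["participant"].nunique() < 2:
            raise ValueError("need at least 2 participants for INDSCAL weights")
        self.ratings = ratings.reset_index(drop=True)
        self.spec = spec
        self.participants = sorted(ratings["participant"].unique())
        self.n_participants = len(self.participants)
        pairs = sorted({(min(i, j), max(i, j))
                        for i, j in zip(ratings["stim_i"], ratings["stim_j"])})
        self._pairs = pairs
        pair_index = {pr: n for n, pr in enumerate(pairs)}
        self._row_pair = np.array([
            pair_index[(min(i, j), max(i, j))]
            for i, j in zip(ratings["stim_i"], ratings["stim_j"])])
        p_index = {p: n for n, p in enumerate(self.participants)}
        self._row_part = np.array([p_index[p] for p in ratings["participant"]])
        self._dissim = (9.0 - ratings["rating"].to_numpy(float))
        self._pi = np.array([i for i, _ in pairs])
        self._pj = np.array([j for _, j in pairs])

    # -- parameter vector layout: [coords | log-weights (n_p - 1) | r?] --

    @property
    def n_params(self) -> int:
        extra = 1 if self.spec.fixed_r is None else 0
        return self.spec.n_coord_params + (self.n_participants - 1) + extra

    def _unpack(self, params: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, float]:
        nc = self.spec.n_coord_params
        coords = (_coords_constrained(params[:nc])
                  if self.spec.coordinate_mode == "constrained_grid"
                  else _coords_free(params[:nc]))
        logw = params[nc:nc + self.n_participants - 1]
        # geometric-mean-1 constraint identifies the coordinate scale
        logw = np.append(logw, -logw.sum())
        weights = np.exp(logw)
        if self.spec.fixed_r is not None:
            r = self.spec.fixed_r
        else:
            r = _R_MIN + (_R_MAX - _R_MIN) / (1.0 + np.exp(-params[-1]))
        return coords, weights, float(r)

    def _ssd(self, params: np.ndarray) -> float:
        coords, weights, r = self._unpack(params)
        diff = np.abs(coords[self._pi] - coords[self._pj])
        d = (diff ** r).sum(axis=1) ** (1.0 / r)
        pred = weights[self._row_part] * d[self._row_pair]
        resid = pred - self._dissim
        return float(resid @ resid)

    def fit(self, n_restarts: int = 20, seed: int = 0,
            tol: float = 1e-8) -> "MdsResults":
        """Multi-start quasi-Newton minimization of the SSD."""
        rng = np.random.default_rng(seed)
        best = None
        n_fail = 0
        for start in range(n_restarts):
            x0 = rng.normal(0.0, 0.7, self.n_params)
            res = optimize.minimize(self._ssd, x0, method="L-BFGS-B",
                                    options={"maxiter": 2000, "ftol": tol})
            if not res.success and not np.isfinite(res.fun):
                n_fail += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(f"optimizer failed on all {n_restarts} restarts")
        coords, weights, r = self._unpack(best.x)
        ssd = float(best.fun)
        # one weight parameter per participant is counted even though the
        # geometric-mean constraint trades one for the coordinate scale
        k = self.spec.n_coord_params + self.n_participants \
            + (1 if self.spec.fixed_r is None else 0)
        n = len(self.ratings)
        return MdsResults(
            spec=self.spec, coordinates=coords,
            weights=dict(zip(self.participants, weights)), r=r, ssd=ssd,
            k=k, n=n, bic=bic_from_ssd(ssd, k, n),
        )


@dataclass
class MdsResults:
    """Best-fitting configuration, weights and fit indices of one spec."""

    spec: MdsModelSpec
    coordinates: np.ndarray  # (9, 2), stimulus s at levels (s // 3, s % 3)
    weights: dict[str, float]
    r: float
    ssd: float
    k: int
    n: int
    bic: float

    def summary(self) -> pd.DataFrame:
        rows = [{"stimulus": s, "x_level": int(_IX[s]), "y_level": int(_IY[s]),
                 "x": self.coordinates[s, 0], "y": self.coordinates[s, 1]}
                for s in range(9)]
        table = pd.DataFrame(rows)
        table.attrs.update({"ssd": self.ssd, "bic": self.bic, "r": self.r,
                            "coordinate_mode": self.spec.coordinate_mode,
                            "metric": self.spec.metric})
        return table

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.coordinates[:, 0], self.coordinates[:, 1], c="k")
        for s in range(9):
            ax.annotate(f"x{_IX[s]}y{_IY[s]}", self.coordinates[s],
                        textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("lip height (a.u.)")
        ax.set_ylabel("eye separation (a.u.)")
        return ax


def fit_mds(ratings: pd.DataFrame, spec: MdsModelSpec, n_restarts: int = 20,
            seed: int = 0) -> MdsResults:
    """Convenience wrapper: build and fit one MDS spec."""
    return MdsModel(ratings, spec).fit(n_restarts=n_restarts, seed=seed)


def compare_mds_specs(ratings: pd.DataFrame,
                      specs: tuple[MdsModelSpec, ...] = STANDARD_SPECS,
                      n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit several specs to the same ratings and rank them by BIC."""
    rows = []
    for i, spec in enumerate(specs):
        res = fit_mds(ratings, spec, n_restarts=n_restarts, seed=seed + i)
        rows.append({"coordinate_mode": spec.coordinate_mode,
                     "metric": spec.metric, "r": res.r, "ssd": res.ssd,
                     "k": res.k, "bic": res.bic})
    table = pd.DataFrame(rows)
    table["best"] = table["bic"] == table["bic"].min()
    return table.sort_values("bic").reset_index(drop=True)
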