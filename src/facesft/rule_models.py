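"""Logical-rule evidence-accumulation models of conjunctive categorization.

Perception of each composite-face dimension (lip height ``x``, eye
separation ``y``) is modelled as Gaussian perceptual noise around fixed
psychological coordinates (a general-recognition-theory representation).
Integrating the perceptual distribution against a decision bound yields the
probability mass on each side of the bound; those masses drive a linear
ballistic accumulator (LBA) race between a target-category and a
contrast-category accumulator.  Channel outcomes are composed into the
architecture under test:

``serial_st``
    One dimension is processed first (lips first with probability ``p_x``).
    Processing self-terminates on contrast evidence; a target response
    requires both channels, and their decision times sum.
``parallel_st``
    Both channels race concurrently.  A contrast response is issued at the
    first contrast resolution; a target response requires both channels to
    resolve target and takes the slower channel's time.
``coactive``
    Both dimensions pool into a single accumulator pair whose drift is the
    bivariate-normal mass inside the conjunctive target region.
``mixed_serial_parallel``
    Trial-by-trial Bernoulli(``p_serial``) mixture of the serial and
    parallel architectures; the parallel component has its own start-point
    range ``A_parallel`` and inflated perceptual noise ``m * sigma``.
``mixed_serial_contaminant`` / ``mixed_parallel_contaminant``
    The base architecture with probability ``1 - p0``, otherwise a
    contaminant trial: RT uniform over the condition's observed RT range
    and a fair-coin response.
``free_drift``
    A single accumulator pair per stimulus with a freely specified drift
    ``nu`` (no perceptual-representation constraints).

All times are in milliseconds; the reported RT is decision time plus the
non-decision time ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from .design import StimulusDesign, assign_role

__all__ = [
    "GRTPerception",
    "LBAParams",
    "ModelSpec",
    "ARCHITECTURES",
    "marginal_drift",
    "bivariate_drift",
    "stimulus_drifts",
    "lba_race",
    "lba_channel_sample",
    "simulate_model",
    "model_predictions",
    "default_grt",
    "default_lba",
]

ARCHITECTURES = (
    "serial_st",
    "parallel_st",
    "coactive",
    "mixed_serial_parallel",
    "mixed_serial_contaminant",
    "mixed_parallel_contaminant",
    "free_drift",
)

_CONTAMINANT_BASES = {
    "mixed_serial_contaminant": "serial_st",
    "mixed_parallel_contaminant": "parallel_st",
}


@dataclass(frozen=True)
class GRTPerception:
    """Gaussian perceptual representation with orthogonal decision bounds.

    ``mu_x``/``mu_y`` are the per-level psychological coordinates (fixed,
    not free parameters — they anchor the drift-rate scale); ``sigma_x``
    and ``sigma_y`` are the perceptual SDs of each dimension and
    ``bound_x``/``bound_y`` the decision-bound positions separating the
    contrast level (level 0) from the target levels (1 and 2).
    """

    mu_x: tuple[float, float, float]
    mu_y: tuple[float, float, float]
    sigma_x: float
    sigma_y: float
    bound_x: float
    bound_y: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("perceptual SDs must be positive")

    @classmethod
    def from_design(cls, design: StimulusDesign, sigma_x: float, sigma_y: float,
                    bound_x: float, bound_y: float) -> "GRTPerception":
        return cls(mu_x=tuple(design.x_coords), mu_y=tuple(design.y_coords),
                   sigma_x=sigma_x, sigma_y=sigma_y,
                   bound_x=bound_x, bound_y=bound_y)

    def scaled(self, m: float) -> "GRTPerception":
        """Inflate both perceptual SDs by ``m`` (parallel mixture component)."""
        if m <= 0:
            raise ValueError("sigma multiplier must be positive")
        return replace(self, sigma_x=self.sigma_x * m, sigma_y=self.sigma_y * m)


@dataclass(frozen=True)
class LBAParams:
    """Linear ballistic accumulator parameters (times in ms).

    ``A`` is the start-point range (start ~ Uniform(0, A)); ``b_target``
    and ``b_contrast`` the response thresholds of the two accumulators;
    ``s`` the between-trial drift-rate SD; ``t0`` the non-decision time.
    """

    A: float
    b_target: float
    b_contrast: float
    s: float
    t0: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.b_target <= 0 or self.b_contrast <= 0:
            raise ValueError("thresholds must be positive")
        if self.s <= 0:
            raise ValueError("drift-rate SD must be positive")
        if self.t0 < 0:
            raise ValueError("non-decision time must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """An architecture tag plus its named parameter vector.

    Only the parameters belonging to the architecture are consulted; the
    nine shared parameters (two perceptual SDs, two bounds, A, two
    thresholds, s, t0) live in ``grt`` and ``lba``.
    """

    architecture: str
    lba: LBAParams
    grt: GRTPerception | None = None
    p_x: float = 0.5            # P(lips processed first) — serial variants
    p_serial: float = 0.5       # serial-mixture weight
    m: float = 1.0              # parallel-component perceptual SD multiplier
    A_parallel: float | None = None  # parallel-component start-point range
    p0: float = 0.0             # contaminant probability
    nu: dict[str, float] | None = None  # per-stimulus drifts (free_drift)
    contaminant_range: tuple[float, float] | None = None  # ms, decision-time scale

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture != "free_drift" and self.grt is None:
            raise ValueError("grt representation required for this architecture")
        if self.architecture == "free_drift" and self.nu is None:
            raise ValueError("free_drift requires per-stimulus drifts nu")
        for p, name in ((self.p_x, "p_x"), (self.p_serial, "p_serial"),
                        (self.p0, "p0")):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.m <= 0:
            raise ValueError("m must be positive")


def marginal_drift(mu: float, sigma: float, bound: float,
                   target_side: str = "above") -> tuple[float, float]:
    """Drift rates from the marginal perceptual distribution of one dimension.

    The target drift is the Gaussian mass on the target side of the
    decision bound; the contrast drift is the complementary mass, so the
    two always sum to one.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (mu - bound) / sigma
    if target_side == "above":
        v_target = ndtr(z)
    elif target_side == "below":
        v_target = ndtr(-z)
    else:
        raise ValueError("target_side must be 'above' or 'below'")
    return float(v_target), float(1.0 - v_target)


def bivariate_drift(mu_x: float, mu_y: float, sigma_x: float, sigma_y: float,
                    bound_x: float, bound_y: float) -> tuple[float, float]:
    """Coactive drift: bivariate-normal mass inside the conjunctive region.

    The perceptual effects on the two dimensions are independent, so the
    target mass is the product of the per-dimension target-side masses.
    """
    vx, _ = marginal_drift(mu_x, sigma_x, bound_x)
    vy, _ = marginal_drift(mu_y, sigma_y, bound_y)
    v_target = vx * vy
    return float(v_target), float(1.0 - v_target)


def stimulus_drifts(grt: GRTPerception, x_level: int, y_level: int
                    ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-channel (target, contrast) drifts for one stimulus."""
    vx = marginal_drift(grt.mu_x[x_level], grt.sigma_x, grt.bound_x)
    vy = marginal_drift(grt.mu_y[y_level], grt.sigma_y, grt.bound_y)
    return vx, vy


# ---------------------------------------------------------------------------
# LBA race primitives


def lba_race(v1: float, v2: float, b1: float, b2: float, A: float, s: float,
             n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Race two LBA accumulators ``n`` times.

    Each accumulator draws a rate ~ Normal(v, s) and a start point
    ~ Uniform(0, A); its finishing time is (threshold - start) / rate for
    positive rates (infinite otherwise, time = distance / rate).  Returns
    ``(first_wins, decision_time)`` where ``first_wins`` is a boolean array.
    Trials on which both sampled rates are non-positive redraw the rates
    (bounded retry budget), conditioning the race on at least one
    finishing accumulator.
    """
    from ._kernels import race_n

    return race_n(float(v1), float(v2), float(b1), float(b2), float(A),
                  float(s), int(n), rng)


def lba_channel_sample(lba: LBAParams, v_first: float, v_second: float,
                       rng: np.random.Generator,
                       A: float | None = None) -> tuple[str, float]:
    """Sample one two-accumulator race; returns (winner, decision_time ms).

    ``v_first`` drives the target accumulator (threshold ``b_target``) and
    ``v_second`` the contrast accumulator (threshold ``b_contrast``).
    """
    A_use = lba.A if A is None else A
    first, t = lba_race(v_first, v_second, lba.b_target, lba.b_contrast,
                        A_use, lba.s, 1, rng)
    return ("first" if first[0] else "second"), float(t[0])


# ---------------------------------------------------------------------------
# Architecture composition (inner loops live in ._kernels)


def _simulate_serial(spec: ModelSpec, vx, vy, n, rng):
    from ._kernels import serial_n

    lba = spec.lba
    return serial_n(vx[0], vx[1], vy[0], vy[1], float(spec.p_x), lba.A,
                    lba.b_target, lba.b_contrast, lba.s, n, rng)


def _simulate_parallel(spec: ModelSpec, vx, vy, n, rng,
                       A: float | None = None):
    from ._kernels import parallel_n

    lba = spec.lba
    A_use = lba.A if A is None else A
    return parallel_n(vx[0], vx[1], vy[0], vy[1], A_use, lba.b_target,
                      lba.b_contrast, lba.s, n, rng)


def _simulate_single_race(v: tuple[float, float], spec: ModelSpec, n, rng):
    lba = spec.lba
    return lba_race(v[0], v[1], lba.b_target, lba.b_contrast, lba.A, lba.s,
                    n, rng)


def simulate_model(spec: ModelSpec, x_level: int, y_level: int, n: int,
                   seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials of one stimulus under an architecture.

    Returns ``(responses, rts)`` with responses in {"target", "contrast"}
    and RTs in ms (decision time + ``t0``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    arch = spec.architecture

    if arch == "free_drift":
        role = assign_role(x_level, y_level).value
        if spec.nu is None or role not in spec.nu:
            raise ValueError(f"free_drift spec lacks a drift for role {role}")
        v = (float(spec.nu[role]), 1.0 - float(spec.nu[role]))
        respond_target, dt = _simulate_single_race(v, spec, n, rng)
    elif arch == "coactive":
        grt = spec.grt
        v = bivariate_drift(grt.mu_x[x_level], grt.mu_y[y_level],
                            grt.sigma_x, grt.sigma_y,
                            grt.bound_x, grt.bound_y)
        respond_target, dt = _simulate_single_race(v, spec, n, rng)
    else:
        base = _CONTAMINANT_BASES.get(arch, arch)
        vx, vy = stimulus_drifts(spec.grt, x_level, y_level)
        if base == "serial_st":
            respond_target, dt = _simulate_serial(spec, vx, vy, n, rng)
        elif base == "parallel_st":
            respond_target, dt = _simulate_parallel(spec, vx, vy, n, rng)
        elif base == "mixed_serial_parallel":
            from ._kernels import mixed_sp_n

            grt_p = spec.grt.scaled(spec.m)
            vx_p, vy_p = stimulus_drifts(grt_p, x_level, y_level)
            A_par = (spec.A_parallel if spec.A_parallel is not None
                     else spec.lba.A)
            lba = spec.lba
            respond_target, dt = mixed_sp_n(
                vx[0], vx[1], vy[0], vy[1], vx_p[0], vx_p[1], vy_p[0],
                vy_p[1], float(spec.p_x), float(spec.p_serial), lba.A,
                float(A_par), lba.b_target, lba.b_contrast, lba.s, n, rng)
        else:  # pragma: no cover
            raise ValueError(f"unknown architecture {arch!r}")

    rts = dt + spec.lba.t0
    responses = np.where(respond_target, "target", "contrast")

    if arch in _CONTAMINANT_BASES and spec.p0 > 0:
        if spec.contaminant_range is None:
            raise ValueError("contaminant architectures need a configured "
                             "contaminant_range (min_rt, max_rt)")
        lo, hi = spec.contaminant_range
        contaminated = rng.random(n) < spec.p0
        k = int(contaminated.sum())
        if k:
            rts[contaminated] = rng.uniform(lo, hi, k)
            responses[contaminated] = np.where(rng.random(k) < 0.5,
                                               "target", "contrast")
    return responses, rts


def model_predictions(spec: ModelSpec, design: StimulusDesign, n_sim: int,
                      seed: int) -> "pd.DataFrame":
    """Monte-Carlo response probabilities and RT quartiles per stimulus.

    Returns a tidy frame with one row per (stimulus, response) cell:
    columns ``x_level, y_level, role, response, p, q25, q50, q75``.
    """
    import pandas as pd

    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable quantiles")
    rng = np.random.default_rng(seed)
    rows = []
    for x, y in design.cells:
        responses, rts = simulate_model(spec, x, y, n_sim, rng)
        role = assign_role(x, y).value
        for resp in ("target", "contrast"):
            mask = responses == resp
            p = float(mask.mean())
            if mask.any():
                q25, q50, q75 = np.percentile(rts[mask], [25, 50, 75])
            else:
                q25 = q50 = q75 = np.nan
            rows.append({"x_level": x, "y_level": y, "role": role,
                         "response": resp, "p": p,
                         "q25": q25, "q50": q50, "q75": q75})
    return pd.DataFrame(rows)


def default_grt(design: StimulusDesign, sigma_x: float = 1.0,
                sigma_y: float = 1.0) -> GRTPerception:
    """GRT representation with bounds midway between levels 0 and 1 shifted
    so the low target level sits 0.75 SD and the high level 2.0 SD above
    the bound (with the default design and unit SDs)."""
    bound_x = design.x_coords[1] - 0.75 * sigma_x
    bound_y = design.y_coords[1] - 0.75 * sigma_y
    return GRTPerception.from_design(design, sigma_x, sigma_y, bound_x, bound_y)


def default_lba() -> LBAParams:
    """Threshold and timing defaults giving human-scale RTs (≈0.5–3 s).

    The drift-rate SD default (s = 0.1) keeps the race out of the
    heavy-tailed regime in which near-zero sampled rates dominate the mean
    RT; with the default design it yields error rates in the range human
    observers produce on this task (roughly 1–12% depending on the item).
    """
    return LBAParams(A=300.0, b_target=1500.0, b_contrast=1500.0, s=0.1,
                     t0=250.0)
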