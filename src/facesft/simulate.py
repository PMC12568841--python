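"""Synthetic datasets with known ground truth.

Three generators emulate the three studies the analysis pipeline serves:

* :func:`simulate_rt_dataset` — trial-level categorization RTs from any
  logical-rule architecture (the double-factorial design: 9 stimuli x
  ``n_trials_per_item`` trials per participant, sessions 2-8).
* :func:`simulate_similarity_ratings` — pairwise similarity ratings on the
  1-8 scale from a weighted-Minkowski distance model plus Gaussian rating
  noise (36 unique pairs x 3 repetitions per participant).
* :func:`simulate_composite_trials` — same/different composite-task trials
  from an equal-variance Gaussian signal-detection observer with per-cell
  sensitivity and criterion.

Every generator is a pure function of its parameters and seed; participant
streams are spawned from one seed sequence so each participant's data is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from .design import StimulusDesign, default_design
from .io import TrialTable, from_dataframe
from .rule_models import ModelSpec, simulate_model

__all__ = [
    "GroundTruth",
    "simulate_rt_dataset",
    "simulate_similarity_ratings",
    "simulate_composite_trials",
    "save_ground_truth",
]

SESSIONS = tuple(range(2, 9))  # session 1 is practice and never generated

CONGRUENCIES = ("congruent", "incongruent")
ALIGNMENTS = ("aligned", "misaligned")


@dataclass(frozen=True)
class GroundTruth:
    """A generating model plus the design and sampling plan."""

    model_spec: ModelSpec
    design: StimulusDesign = field(default_factory=default_design)
    n_trials_per_item: int = 400
    n_participants: int = 1
    condition: str = "aligned"
    session_slope_ms: float = 0.0  # optional per-session linear speed-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_item < 1:
            raise ValueError("n_trials_per_item must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def simulate_rt_dataset(truth: GroundTruth) -> TrialTable:
    """Generate trial-level RT data from a known architecture.

    Emits ``n_participants * 9 * n_trials_per_item`` trials.  Sessions 2-8
    are assigned uniformly at random per trial; an optional linear session
    speed-up (``session_slope_ms`` per session step) exercises the session
    term of the target-category ANOVA.
    """
    streams = np.random.SeedSequence(truth.seed).spawn(truth.n_participants)
    frames = []
    for p_idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"S{p_idx + 1:02d}"
        for x, y in truth.design.cells:
            responses, rts = simulate_model(truth.model_spec, x, y,
                                            truth.n_trials_per_item, rng)
            sessions = rng.integers(SESSIONS[0], SESSIONS[-1] + 1,
                                    truth.n_trials_per_item)
            rts = rts - truth.session_slope_ms * (sessions - SESSIONS[0])
            frames.append(pd.DataFrame({
                "participant": pid,
                "condition": truth.condition,
                "session": sessions,
                "x_level": x,
                "y_level": y,
                "response": responses,
                "rt_ms": np.maximum(rts, 1.0),
            }))
    df = pd.concat(frames, ignore_index=True)
    return from_dataframe(df, truth.design, source=f"synthetic(seed={truth.seed})")


def simulate_similarity_ratings(coords: np.ndarray, weights: np.ndarray,
                                metric_r: float, noise_sd: float,
                                intercept: float = 9.0, slope: float = 1.7,
                                n_repetitions: int = 3,
                                seed: int = 0) -> pd.DataFrame:
    """Similarity ratings from a weighted-Minkowski distance model.

    rating = clamp(round(intercept - slope * w_p * d_ij(r) + eps), 1, 8)
    with eps ~ Normal(0, noise_sd).  ``coords`` is the (9, 2) stimulus
    configuration; ``weights`` one positive scale factor per participant.
    Each participant rates all 36 unordered pairs ``n_repetitions`` times.

    The defaults make the rating map the exact inverse of the analysis
    transform (dissimilarity = 9 - rating) and keep expected ratings inside
    the scale over the default design's distance range, so end-of-scale
    clamping — which censors long distances and distorts the apparent
    metric — stays rare for weights near 1.
    """
    coords = np.asarray(coords, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_stimuli, 2)")
    if slope <= 0:
        raise ValueError("slope must be positive: similarity must decrease "
                         "with distance")
    if metric_r < 1:
        raise ValueError("metric exponent r must be >= 1")
    if (weights <= 0).any():
        raise ValueError("participant weights must be positive")
    pairs = list(combinations(range(len(coords)), 2))
    diffs = np.abs(coords[[i for i, _ in pairs]] - coords[[j for _, j in pairs]])
    d = (diffs ** metric_r).sum(axis=1) ** (1.0 / metric_r)
    streams = np.random.SeedSequence(seed).spawn(len(weights))
    rows = []
    for p_idx, (w, ss) in enumerate(zip(weights, streams)):
        rng = np.random.default_rng(ss)
        pid = f"P{p_idx + 1:02d}"
        for rep in range(1, n_repetitions + 1):
            eps = rng.normal(0.0, noise_sd, len(pairs)) if noise_sd > 0 else 0.0
            raw = np.round(intercept - slope * w * d + eps)
            rating = np.clip(raw, 1, 8).astype(int)
            for (i, j), r in zip(pairs, rating):
                rows.append({"participant": pid, "stim_i": i, "stim_j": j,
                             "repetition": rep, "rating": int(r)})
    return pd.DataFrame(rows)


def simulate_composite_trials(dprime: dict[tuple[str, str], float],
                              criterion: dict[tuple[str, str], float],
                              n_per_cell: int, n_participants: int = 36,
                              seed: int = 0) -> pd.DataFrame:
    """Same/different composite-task trials from a Gaussian SDT observer.

    ``dprime`` and ``criterion`` are keyed by (congruency, alignment).
    In each cell every participant sees ``n_per_cell`` "different" (signal)
    trials with evidence ~ Normal(d', 1) and ``n_per_cell`` "same" (noise)
    trials with evidence ~ Normal(0, 1), responding "different" iff the
    evidence exceeds the decision threshold d'/2 + c — i.e. ``criterion``
    is the standard SDT bias index c, zero at the unbiased midpoint, so
    the generated hit rate is Phi(d'/2 - c) and the equal-variance indices
    recover (d', c) exactly in expectation.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    for key in dprime:
        if dprime[key] < 0:
            raise ValueError(f"d-prime must be non-negative in cell {key}")
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    rows = []
    for p_idx, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"C{p_idx + 1:02d}"
        for cong in CONGRUENCIES:
            for align in ALIGNMENTS:
                dp = dprime[(cong, align)]
                c = criterion[(cong, align)]
                threshold = dp / 2.0 + c
                for trial_type, loc in (("different", dp), ("same", 0.0)):
                    evidence = rng.normal(loc, 1.0, n_per_cell)
                    resp = np.where(evidence > threshold, "different", "same")
                    for r in resp:
                        rows.append({"participant": pid, "congruency": cong,
                                     "alignment": align,
                                     "trial_type": trial_type, "response": r})
    return pd.DataFrame(rows)


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Persist the generating parameters as YAML for recovery studies."""
    spec = truth.model_spec
    doc = {
        "architecture": spec.architecture,
        "lba": {"A": spec.lba.A, "b_target": spec.lba.b_target,
                "b_contrast": spec.lba.b_contrast, "s": spec.lba.s,
                "t0": spec.lba.t0},
        "p_x": spec.p_x, "p_serial": spec.p_serial, "m": spec.m,
        "A_parallel": spec.A_parallel, "p0": spec.p0, "nu": spec.nu,
        "contaminant_range": (list(spec.contaminant_range)
                              if spec.contaminant_range else None),
        "design": {"x_coords": list(truth.design.x_coords),
                   "y_coords": list(truth.design.y_coords)},
        "n_trials_per_item": truth.n_trials_per_item,
        "n_participants": truth.n_participants,
        "condition": truth.condition,
        "seed": truth.seed,
    }
    if spec.grt is not None:
        doc["grt"] = {"sigma_x": spec.grt.sigma_x, "sigma_y": spec.grt.sigma_y,
                      "bound_x": spec.grt.bound_x, "bound_y": spec.grt.bound_y}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
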