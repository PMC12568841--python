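"""Numba-compiled inner loops for LBA races and kernel density estimation.

These kernels are the hot path of the PDA likelihood (tens of thousands of
simulated trials per evaluation, thousands of evaluations per fit).  They
consume a ``numpy.random.Generator`` directly, so results are bit-for-bit
reproducible from a seed and identical across the compiled and interpreted
entry points.

Draw-order convention (one trial): each two-accumulator race consumes the
target rate, the contrast rate (jointly redrawn while both are
non-positive), then the two start points.  Serial trials consume the
processing-order variate first, then both channel races; parallel trials
consume the two channel races in x-then-y order.  Keeping the per-trial
draw count fixed within an architecture means equal seeds yield common
random numbers across stimuli, which cancels most Monte-Carlo noise in
between-item contrasts such as the MIC.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_RATE_RETRY = 1000


@njit(cache=True, inline="always")
def _race_one(vt, vc, bt, bc, A, s, rng):
    """One race between target and contrast accumulators.

    Returns (target_won, decision_time).  Both rates are redrawn while
    jointly non-positive; a non-positive rate makes that accumulator
    non-finishing (infinite time).
    """
    r1 = rng.normal(vt, s)
    r2 = rng.normal(vc, s)
    tries = 0
    while r1 <= 0.0 and r2 <= 0.0:
        tries += 1
        if tries > _MAX_RATE_RETRY:
            raise RuntimeError("could not draw a positive drift rate")
        r1 = rng.normal(vt, s)
        r2 = rng.normal(vc, s)
    u1 = rng.uniform(0.0, A) if A > 0.0 else 0.0
    u2 = rng.uniform(0.0, A) if A > 0.0 else 0.0
    t1 = (bt - u1) / r1 if r1 > 0.0 else np.inf
    t2 = (bc - u2) / r2 if r2 > 0.0 else np.inf
    if t1 <= t2:
        return True, t1
    return False, t2


@njit(cache=True)
def race_n(vt, vc, bt, bc, A, s, n, rng):
    """n independent target-vs-contrast races."""
    won = np.empty(n, np.bool_)
    t = np.empty(n)
    for i in range(n):
        won[i], t[i] = _race_one(vt, vc, bt, bc, A, s, rng)
    return won, t


@njit(cache=True)
def serial_n(vxt, vxc, vyt, vyc, p_x, A, bt, bc, s, n, rng):
    """Serial self-terminating composition (AND rule).

    The first channel (lips with probability p_x) runs to resolution; a
    contrast resolution self-terminates, otherwise the second channel runs
    and decides, with the channel times summing.  Both channel races are
    always consumed so the random stream is item-independent.
    """
    resp = np.empty(n, np.bool_)
    t = np.empty(n)
    for i in range(n):
        x_first = rng.random() < p_x
        xw, xt = _race_one(vxt, vxc, bt, bc, A, s, rng)
        yw, yt = _race_one(vyt, vyc, bt, bc, A, s, rng)
        if x_first:
            w1, t1, w2, t2 = xw, xt, yw, yt
        else:
            w1, t1, w2, t2 = yw, yt, xw, xt
        if not w1:  # first channel resolved contrast: stop
            resp[i] = False
            t[i] = t1
        else:
            resp[i] = w2
            t[i] = t1 + t2
    return resp, t


@njit(cache=True)
def parallel_n(vxt, vxc, vyt, vyc, A, bt, bc, s, n, rng):
    """Parallel self-terminating composition (AND rule).

    Contrast is reported at the earliest contrast resolution among the
    channels that resolved contrast; target requires both channels and
    takes the slower channel's time.
    """
    resp = np.empty(n, np.bool_)
    t = np.empty(n)
    for i in range(n):
        xw, xt = _race_one(vxt, vxc, bt, bc, A, s, rng)
        yw, yt = _race_one(vyt, vyc, bt, bc, A, s, rng)
        if xw and yw:
            resp[i] = True
            t[i] = xt if xt > yt else yt
        else:
            resp[i] = False
            if not xw and not yw:
                t[i] = xt if xt < yt else yt
            elif not xw:
                t[i] = xt
            else:
                t[i] = yt
    return resp, t


@njit(cache=True)
def mixed_sp_n(vxt, vxc, vyt, vyc, pxt, pxc, pyt, pyc, p_x, p_serial,
               A, A_parallel, bt, bc, s, n, rng):
    """Trial-level mixture of the serial and parallel compositions.

    The parallel component uses its own drifts (``p*``, from the inflated
    perceptual SDs) and start-point range.
    """
    resp = np.empty(n, np.bool_)
    t = np.empty(n)
    for i in range(n):
        if rng.random() < p_serial:
            x_first = rng.random() < p_x
            xw, xt = _race_one(vxt, vxc, bt, bc, A, s, rng)
            yw, yt = _race_one(vyt, vyc, bt, bc, A, s, rng)
            if x_first:
                w1, t1, w2, t2 = xw, xt, yw, yt
            else:
                w1, t1, w2, t2 = yw, yt, xw, xt
            if not w1:
                resp[i] = False
                t[i] = t1
            else:
                resp[i] = w2
                t[i] = t1 + t2
        else:
            xw, xt = _race_one(pxt, pxc, bt, bc, A_parallel, s, rng)
            yw, yt = _race_one(pyt, pyc, bt, bc, A_parallel, s, rng)
            if xw and yw:
                resp[i] = True
                t[i] = xt if xt > yt else yt
            else:
                resp[i] = False
                if not xw and not yw:
                    t[i] = xt if xt < yt else yt
                elif not xw:
                    t[i] = xt
                else:
                    t[i] = yt
    return resp, t


@njit(cache=True)
def kde_eval(samples, eval_at, bw, n_bins):
    """Binned Gaussian KDE evaluated at ``eval_at``.

    Histogram the samples on ``n_bins`` bins padded by four bandwidths,
    convolve with a discrete Gaussian kernel, and linearly interpolate.
    """
    n = samples.size
    lo = samples[0]
    hi = samples[0]
    for i in range(n):
        if samples[i] < lo:
            lo = samples[i]
        if samples[i] > hi:
            hi = samples[i]
    lo -= 4.0 * bw
    hi += 4.0 * bw
    width = (hi - lo) / n_bins
    hist = np.zeros(n_bins)
    for i in range(n):
        k = int((samples[i] - lo) / width)
        if k < 0:
            k = 0
        elif k >= n_bins:
            k = n_bins - 1
        hist[k] += 1.0
    inv = 1.0 / (n * width)
    sigma_b = bw / width
    half = int(4.0 * sigma_b) + 1
    kern = np.empty(2 * half + 1)
    ksum = 0.0
    for j in range(-half, half + 1):
        v = np.exp(-0.5 * (j / sigma_b) ** 2)
        kern[j + half] = v
        ksum += v
    for j in range(2 * half + 1):
        kern[j] /= ksum
    smooth = np.zeros(n_bins)
    for b in range(n_bins):
        h = hist[b]
        if h == 0.0:
            continue
        j0 = b - half
        for j in range(2 * half + 1):
            idx = j0 + j
            if 0 <= idx < n_bins:
                smooth[idx] += h * kern[j]
    out = np.empty(eval_at.size)
    for i in range(eval_at.size):
        pos = (eval_at[i] - lo) / width - 0.5
        if pos <= 0.0 or pos >= n_bins - 1:
            out[i] = 0.0
            continue
        b = int(pos)
        frac = pos - b
        out[i] = ((1.0 - frac) * smooth[b] + frac * smooth[b + 1]) * inv
    return out
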