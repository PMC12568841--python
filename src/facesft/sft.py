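"""Nonparametric Systems Factorial Technology analyses.

Implements the survivor-function machinery for diagnosing processing
architecture from double-factorial RT data: the mean interaction contrast
(MIC), the survivor interaction contrast (SIC) with bootstrap confidence
bands, directional Kolmogorov-Smirnov stochastic-dominance checks, the
D+/D- deflection tests of the SIC, the per-participant target-category
factorial ANOVA, planned contrast-category comparisons, and the
deterministic architecture-classification rule that combines them.

Only correct responses enter these analyses; error RTs are handled by the
parametric models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import TARGET_ROLES

__all__ = [
    "SurvivorEstimate",
    "SICResult",
    "survivor_fn",
    "mic",
    "mic_from_samples",
    "sic",
    "ks_dominance_suite",
    "sic_deflection_tests",
    "target_category_anova",
    "contrast_category_tests",
    "classify_architecture",
    "summarize_sic_shape",
    "rts_by_item",
]

_TARGET_KEYS = ("LL", "LH", "HL", "HH")


@dataclass
class SurvivorEstimate:
    """Empirical survivor function S(t) = P(T > t) of one item's RTs."""

    t_grid: np.ndarray
    S: np.ndarray
    n: int


@dataclass
class SICResult:
    """Survivor interaction contrast with its summary statistics.

    ``sic`` is evaluated on ``t_grid`` (piecewise-constant between grid
    points); ``samples`` retains the raw per-item RTs so resampling tests
    can be run downstream.  ``boot_lower``/``boot_upper`` are pointwise
    percentile envelopes from resampling each item's RTs with replacement.
    """

    t_grid: np.ndarray
    sic: np.ndarray
    mic: float
    samples: dict[str, np.ndarray]
    boot_lower: np.ndarray | None = None
    boot_upper: np.ndarray | None = None
    n_boot: int = 0

    def integral(self) -> float:
        """Exact integral of the piecewise-constant SIC over the grid.

        Because the empirical survivor functions are step functions with
        jumps only at sample points, this equals the MIC of the sample
        means up to floating-point error.
        """
        dt = np.diff(self.t_grid)
        return float(np.sum(self.sic[:-1] * dt))

    @property
    def d_plus(self) -> float:
        return float(max(self.sic.max(), 0.0))

    @property
    def d_minus(self) -> float:
        return float(max(-self.sic.min(), 0.0))

    def plot(self, ax=None):
        """Plot the SIC curve with its bootstrap envelope, if present."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.t_grid, self.sic, where="post", color="k", label="SIC")
        if self.boot_lower is not None:
            ax.fill_between(self.t_grid, self.boot_lower, self.boot_upper,
                            step="post", alpha=0.25, color="grey",
                            label=f"bootstrap band (n={self.n_boot})")
        ax.axhline(0.0, color="r", lw=0.5)
        ax.set_xlabel("t (ms)")
        ax.set_ylabel("SIC(t)")
        ax.legend()
        return ax


def _survivor_on_grid(rts: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    srt = np.sort(rts)
    return 1.0 - np.searchsorted(srt, t_grid, side="right") / srt.size


def survivor_fn(rts: np.ndarray, t_grid: np.ndarray) -> SurvivorEstimate:
    """Empirical survivor function of one item condition's RTs.

    Uses the strict-inequality convention S(t) = #{rt > t} / n, so
    S equals 0 at and beyond the sample maximum.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty RT sample")
    t_grid = np.asarray(t_grid, dtype=float)
    return SurvivorEstimate(t_grid=t_grid, S=_survivor_on_grid(rts, t_grid),
                            n=rts.size)


def mic(mean_ll: float, mean_lh: float, mean_hl: float, mean_hh: float) -> float:
    """Mean interaction contrast (RT_LL - RT_LH) - (RT_HL - RT_HH) in ms."""
    for m in (mean_ll, mean_lh, mean_hl, mean_hh):
        if not np.isfinite(m):
            raise ValueError("all four means must be finite")
    return float((mean_ll - mean_lh) - (mean_hl - mean_hh))


def mic_from_samples(samples: dict[str, np.ndarray]) -> float:
    return mic(*(np.mean(samples[k]) for k in _TARGET_KEYS))


def sic(samples: dict[str, np.ndarray], t_grid: np.ndarray | None = None,
        n_boot: int = 1000, seed: int = 0,
        band_level: float = 0.95) -> SICResult:
    """Survivor interaction contrast of the four target-item RT samples.

    SIC(t) = [S_LL(t) - S_LH(t)] - [S_HL(t) - S_HH(t)].  The default time
    grid is 0 followed by the pooled unique RTs, on which the empirical
    survivor functions are exact.  Bootstrap bands resample each item's
    RTs with replacement ``n_boot`` times (pointwise percentile envelope).
    """
    samples = {k: np.asarray(samples[k], dtype=float) for k in _TARGET_KEYS}
    for k, v in samples.items():
        if v.size == 0:
            raise ValueError(f"empty sample for item {k}")
    if t_grid is None:
        pooled = np.concatenate(list(samples.values()))
        t_grid = np.concatenate(([0.0], np.unique(pooled)))
    t_grid = np.asarray(t_grid, dtype=float)

    def _sic_curve(smp: dict[str, np.ndarray]) -> np.ndarray:
        S = {k: _survivor_on_grid(v, t_grid) for k, v in smp.items()}
        return (S["LL"] - S["LH"]) - (S["HL"] - S["HH"])

    curve = _sic_curve(samples)
    result = SICResult(t_grid=t_grid, sic=curve,
                       mic=mic_from_samples(samples), samples=samples)
    if n_boot < 1:
        warnings.warn("n_boot < 1: bootstrap bands omitted")
        return result
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, t_grid.size))
    for b in range(n_boot):
        resampled = {k: rng.choice(v, size=v.size, replace=True)
                     for k, v in samples.items()}
        boot[b] = _sic_curve(resampled)
    alpha = (1.0 - band_level) / 2.0
    result.boot_lower = np.quantile(boot, alpha, axis=0)
    result.boot_upper = np.quantile(boot, 1.0 - alpha, axis=0)
    result.n_boot = n_boot
    return result


def _ks_onesided(fast: np.ndarray, slow: np.ndarray) -> tuple[float, float]:
    """Directional two-sample KS test that ``fast`` dominates ``slow``.

    The statistic is the maximum ECDF difference in the tested direction,
    sup_t [F_fast(t) - F_slow(t)] (equivalently sup_t [S_slow - S_fast]).
    """
    res = stats.ks_2samp(fast, slow, alternative="greater")
    return float(res.statistic), float(res.pvalue)


#: test order: the first four should be significant under stochastic
#: dominance (HH fastest ... LL slowest), the last four should not.
DOMINANCE_TESTS = (
    ("S_HH > S_HL", "HH", "HL"),
    ("S_HH > S_LH", "HH", "LH"),
    ("S_HL > S_LL", "HL", "LL"),
    ("S_LH > S_LL", "LH", "LL"),
    ("S_HH < S_HL", "HL", "HH"),
    ("S_HH < S_LH", "LH", "HH"),
    ("S_HL < S_LL", "LL", "HL"),
    ("S_LH < S_LL", "LL", "LH"),
)


def ks_dominance_suite(samples: dict[str, np.ndarray],
                       alpha: float = 0.05) -> tuple[pd.DataFrame, bool]:
    """Stochastic-dominance check on the four target items.

    Runs the eight directional KS tests; the dominance verdict requires
    the first four (the expected orderings) to be significant and the
    reversed four not to be, at level ``alpha``.
    """
    for k in _TARGET_KEYS:
        if np.asarray(samples[k]).size < 2:
            raise ValueError(f"need at least 2 RTs per item, item {k} too small")
    rows = []
    for label, a, b in DOMINANCE_TESTS:
        stat, p = _ks_onesided(np.asarray(samples[a], float),
                               np.asarray(samples[b], float))
        rows.append({"test": label, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    sig = table["p"].to_numpy() < alpha
    verdict = bool(sig[:4].all() and not sig[4:].any())
    return table, verdict


def sic_deflection_tests(result: SICResult, n_resample: int = 2000,
                         seed: int = 0) -> dict[str, float]:
    """Significance of the SIC's maximum (D+) and minimum (D-) deflections.

    The null distribution is generated by permuting the high/low
    discriminability labels independently within each dimension across
    trials (marginal sample sizes preserved), destroying any factorial
    interaction while keeping the pooled RT distribution fixed.
    """
    samples = result.samples
    rts = np.concatenate([samples[k] for k in _TARGET_KEYS])
    x_lab = np.concatenate([np.repeat(k[0], samples[k].size) for k in _TARGET_KEYS])
    y_lab = np.concatenate([np.repeat(k[1], samples[k].size) for k in _TARGET_KEYS])
    if rts.size < 8:
        raise ValueError("too few trials to permute")
    d_plus, d_minus = result.d_plus, result.d_minus
    t_grid = result.t_grid
    rng = np.random.default_rng(seed)
    exceed_plus = exceed_minus = 0
    n_done = 0
    while n_done < n_resample:
        xp = rng.permutation(x_lab)
        yp = rng.permutation(y_lab)
        perm = {}
        ok = True
        for k in _TARGET_KEYS:
            mask = (xp == k[0]) & (yp == k[1])
            if not mask.any():
                ok = False
                break
            perm[k] = rts[mask]
        if not ok:
            continue
        S = {k: _survivor_on_grid(v, t_grid) for k, v in perm.items()}
        curve = (S["LL"] - S["LH"]) - (S["HL"] - S["HH"])
        if curve.max() >= d_plus:
            exceed_plus += 1
        if -curve.min() >= d_minus:
            exceed_minus += 1
        n_done += 1
    return {
        "d_plus": d_plus,
        "p_plus": (1 + exceed_plus) / (n_resample + 1),
        "d_minus": d_minus,
        "p_minus": (1 + exceed_minus) / (n_resample + 1),
    }


def _hl_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Attach top/bottom discriminability labels to target-category trials.

    The bottom face half carries the lip-height dimension (x) and the top
    half the eye-separation dimension (y); level 2 is the high- and level 1
    the low-discriminability target level.
    """
    out = df.copy()
    out["bottom"] = np.where(out["x_level"] == 2, "H", "L")
    out["top"] = np.where(out["y_level"] == 2, "H", "L")
    return out


def target_category_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Session x top x bottom fixed-effects ANOVA on correct target RTs.

    ``df`` holds one participant's trials (schema columns plus ``correct``
    and ``role``).  Returns a table with F, numerator/denominator df, p and
    partial eta squared for every main effect and interaction.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = df[df["correct"] & df["role"].isin([r.value for r in TARGET_ROLES])]
    data = _hl_labels(data)
    counts = data.groupby(["session", "top", "bottom"]).size()
    n_sessions = data["session"].nunique()
    if len(counts) < n_sessions * 4 or (counts == 0).any():
        missing = counts[counts == 0].index.tolist() if (counts == 0).any() else \
            "an absent session x item cell"
        raise ValueError(f"empty design cell: {missing}")
    model = smf.ols("rt_ms ~ C(session) * C(top) * C(bottom)", data=data).fit()
    table = anova_lm(model, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    rows = []
    for effect in table.index:
        if effect == "Residual":
            continue
        ss = float(table.loc[effect, "sum_sq"])
        rows.append({
            "effect": effect.replace("C(", "").replace(")", ""),
            "df_num": float(table.loc[effect, "df"]),
            "df_den": df_err,
            "F": float(table.loc[effect, "F"]),
            "p": float(table.loc[effect, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_err),
        })
    return pd.DataFrame(rows)


#: planned comparisons in the layout of the contrast-category analysis:
#: exterior vs interior on each dimension, then each vs the redundant item.
CONTRAST_COMPARISONS = (
    ("E_top - I_top", "Ey", "Iy"),
    ("E_bottom - I_bottom", "Ex", "Ix"),
    ("E_top - R", "Ey", "R"),
    ("I_top - R", "Iy", "R"),
    ("E_bottom - R", "Ex", "R"),
    ("I_bottom - R", "Ix", "R"),
)


def contrast_category_tests(df: pd.DataFrame) -> pd.DataFrame:
    """Planned Welch t-tests on correct contrast-category RTs.

    Compares interior vs exterior items on each dimension and every
    non-redundant item against the redundant stimulus, reporting the mean
    difference (ms), Welch t, df, p, and Cohen's d (pooled-SD)."""
    data = df[df["correct"]]
    groups = {role: data.loc[data["role"] == role, "rt_ms"].to_numpy()
              for role in ("R", "Ix", "Ex", "Iy", "Ey")}
    for role, v in groups.items():
        if v.size < 2:
            raise ValueError(f"no correct RTs for contrast role {role}")
    rows = []
    for label, a, b in CONTRAST_COMPARISONS:
        va, vb = groups[a], groups[b]
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        # Welch-Satterthwaite df
        sa2, sb2 = va.var(ddof=1) / va.size, vb.var(ddof=1) / vb.size
        dof = (sa2 + sb2) ** 2 / (sa2 ** 2 / (va.size - 1)
                                  + sb2 ** 2 / (vb.size - 1))
        pooled = np.sqrt(((va.size - 1) * va.var(ddof=1)
                          + (vb.size - 1) * vb.var(ddof=1))
                         / (va.size + vb.size - 2))
        rows.append({"comparison": label,
                     "mean_diff": float(va.mean() - vb.mean()),
                     "t": float(t), "df": float(dof), "p": float(p),
                     "cohens_d": float((va.mean() - vb.mean()) / pooled)})
    return pd.DataFrame(rows)


def summarize_sic_shape(deflections: dict[str, float], sic_curve: np.ndarray,
                        t_grid: np.ndarray, alpha: float = 0.05
                        ) -> tuple[str, bool]:
    """Reduce D+/D- tests and the SIC curve to a categorical shape token.

    "positive" if only D+ is significant, "mostly-negative" if only D-,
    otherwise "s-shaped" (suffixed "-mostly-positive" when the positive
    area exceeds twice the negative area).  Also returns whether both
    deflections are significant, which flags an ambiguous over-additive
    S-shape.
    """
    plus_sig = deflections["p_plus"] < alpha
    minus_sig = deflections["p_minus"] < alpha
    if plus_sig and not minus_sig:
        return "positive", False
    if minus_sig and not plus_sig:
        return "mostly-negative", False
    dt = np.diff(t_grid)
    vals = sic_curve[:-1]
    pos_area = float(np.sum(np.clip(vals, 0, None) * dt))
    neg_area = float(np.sum(np.clip(-vals, 0, None) * dt))
    token = "s-shaped-mostly-positive" if pos_area > 2.0 * neg_area else "s-shaped"
    return token, (plus_sig and minus_sig)


_SHAPES = {"positive", "mostly-negative", "s-shaped", "s-shaped-mostly-positive"}


def classify_architecture(sic_shape: str, mic_significant: bool,
                          interior_pattern: dict[str, str],
                          both_deflections_significant: bool = False
                          ) -> list[str]:
    """Qualitative architecture labels from the nonparametric summaries.

    ``interior_pattern`` maps "top"/"bottom" to one of "I<E", "I>E", "I=E"
    (interior vs exterior mean RT on that dimension).  Multiple labels are
    returned when the evidence is ambiguous.  The rule applies the SIC
    shape first, then the MIC, then the interior-vs-exterior pattern:
    a significantly positive SIC indicates coactivity, an entirely
    negative one parallel self-terminating processing, and an S-shape
    (equal positive and negative area) serial processing — with identical
    interior/exterior RT distributions pointing to parallel
    self-termination as the alternative reading.
    """
    if sic_shape not in _SHAPES:
        raise ValueError(f"unknown SIC shape token {sic_shape!r}")
    for dim in ("top", "bottom"):
        if interior_pattern.get(dim) not in {"I<E", "I>E", "I=E"}:
            raise ValueError(f"interior_pattern[{dim!r}] must be I<E, I>E or I=E")
    if sic_shape == "positive":
        return ["Coactive"] if mic_significant else ["Coactive", "Serial ST"]
    if sic_shape == "mostly-negative":
        return ["Parallel ST"]
    if sic_shape == "s-shaped-mostly-positive":
        return ["Serial ST"]
    # s-shaped
    if both_deflections_significant:
        return ["Coactive", "Serial ST"]
    if all(interior_pattern[d] == "I=E" for d in ("top", "bottom")):
        return ["Parallel ST", "Serial ST"]
    return ["Serial ST"]


def rts_by_item(df: pd.DataFrame, correct_only: bool = True
                ) -> dict[str, np.ndarray]:
    """Correct RTs of the four target items keyed LL/LH/HL/HH."""
    data = df[df["correct"]] if correct_only else df
    return {k: data.loc[data["role"] == k, "rt_ms"].to_numpy()
            for k in _TARGET_KEYS}
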