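"""Signal detection analysis of the composite-face same/different task.

"Different" trials are treated as signal and "same" trials as noise, so a
hit is a "different" response to a different pair and a false alarm a
"different" response to an identical pair.  Equal-variance Gaussian SDT
gives sensitivity d' = z(H) - z(F) and criterion c = -(z(H) + z(F)) / 2;
with this signal mapping a liberal shift toward responding "different"
(as observed for misaligned faces) yields negative criteria.

The congruency x alignment interaction in d' — the classic marker of
holistic processing in the complete composite design — is tested with a
2 x 2 repeated-measures ANOVA in which every effect is evaluated against
its own participant-by-effect error term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SdtCell", "sdt_indices", "sdt_cells_from_trials",
           "rm_anova_2x2", "composite_face_analysis"]


@dataclass(frozen=True)
class SdtCell:
    """Trial counts of one participant in one congruency x alignment cell."""

    participant: str
    congruency: str
    alignment: str
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        counts = (self.hits, self.misses, self.false_alarms,
                  self.correct_rejections)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.hits + self.misses == 0 or \
                self.false_alarms + self.correct_rejections == 0:
            raise ValueError("need at least one signal and one noise trial")


def _corrected_rate(k: int, n: int) -> float:
    """Proportion with the 1/(2N) correction at the 0 and 1 extremes."""
    p = k / n
    if p == 0.0:
        return 1.0 / (2 * n)
    if p == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def sdt_indices(cell: SdtCell) -> tuple[float, float]:
    """Equal-variance Gaussian sensitivity and criterion of one cell.

    d' = z(H) - z(F); c = -(z(H) + z(F)) / 2.  Hit and false-alarm rates
    of exactly 0 or 1 are pulled in by 1/(2N) before the z-transform so
    both indices stay finite.
    """
    h = _corrected_rate(cell.hits, cell.hits + cell.misses)
    f = _corrected_rate(cell.false_alarms,
                        cell.false_alarms + cell.correct_rejections)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return float(zh - zf), float(-0.5 * (zh + zf))


def sdt_cells_from_trials(trials: pd.DataFrame) -> list[SdtCell]:
    """Tally same/different trials into per-participant, per-cell counts.

    Expects columns ``participant, congruency, alignment, trial_type,
    response`` with trial_type/response in {"same", "different"}.
    """
    cells = []
    group_cols = ["participant", "congruency", "alignment"]
    for (pid, cong, align), grp in trials.groupby(group_cols):
        signal = grp[grp["trial_type"] == "different"]
        noise = grp[grp["trial_type"] == "same"]
        cells.append(SdtCell(
            participant=pid, congruency=cong, alignment=align,
            hits=int((signal["response"] == "different").sum()),
            misses=int((signal["response"] == "same").sum()),
            false_alarms=int((noise["response"] == "different").sum()),
            correct_rejections=int((noise["response"] == "same").sum()),
        ))
    return cells


def rm_anova_2x2(scores: pd.DataFrame, dv: str = "value") -> pd.DataFrame:
    """2 x 2 repeated-measures ANOVA on per-participant cell scores.

    ``scores`` has one row per participant x congruency x alignment cell
    with the dependent variable in column ``dv``.  Each effect (two main
    effects and the interaction) is tested against its participant-by-
    effect interaction; the table reports F, df, MSE, p and partial eta
    squared.
    """
    needed = {"participant", "congruency", "alignment", dv}
    if not needed <= set(scores.columns):
        raise ValueError(f"scores must have columns {sorted(needed)}")
    counts = scores.groupby(["participant", "congruency", "alignment"]).size()
    n_participants = scores["participant"].nunique()
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    if len(counts) != n_participants * 4 or (counts != 1).any():
        raise ValueError("every participant needs exactly one score per "
                         "congruency x alignment cell")
    wide = scores.pivot_table(index="participant",
                              columns=["congruency", "alignment"], values=dv)
    y = wide.to_numpy()  # columns (c1,a1),(c1,a2),(c2,a1),(c2,a2)
    n = y.shape[0]
    # orthonormal-in-effect within-subject contrasts: each effect's F is
    # the one-sample F of its per-participant contrast scores
    contrasts = (
        ("congruency", np.array([1.0, 1.0, -1.0, -1.0]) / 2.0),
        ("alignment", np.array([1.0, -1.0, 1.0, -1.0]) / 2.0),
        ("congruency x alignment", np.array([1.0, -1.0, -1.0, 1.0]) / 2.0),
    )
    rows = []
    for effect, c in contrasts:
        L = y @ c
        ss_eff = n * float(L.mean()) ** 2
        ss_err = float(((L - L.mean()) ** 2).sum())
        dfd = n - 1
        mse = ss_err / dfd
        f = ss_eff / mse if mse > 0 else (0.0 if ss_eff == 0 else np.inf)
        p = float(stats.f.sf(f, 1, dfd)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append({"effect": effect, "F": f, "df_num": 1.0,
                     "df_den": float(dfd), "MSE": mse, "p": p,
                     "partial_eta_sq": eta})
    return pd.DataFrame(rows)


def composite_face_analysis(trials: pd.DataFrame
                            ) -> dict[str, pd.DataFrame]:
    """Full composite-task pipeline: per-cell indices and the two ANOVAs.

    Returns the per-participant d'/criterion table and the repeated-
    measures ANOVA tables for both indices.
    """
    cells = sdt_cells_from_trials(trials)
    rows = []
    for cell in cells:
        dprime, criterion = sdt_indices(cell)
        rows.append({"participant": cell.participant,
                     "congruency": cell.congruency,
                     "alignment": cell.alignment,
                     "d_prime": dprime, "criterion": criterion})
    indices = pd.DataFrame(rows)
    out = {"indices": indices}
    for dv in ("d_prime", "criterion"):
        scores = indices.rename(columns={dv: "value"})[
            ["participant", "congruency", "alignment", "value"]]
        out[f"anova_{dv}"] = rm_anova_2x2(scores)
    return out
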