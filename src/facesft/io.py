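"""Trial-table I/O and response-time trimming.

The on-disk contract is a tidy UTF-8 CSV with header columns
``participant,condition,session,x_level,y_level,response,rt_ms``.
``response`` is one of ``target``/``contrast``; ``rt_ms`` is a positive
response time in milliseconds.  ``correct`` is always derived from the
design's conjunctive rule, never read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .design import StimulusDesign, assign_role

__all__ = ["TrialTable", "read_trials", "write_trials", "trim_rts", "SchemaError"]

REQUIRED_COLUMNS = (
    "participant",
    "condition",
    "session",
    "x_level",
    "y_level",
    "response",
    "rt_ms",
)

VALID_CONDITIONS = ("aligned", "misaligned")
VALID_RESPONSES = ("target", "contrast")

RT_FLOOR_MS = 200.0  # trials faster than this are discarded as anticipations


class SchemaError(ValueError):
    """A trials file does not conform to the documented schema."""


@dataclass
class TrialTable:
    """Validated trial-level records plus provenance metadata.

    ``df`` carries the schema columns plus derived ``correct`` (bool) and
    ``role`` (stimulus role string).
    """

    df: pd.DataFrame
    design: StimulusDesign
    source: str | None = None
    trim_report: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.df)

    def for_participant(self, participant: str) -> pd.DataFrame:
        return self.df[self.df["participant"] == participant]

    @property
    def participants(self) -> list[str]:
        return sorted(self.df["participant"].unique())


def _validate(df: pd.DataFrame, design: StimulusDesign) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = df.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = ~np.isfinite(rt) | (rt <= 0)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"invalid rt_ms at row {idx}: {df['rt_ms'].iloc[idx]!r}")
    df["rt_ms"] = rt.astype(float)
    for col in ("x_level", "y_level"):
        lv = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(lv) | ~lv.isin((0, 1, 2))
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{col} out of range at row {idx}: {df[col].iloc[idx]!r}")
        df[col] = lv.astype(int)
    bad = ~df["response"].isin(VALID_RESPONSES)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"invalid response at row {idx}: {df['response'].iloc[idx]!r}")
    bad = ~df["condition"].isin(VALID_CONDITIONS)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"invalid condition at row {idx}: {df['condition'].iloc[idx]!r}")
    df["session"] = pd.to_numeric(df["session"]).astype(int)
    if (df["session"] < 1).any():
        raise SchemaError("session indices must be >= 1")
    is_target = df.apply(lambda r: design.is_target(r["x_level"], r["y_level"]), axis=1)
    df["correct"] = np.where(is_target, df["response"] == "target",
                             df["response"] == "contrast")
    df["role"] = [assign_role(x, y).value
                  for x, y in zip(df["x_level"], df["y_level"])]
    return df


def read_trials(path: str | Path, design: StimulusDesign) -> TrialTable:
    """Read and validate a trials CSV against the documented schema."""
    df = pd.read_csv(path, encoding="utf-8")
    return TrialTable(df=_validate(df, design), design=design, source=str(path))


def from_dataframe(df: pd.DataFrame, design: StimulusDesign,
                   source: str | None = None) -> TrialTable:
    """Build a validated TrialTable from an in-memory frame."""
    return TrialTable(df=_validate(df, design), design=design, source=source)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write the schema columns (derived columns are not persisted)."""
    table.df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False,
                                                   encoding="utf-8")


def trim_rts(table: TrialTable, floor_ms: float = RT_FLOOR_MS,
             sd_mult: float = 3.0) -> tuple[TrialTable, pd.DataFrame]:
    """Single-pass RT trimming: absolute floor, then a per-cell upper fence.

    Trials with ``rt < floor_ms`` are removed first; then, within each
    (participant, x_level, y_level) item cell, trials with
    ``rt > mean + sd_mult * SD`` — mean and SD computed on the floored data
    for that cell — are removed.  The fence uses a strict inequality and is
    not iterated.  Cells with a single remaining trial (SD undefined) only
    apply the floor.

    Returns the kept table and a per-cell report with columns
    ``participant, x_level, y_level, n_before, n_removed_floor,
    n_removed_upper, fraction_removed``.
    """
    df = table.df
    rows = []
    kept_masks = []
    for (p, x, y), cell in df.groupby(["participant", "x_level", "y_level"],
                                      sort=True):
        rt = cell["rt_ms"].to_numpy()
        above_floor = rt >= floor_ms
        n_floor = int((~above_floor).sum())
        floored = rt[above_floor]
        keep = above_floor.copy()
        n_upper = 0
        if floored.size >= 2:
            fence = floored.mean() + sd_mult * floored.std(ddof=1)
            over = above_floor & (rt > fence)
            n_upper = int(over.sum())
            keep = above_floor & ~over
        kept_masks.append(pd.Series(keep, index=cell.index))
        n = len(cell)
        rows.append({
            "participant": p, "x_level": x, "y_level": y, "n_before": n,
            "n_removed_floor": n_floor, "n_removed_upper": n_upper,
            "fraction_removed": (n_floor + n_upper) / n if n else 0.0,
        })
    if kept_masks:
        keep_all = pd.concat(kept_masks).reindex(df.index).fillna(False)
    else:
        keep_all = pd.Series(False, index=df.index)
    report = pd.DataFrame(rows)
    kept = TrialTable(df=df[keep_all.astype(bool)].reset_index(drop=True),
                      design=table.design, source=table.source,
                      trim_report=report)
    return kept, report
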