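"""Per-ROI, per-state summary statistics and the Friedman repeated-measures test.

The experimental design is repeated measures: every participant is observed in
all three states (baseline, stress, relax), several frames per state.  Summary
cells are sample mean and SD (n-1 denominator) of the per-frame ROI means.
The Friedman test ranks each subject's three per-phase mean temperatures and
asks whether the rank sums deviate from exchangeability:

    Q = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1)

with the standard tie correction (divide by ``1 - sum(t^3 - t) / (n k (k^2-1))``
over tied groups within blocks) and p from the chi-square distribution with
k - 1 degrees of freedom.  Blocks default to subjects (per-phase means), which
respects within-subject correlation; frame-level blocks are available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi_extraction import ROI_NAMES

__all__ = [
    "STATE_ORDER",
    "FriedmanResult",
    "summarize_by_state",
    "per_subject_phase_means",
    "friedman_test",
    "friedman_by_roi",
    "write_summary",
]

STATE_ORDER = ("baseline", "stress", "relax")


@dataclass
class FriedmanResult:
    statistic: float  # Q, chi-square distributed under the null
    p_value: float
    n_blocks: int
    k: int = 3


def _check_phases(df: pd.DataFrame) -> None:
    bad = set(df["phase"]) - set(STATE_ORDER)
    if bad:
        raise ValueError(f"unexpected phase labels {sorted(bad)}")


def summarize_by_state(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and n per (ROI, phase) cell.

    Raises when a phase has fewer than two rows (SD undefined).
    """
    if table.empty:
        raise ValueError("empty feature table")
    _check_phases(table)
    counts = table.groupby("phase").size()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(f"SD undefined: phases with < 2 rows: {list(thin.index)}")
    rows = []
    for roi in ROI_NAMES:
        for phase in STATE_ORDER:
            vals = table.loc[table["phase"] == phase, roi].to_numpy(dtype=float)
            rows.append(
                {
                    "roi": roi,
                    "phase": phase,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def per_subject_phase_means(
    table: pd.DataFrame, roi: str, allow_unbalanced: bool = False
) -> np.ndarray:
    """n_subjects x 3 matrix of each subject's mean ROI temperature per phase.

    Columns follow ``STATE_ORDER``.  Requires a balanced table (equal frame
    counts in every subject x phase cell) unless ``allow_unbalanced``.
    """
    if roi not in ROI_NAMES:
        raise ValueError(f"unknown ROI {roi!r}")
    _check_phases(table)
    counts = table.groupby(["participant_id", "phase"]).size()
    if not allow_unbalanced and counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal frame counts per subject/phase")
    pivot = table.pivot_table(
        index="participant_id", columns="phase", values=roi, aggfunc="mean"
    )
    if pivot.isna().any().any():
        raise ValueError("subject missing a phase")
    return pivot[list(STATE_ORDER)].to_numpy(dtype=float)


def friedman_test(block_matrix: np.ndarray) -> FriedmanResult:
    """Friedman rank test over an n x k block matrix (blocks = rows).

    Ties within a block get mean ranks; the tie-corrected statistic is
    referred to chi-square with k - 1 df.  A fully tied matrix returns
    Q = 0, p = 1.
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("block matrix must be 2-D")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 blocks and >= 2 treatments, got {m.shape}")
    if np.any(~np.isfinite(m)):
        raise ValueError("block matrix contains missing values")

    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    # tie correction: sum over blocks of sum(t^3 - t) across tied groups
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:  # every block fully tied
        return FriedmanResult(statistic=0.0, p_value=1.0, n_blocks=n, k=k)
    q /= denom
    p = float(sps.chi2.sf(q, k - 1))
    return FriedmanResult(statistic=float(q), p_value=min(max(p, 0.0), 1.0), n_blocks=n, k=k)


def friedman_by_roi(
    table: pd.DataFrame, subject_level: bool = True
) -> dict[str, FriedmanResult]:
    """Friedman test per ROI; blocks are subjects (default) or single frames.

    Frame-level blocks pair the i-th frame of each phase within a subject and
    exist only as a sensitivity check on the aggregation level.
    """
    out = {}
    for roi in ROI_NAMES:
        if subject_level:
            m = per_subject_phase_means(table, roi)
        else:
            blocks = []
            for _, sub in table.groupby("participant_id"):
                per_phase = [
                    sub.loc[sub["phase"] == ph, roi].to_numpy(dtype=float)
                    for ph in STATE_ORDER
                ]
                depth = min(len(v) for v in per_phase)
                blocks.extend(np.column_stack([v[:depth] for v in per_phase]))
            m = np.asarray(blocks)
        out[roi] = friedman_test(m)
    return out


def write_summary(
    summary: pd.DataFrame, friedman: dict[str, FriedmanResult], path
) -> pd.DataFrame:
    """Export a wide per-ROI table: mean/SD per state plus Q, p, significance."""
    rows = []
    for roi in ROI_NAMES:
        row: dict = {"roi": roi}
        for phase in STATE_ORDER:
            cell = summary[(summary["roi"] == roi) & (summary["phase"] == phase)]
            row[f"{phase}_mean"] = round(float(cell["mean"].iloc[0]), 2)
            row[f"{phase}_sd"] = round(float(cell["sd"].iloc[0]), 2)
        res = friedman[roi]
        row["friedman_q"] = round(res.statistic, 2)
        row["friedman_p"] = round(res.p_value, 4)
        row["p_lt_0.05"] = bool(res.p_value < 0.05)
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
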