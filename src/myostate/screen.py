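"""Drug-screen scoring on well compositions: differentiating and
dedifferentiating scores, hit calling, ranking, and cross-culture
intersection.

Scores operate on the five-state well percentages (0-100 scale):

* differentiating score =
  (%committed + %differentiated - %cycling progenitors) of the treated
  well minus the same bracket for the untreated control;
* dedifferentiating score =
  (%quiescent MuSC-like + %cycling MuSC-like) treated minus control.

A differentiating hit strictly increases committed+differentiated and
strictly decreases cycling progenitors versus control (an optional
minimum-effect margin guards against plate noise; default 0).  A
dedifferentiating hit enriches the MuSC-like fraction at least 1.5-fold.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .gating import STATES

__all__ = [
    "differentiating_score",
    "dedifferentiating_score",
    "musc_fold_change",
    "is_differentiating_hit",
    "is_dedifferentiating_hit",
    "combined_differentiating_score",
    "average_compositions",
    "score_screen",
    "rank_and_intersect",
]

_PCT_COLS = [f"pct_{s}" for s in STATES]
_DIFF_DOSES = (10.0, 1.0, 0.1, 0.01)


def _bracket_diff(comp: Mapping[str, float]) -> float:
    return (
        comp["pct_committed"]
        + comp["pct_differentiated"]
        - comp["pct_cycling_progenitor"]
    )


def _musc(comp: Mapping[str, float]) -> float:
    return comp["pct_quiescent_musc"] + comp["pct_cycling_musc"]


def _check(comp: Mapping[str, float]) -> None:
    missing = [c for c in _PCT_COLS if c not in comp]
    if missing:
        raise ValueError(f"composition lacks columns: {missing}")


def differentiating_score(
    treated: Mapping[str, float], control: Mapping[str, float]
) -> float:
    """Differentiating score of a treated composition versus control."""
    _check(treated)
    _check(control)
    return float(_bracket_diff(treated) - _bracket_diff(control))


def dedifferentiating_score(
    treated: Mapping[str, float], control: Mapping[str, float]
) -> float:
    """Dedifferentiating (MuSC-like enrichment) score versus control."""
    _check(treated)
    _check(control)
    return float(_musc(treated) - _musc(control))


def musc_fold_change(
    treated: Mapping[str, float], control: Mapping[str, float]
) -> float:
    """Fold change of the MuSC-like percentage (quiescent + cycling).

    A zero-control fraction yields +inf when the treated fraction is
    positive and NaN when both are zero.
    """
    _check(treated)
    _check(control)
    t, c = _musc(treated), _musc(control)
    if c == 0:
        return float("inf") if t > 0 else float("nan")
    return float(t / c)


def is_differentiating_hit(
    treated: Mapping[str, float],
    control: Mapping[str, float],
    margin: float = 0.0,
) -> bool:
    """Hit iff committed+differentiated strictly increases and cycling
    progenitors strictly decrease versus control (by more than ``margin``
    percentage points each)."""
    _check(treated)
    _check(control)
    up = (
        treated["pct_committed"] + treated["pct_differentiated"]
        > control["pct_committed"] + control["pct_differentiated"] + margin
    )
    down = (
        treated["pct_cycling_progenitor"]
        < control["pct_cycling_progenitor"] - margin
    )
    return bool(up and down)


def is_dedifferentiating_hit(
    treated: Mapping[str, float],
    control: Mapping[str, float],
    fold_threshold: float = 1.5,
) -> bool:
    """Hit iff the MuSC-like fraction is enriched at least ``fold_threshold``
    fold over control (boundary inclusive)."""
    fold = musc_fold_change(treated, control)
    return bool(not np.isnan(fold) and fold >= fold_threshold)


def combined_differentiating_score(
    per_dose_scores: Mapping[float, float],
    backbone_score: float,
    doses: tuple[float, ...] = _DIFF_DOSES,
    allow_partial: bool = False,
) -> float:
    """Combination-screen score: mean of the per-dose differentiating scores
    minus the backbone compound's own score.

    All four doses (10 uM, 1 uM, 100 nM, 10 nM by default) must be present
    unless ``allow_partial``.
    """
    if backbone_score is None:
        raise ValueError("backbone_score is required")
    present = [d for d in doses if d in per_dose_scores]
    missing = [d for d in doses if d not in per_dose_scores]
    if missing and not allow_partial:
        raise ValueError(f"missing dose scores: {missing}")
    if not present:
        raise ValueError("no dose scores available")
    return float(np.mean([per_dose_scores[d] for d in present]) - backbone_score)


def average_compositions(compositions: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells at the composition level per
    plate x compound x dose (keeping the control-cancellation identity
    exact), summing nuclei counts."""
    agg = {c: "mean" for c in _PCT_COLS}
    agg["n_nuclei"] = "sum"
    out = (
        compositions.groupby(["plate", "compound", "dose_um"], sort=True)
        .agg(agg)
        .reset_index()
    )
    return out


def score_screen(
    compositions: pd.DataFrame,
    control_compound: str = "DMSO",
    hit_dose: float = 1.0,
    fold_threshold: float = 1.5,
    diff_margin: float = 0.0,
) -> pd.DataFrame:
    """Score every compound x dose of a screen against its plate's untreated
    control.

    Replicate wells are averaged at the composition level before scoring.
    Hits are called at ``hit_dose`` (other doses carry NA hit flags).
    Returns one row per plate x compound x dose with ``s_diff``,
    ``s_dediff``, ``fold_musc``, ``is_diff_hit`` and ``is_dediff_hit``.
    """
    avg = average_compositions(compositions)
    results = []
    for plate, grp in avg.groupby("plate", sort=True):
        ctrl_rows = grp[grp["compound"] == control_compound]
        if ctrl_rows.empty:
            raise ValueError(f"plate {plate!r} has no control compound "
                             f"{control_compound!r}")
        control = ctrl_rows[_PCT_COLS].mean()
        for _, row in grp.iterrows():
            if row["compound"] == control_compound:
                continue
            at_hit_dose = row["dose_um"] == hit_dose
            results.append(
                {
                    "plate": plate,
                    "compound": row["compound"],
                    "dose_um": row["dose_um"],
                    "s_diff": differentiating_score(row, control),
                    "s_dediff": dedifferentiating_score(row, control),
                    "fold_musc": musc_fold_change(row, control),
                    "is_diff_hit": (
                        is_differentiating_hit(row, control, margin=diff_margin)
                        if at_hit_dose
                        else pd.NA
                    ),
                    "is_dediff_hit": (
                        is_dedifferentiating_hit(
                            row, control, fold_threshold=fold_threshold
                        )
                        if at_hit_dose
                        else pd.NA
                    ),
                }
            )
    return pd.DataFrame(
        results,
        columns=[
            "plate", "compound", "dose_um", "s_diff", "s_dediff",
            "fold_musc", "is_diff_hit", "is_dediff_hit",
        ],
    )


def rank_and_intersect(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    hit_col: str = "is_diff_hit",
    score_col: str = "s_diff",
) -> pd.DataFrame:
    """Shared hits of two screens, ranked by the mean of the two scores.

    Compounds flagged hit in both inputs are retained; ties in the mean
    score break lexicographically by compound identifier.  Disjoint hit
    sets yield an empty table.
    """
    def hits(res: pd.DataFrame) -> pd.DataFrame:
        mask = res[hit_col].fillna(False).astype(bool)
        return res[mask].groupby("compound")[score_col].mean()

    a, b = hits(results_a), hits(results_b)
    shared = sorted(set(a.index) & set(b.index))
    out = pd.DataFrame(
        {
            "compound": shared,
            "score_a": [a[c] for c in shared],
            "score_b": [b[c] for c in shared],
        }
    )
    out["mean_score"] = (out["score_a"] + out["score_b"]) / 2.0
    out = out.sort_values(
        ["mean_score", "compound"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
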