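"""High-content image-screen gating of myogenic cell states.

Cells stained for myogenin, Ki-67 and myosin heavy chain (MyHC) are assigned
to one of five myogenic states:

    quiescent MuSC-like     myogenin-  Ki-67-
    cycling MuSC-like       myogenin-  Ki-67+
    cycling progenitor      myogenin+  Ki-67+  MyHC-
    committed progenitor    myogenin+  Ki-67-  MyHC-
    differentiated          MyHC+ (takes priority over the other markers)

Marker positivity is decided against per-plate background thresholds taken
from an unstained control well: a cell is positive when its intensity is
strictly above the chosen quantile (default 0.99) of the unstained
distribution for that marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "MARKERS",
    "QUIESCENT_MUSC",
    "CYCLING_MUSC",
    "CYCLING_PROGENITOR",
    "COMMITTED",
    "DIFFERENTIATED",
    "RESPONDER",
    "NONRESPONDER",
    "BackgroundThresholds",
    "estimate_background",
    "gate_cells",
    "compose_wells",
    "classify_responder",
]

QUIESCENT_MUSC = "quiescent_musc"
CYCLING_MUSC = "cycling_musc"
CYCLING_PROGENITOR = "cycling_progenitor"
COMMITTED = "committed"
DIFFERENTIATED = "differentiated"

#: Canonical state order; well compositions report percentages in this order.
STATES: tuple[str, ...] = (
    QUIESCENT_MUSC,
    CYCLING_MUSC,
    CYCLING_PROGENITOR,
    COMMITTED,
    DIFFERENTIATED,
)

#: Intensity columns expected in a per-cell imaging table.
MARKERS: tuple[str, ...] = ("int_myog", "int_ki67", "int_myhc")

RESPONDER = "RESPONDER"
NONRESPONDER = "NONRESPONDER"


@dataclass(frozen=True)
class BackgroundThresholds:
    """Per-marker background intensity thresholds from an unstained control."""

    thresholds: Mapping[str, float]
    quantile: float

    def __post_init__(self) -> None:
        missing = set(MARKERS) - set(self.thresholds)
        if missing:
            raise ValueError(f"thresholds missing markers: {sorted(missing)}")

    def __getitem__(self, marker: str) -> float:
        return float(self.thresholds[marker])


def estimate_background(
    unstained: pd.DataFrame,
    quantile: float = 0.99,
    markers: Sequence[str] = MARKERS,
) -> BackgroundThresholds:
    """Estimate per-marker background thresholds from an unstained control well.

    The threshold is the given quantile of the unstained intensity
    distribution; downstream positivity is ``intensity > threshold``.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must lie in [0, 1]")
    missing = [m for m in markers if m not in unstained.columns]
    if missing:
        raise ValueError(f"unstained table lacks marker columns: {missing}")
    if len(unstained) == 0:
        raise ValueError("unstained control table is empty")
    if len(unstained) < 50:
        warnings.warn(
            f"only {len(unstained)} unstained cells; background thresholds "
            "may be unstable",
            stacklevel=2,
        )
    thresholds = {
        m: float(np.quantile(np.asarray(unstained[m], dtype=float), quantile))
        for m in markers
    }
    return BackgroundThresholds(thresholds=thresholds, quantile=quantile)


def gate_cells(
    cells: pd.DataFrame, thresholds: BackgroundThresholds
) -> pd.Series:
    """Assign each cell one of the five myogenic states.

    MyHC positivity dominates: any MyHC+ cell is ``differentiated`` regardless
    of the other markers; the remaining cells fall into the 2x2 gate on
    (myogenin, Ki-67).
    """
    missing = [m for m in MARKERS if m not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks marker columns: {missing}")

    myog = cells["int_myog"].to_numpy(dtype=float) > thresholds["int_myog"]
    ki67 = cells["int_ki67"].to_numpy(dtype=float) > thresholds["int_ki67"]
    myhc = cells["int_myhc"].to_numpy(dtype=float) > thresholds["int_myhc"]

    labels = np.empty(len(cells), dtype=object)
    labels[myhc] = DIFFERENTIATED
    rest = ~myhc
    labels[rest & myog & ki67] = CYCLING_PROGENITOR
    labels[rest & myog & ~ki67] = COMMITTED
    labels[rest & ~myog & ki67] = CYCLING_MUSC
    labels[rest & ~myog & ~ki67] = QUIESCENT_MUSC
    return pd.Series(labels, index=cells.index, name="state")


def compose_wells(
    labels: pd.Series,
    cells: pd.DataFrame,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Summarize per-well nuclei counts and five-state percentages (0-100).

    Wells with fewer than ``min_cells`` nuclei are flagged ``low_confidence``.
    Percentages over the five states sum to 100 for every non-empty well.
    """
    required = {"plate", "well", "compound", "dose_um"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    if not labels.index.equals(cells.index):
        raise ValueError("labels must be indexed like the cell table")

    work = cells[["plate", "well", "compound", "dose_um"]].copy()
    work["state"] = labels

    rows = []
    for (plate, well), grp in work.groupby(["plate", "well"], sort=True):
        n = len(grp)
        counts = grp["state"].value_counts()
        row = {
            "plate": plate,
            "well": well,
            "compound": grp["compound"].iloc[0],
            "dose_um": grp["dose_um"].iloc[0],
            "n_nuclei": n,
            "low_confidence": n < min_cells,
        }
        for state in STATES:
            row[f"pct_{state}"] = 100.0 * counts.get(state, 0) / n
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=["plate", "well", "compound", "dose_um", "n_nuclei",
                     "low_confidence"] + [f"pct_{s}" for s in STATES]
        )
    return out


def classify_responder(
    pct_differentiated: float | np.ndarray, threshold: float = 10.0
) -> str | np.ndarray:
    """Call a sample a responder when its differentiated fraction exceeds
    ``threshold`` percent (strictly; the boundary is a non-responder)."""
    pct = np.asarray(pct_differentiated, dtype=float)
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.where(pct > threshold, RESPONDER, NONRESPONDER)
    if np.isscalar(pct_differentiated) or np.ndim(pct_differentiated) == 0:
        return str(out[()])
    return out
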