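"""Per-cell quality control and hashtag (HTO) sample demultiplexing.

QC removes low-quality cells by three printed rules: detected genes outside
[min_genes, max_genes], total UMIs outside [min_umi, max_umi], or
mitochondrial UMI percentage above max_mito_pct.  Removal bounds are strict
(<200 genes removed, 200 kept; >15% mito removed, 15% kept).

Hashtag demultiplexing normalizes raw HTO counts with a per-cell centered
log-ratio (CLR) transform and assigns each cell to the hashtag with the
maximal CLR signal; exact ties (or margins below ``min_margin``) are flagged
AMBIGUOUS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "AMBIGUOUS",
    "QCThresholds",
    "qc_metrics",
    "filter_cells",
    "clr_normalize_hto",
    "demux_hashtags",
]

AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention bounds.

    Defaults follow the standard droplet scRNA-seq practice of removing
    cells with <200 or >8000 detected genes, <1000 or >50,000 UMIs, or more
    than 15% mitochondrial UMIs.
    """

    min_genes: int = 200
    max_genes: int = 8000
    min_umi: int = 1000
    max_umi: int = 50000
    max_mito_pct: float = 15.0

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not self.min_umi < self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not 0 <= self.max_mito_pct <= 100:
            raise ValueError("max_mito_pct must lie in [0, 100]")


def qc_metrics(
    counts: CountMatrix,
    mito_features: Iterable[str] | None = None,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total UMIs, mitochondrial percent.

    Mitochondrial features are either the supplied identifier set or, when
    none is given, every feature whose name starts with ``mito_prefix``.
    Cells with zero total counts get ``mito_pct`` 0 and are flagged
    ``zero_total``.
    """
    features = pd.Index(counts.features)
    if mito_features is None:
        mito_set = set(features[features.str.startswith(mito_prefix)])
    else:
        mito_set = set(mito_features)
        unknown = mito_set - set(features)
        if unknown:
            raise ValueError(
                f"mito_features not in the matrix: {sorted(unknown)[:5]}"
            )
    if not mito_set:
        warnings.warn(
            "no mitochondrial features identified; mito_pct will be 0",
            stacklevel=2,
        )

    csc = counts.matrix.tocsc()
    n_genes = np.asarray((csc > 0).sum(axis=0)).ravel()
    n_umi = np.asarray(csc.sum(axis=0)).ravel()
    mito_mask = np.asarray(features.isin(mito_set))
    mito_umi = (
        np.asarray(csc[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros_like(n_umi)
    )
    zero_total = n_umi == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(zero_total, 0.0, 100.0 * mito_umi / np.maximum(n_umi, 1))
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(np.int64),
            "n_umi": n_umi.astype(np.int64),
            "mito_pct": mito_pct,
            "zero_total": zero_total,
        },
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def filter_cells(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.Series:
    """Boolean keep-mask applying the three QC rules.

    A cell is kept iff ``min_genes <= n_genes <= max_genes`` and
    ``min_umi <= n_umi <= max_umi`` and ``mito_pct <= max_mito_pct``
    (boundaries survive the strict removal rules).
    """
    thr = thresholds or QCThresholds()
    keep = (
        metrics["n_genes"].between(thr.min_genes, thr.max_genes)
        & metrics["n_umi"].between(thr.min_umi, thr.max_umi)
        & (metrics["mito_pct"] <= thr.max_mito_pct)
    )
    keep.name = "keep"
    return keep


def clr_normalize_hto(hto: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-cell centered log-ratio transform of raw HTO counts.

    For each cell, ``clr_h = log(x_h + pc) - mean_h log(x_h + pc)``; the CLR
    vector of every cell sums to zero.  Returns a cells-by-hashtags frame.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if hto.n_features < 2:
        raise ValueError("CLR needs at least 2 hashtags")
    x = hto.matrix.toarray().astype(np.float64)  # hashtags x cells
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(
        clr.T,
        index=pd.Index(hto.barcodes, name="barcode"),
        columns=list(hto.features),
    )


def demux_hashtags(
    clr: pd.DataFrame,
    hashtag_to_sample: Mapping[str, str],
    min_margin: float = 0.0,
) -> pd.DataFrame:
    """Assign each cell to the hashtag with maximal CLR signal.

    Cells whose top two CLR values are exactly tied or differ by less than
    ``min_margin`` are flagged :data:`AMBIGUOUS`.  ``hashtag_to_sample`` maps
    every hashtag to a sample identity and must cover all hashtags.
    """
    missing = set(clr.columns) - set(hashtag_to_sample)
    if missing:
        raise ValueError(f"hashtag_to_sample lacks hashtags: {sorted(missing)}")

    values = clr.to_numpy(dtype=float)
    order = np.argsort(values, axis=1)
    top_idx = order[:, -1]
    top = values[np.arange(len(values)), top_idx]
    second = values[np.arange(len(values)), order[:, -2]]
    margin = top - second
    ambiguous = (margin == 0) | (margin < min_margin)

    hashtags = np.asarray(clr.columns, dtype=object)
    assigned = hashtags[top_idx]
    assigned[ambiguous] = AMBIGUOUS
    sample = np.array(
        [hashtag_to_sample.get(h, AMBIGUOUS) for h in assigned], dtype=object
    )

    out = clr.rename(columns=lambda h: f"clr_{h}").copy()
    out["assigned_hashtag"] = assigned
    out["sample_id"] = sample
    return out
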