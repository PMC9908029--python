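"""Log-normalization, per-cell signature (module) scoring, cycling
classification, and marker-gene derivation.

Module scores follow the expression-bin control-gene scheme: all genes are
binned by mean expression, each signature gene draws control genes from its
own bin, and the score is the per-cell mean of the signature genes minus the
mean of the pooled control genes.  A signature of randomly drawn genes
therefore scores zero in expectation.

High-cycling cells are defined as cells with an S or G2-M score above zero;
all other cells (including exact zeros) are low-cycling.

Marker derivation keeps genes expressed in at least ``min_pct`` of the
cluster's cells with a log fold change above ``lfc_threshold`` and a
Bonferroni-corrected rank-sum p-value below ``alpha``; only overexpressed
genes (direction +1) are reported.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import CountMatrix, LogExpression

__all__ = [
    "HIGH_CYCLING",
    "LOW_CYCLING",
    "log_normalize",
    "module_score",
    "module_scores",
    "classify_cycling",
    "find_markers",
]

HIGH_CYCLING = "HIGH_CYCLING"
LOW_CYCLING = "LOW_CYCLING"


def log_normalize(counts: CountMatrix, scale: float = 10_000.0) -> LogExpression:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    Per cell, ``x -> log1p(scale * x / total)``.  Cells with zero total
    counts map to all-zero columns (with a warning).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    csc = counts.matrix.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cells have zero total counts; their "
            "normalized profiles are all-zero",
            stacklevel=2,
        )
    inv = np.where(zero, 0.0, scale / np.maximum(totals, 1e-300))
    normalized = csc @ sp.diags(inv)
    normalized.data = np.log1p(normalized.data)
    return LogExpression(
        matrix=normalized.tocsr(),
        genes=counts.features,
        barcodes=counts.barcodes,
        scale_factor=float(scale),
    )


def _expression_bins(gene_means: pd.Series, n_bins: int) -> pd.Series:
    """Bin genes into ``n_bins`` equal-size groups of mean expression."""
    ranks = gene_means.rank(method="first")
    return pd.Series(
        pd.qcut(ranks, n_bins, labels=False), index=gene_means.index
    )


def module_score(
    expr: LogExpression,
    genes: Iterable[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score for one gene set.

    Signature genes absent from the data are dropped with a warning; an
    empty overlap is an error.  For each signature gene, ``n_ctrl`` control
    genes are sampled (seeded, without replacement) from its expression bin;
    if the bin holds at most ``n_ctrl`` genes the whole bin is used.  The
    score is mean(signature genes) - mean(pooled control genes) per cell.
    """
    gene_list = list(dict.fromkeys(genes))
    index = pd.Index(expr.genes)
    present = [g for g in gene_list if g in set(index)]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if len(present) < len(gene_list):
        warnings.warn(
            f"{len(gene_list) - len(present)} signature genes absent; dropped",
            stacklevel=2,
        )

    n_bins = min(n_bins, expr.n_genes)
    dense = expr.matrix  # genes x cells, csr
    gene_means = pd.Series(
        np.asarray(dense.mean(axis=1)).ravel(), index=index
    )
    bins = _expression_bins(gene_means, n_bins)
    by_bin = {b: idx.to_numpy() for b, idx in bins.groupby(bins).groups.items()}

    rng = np.random.default_rng(seed)
    controls: list[str] = []
    for g in present:
        pool = by_bin[bins[g]]
        if len(pool) <= n_ctrl:
            controls.extend(pool.tolist())
        else:
            controls.extend(rng.choice(pool, size=n_ctrl, replace=False).tolist())

    loc = {g: i for i, g in enumerate(index)}
    sig_rows = np.array([loc[g] for g in present])
    ctrl_rows = np.array([loc[g] for g in controls])
    sig_mean = np.asarray(dense[sig_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(dense[ctrl_rows].mean(axis=0)).ravel()
    return pd.Series(
        sig_mean - ctrl_mean, index=pd.Index(expr.barcodes, name="barcode"),
        name="module_score",
    )


def module_scores(
    expr: LogExpression,
    signatures: Mapping[str, Iterable[str]],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Module scores for several signatures; one column per signature."""
    return pd.DataFrame(
        {
            name: module_score(expr, genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
            for name, genes in signatures.items()
        }
    )


def classify_cycling(
    s_score: float | np.ndarray | pd.Series,
    g2m_score: float | np.ndarray | pd.Series,
) -> str | np.ndarray | pd.Series:
    """High/low-cycling rule: HIGH iff S score > 0 or G2-M score > 0.

    Exact zeros classify as LOW_CYCLING.  Accepts scalars or aligned arrays.
    """
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(g))):
        raise ValueError("cycling scores must be finite")
    label = np.where((s > 0) | (g > 0), HIGH_CYCLING, LOW_CYCLING)
    if isinstance(s_score, pd.Series):
        return pd.Series(label, index=s_score.index, name="cycling")
    if np.ndim(s_score) == 0:
        return str(label[()])
    return label


def _cluster_stats(
    dense: np.ndarray, masks: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    means = {c: dense[:, m].mean(axis=1) for c, m in masks.items()}
    pcts = {c: (dense[:, m] > 0).mean(axis=1) for c, m in masks.items()}
    return means, pcts


def find_markers(
    expr: LogExpression,
    labels: pd.Series | Mapping[str, str],
    min_pct: float = 0.05,
    lfc_threshold: float = 0.25,
    alpha: float = 0.05,
    mode: str = "one_vs_rest",
) -> pd.DataFrame:
    """Derive per-cluster marker genes (overexpressed only, direction +1).

    ``one_vs_rest`` compares each cluster against all remaining cells;
    ``pairwise`` retains genes passing the fraction and fold-change
    thresholds against *every* other cluster (reporting the weakest fold
    change and the largest p-value across comparisons).  P-values come from
    the two-sided rank-sum (Mann-Whitney) test and are Bonferroni-corrected
    by the number of tests actually performed.
    """
    if mode not in ("one_vs_rest", "pairwise"):
        raise ValueError("mode must be 'one_vs_rest' or 'pairwise'")
    labels = pd.Series(labels)
    if not labels.index.equals(pd.Index(expr.barcodes)):
        labels = labels.reindex(expr.barcodes)
        if labels.isna().any():
            raise ValueError("labels must cover every cell")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    masks = {c: (labels == c).to_numpy() for c in clusters}
    for c, m in masks.items():
        if m.sum() < 3:
            raise ValueError(f"cluster {c!r} has fewer than 3 cells")

    dense = expr.matrix.toarray()
    gene_index = pd.Index(expr.genes)
    means, pcts = _cluster_stats(dense, masks)

    records: list[dict] = []
    n_tests = 0
    for c in clusters:
        in_mask = masks[c]
        if mode == "one_vs_rest":
            rest_mask = ~in_mask
            lfc = means[c] - dense[:, rest_mask].mean(axis=1)
            cand = (pcts[c] >= min_pct) & (lfc > lfc_threshold)
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                continue
            pvals = stats.mannwhitneyu(
                dense[np.ix_(idx, in_mask)],
                dense[np.ix_(idx, rest_mask)],
                axis=1,
                alternative="two-sided",
            ).pvalue
            n_tests += idx.size
            for i, p in zip(idx, pvals):
                records.append(
                    {
                        "cluster": c,
                        "gene": gene_index[i],
                        "log_fold_change": float(lfc[i]),
                        "pct_in_cluster": float(pcts[c][i]),
                        "p_value": float(p),
                    }
                )
        else:
            others = [d for d in clusters if d != c]
            lfc_all = np.stack([means[c] - means[d] for d in others])
            cand = (pcts[c] >= min_pct) & np.all(lfc_all > lfc_threshold, axis=0)
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                continue
            pmax = np.zeros(idx.size)
            for d in others:
                p = stats.mannwhitneyu(
                    dense[np.ix_(idx, in_mask)],
                    dense[np.ix_(idx, masks[d])],
                    axis=1,
                    alternative="two-sided",
                ).pvalue
                n_tests += idx.size
                pmax = np.maximum(pmax, p)
            lfc_min = lfc_all.min(axis=0)
            for k, i in enumerate(idx):
                records.append(
                    {
                        "cluster": c,
                        "gene": gene_index[i],
                        "log_fold_change": float(lfc_min[i]),
                        "pct_in_cluster": float(pcts[c][i]),
                        "p_value": float(pmax[k]),
                    }
                )

    table = pd.DataFrame(
        records,
        columns=["cluster", "gene", "log_fold_change", "pct_in_cluster", "p_value"],
    )
    if table.empty:
        table["p_bonferroni"] = pd.Series(dtype=float)
        table["direction"] = pd.Series(dtype=int)
        return table
    table["p_bonferroni"] = np.minimum(table["p_value"] * n_tests, 1.0)
    table["direction"] = 1
    table = table[table["p_bonferroni"] < alpha]
    table = table.sort_values(
        ["cluster", "log_fold_change", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table
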