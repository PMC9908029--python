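"""Disk I/O for the standard formats used across the pipeline.

Count matrices follow the 10x convention: ``matrix.mtx`` (Matrix Market,
1-based indices, features on rows) alongside ``features.tsv`` and
``barcodes.tsv``.  Signatures travel as GMT (unsigned, all +1) or
two-column TSV (gene, direction in {+1, -1}); cohorts and cell tables are
plain CSV with a header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CohortTable, CountMatrix, SignedSignature
from .gating import MARKERS

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_signature_tsv",
    "read_signature_tsv",
    "write_gmt",
    "read_gmt",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cell_table",
    "read_cell_table",
]

_CELL_TABLE_COLUMNS = ["plate", "well", "compound", "dose_um", "cell_id", *MARKERS]


def write_count_matrix(counts: CountMatrix, directory: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        directory / "matrix.mtx", counts.matrix.tocoo(), field="integer"
    )
    pd.Series(counts.features).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    return directory


def read_count_matrix(directory: str | Path, modality: str = "rna") -> CountMatrix:
    """Read a 10x-style Matrix Market triple written by
    :func:`write_count_matrix`."""
    directory = Path(directory)
    matrix = sp.csr_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    features = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None
    )[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None
    )[0].to_numpy(dtype=object)
    return CountMatrix(
        matrix=matrix, features=features, barcodes=barcodes, modality=modality
    )


def write_signature_tsv(signature: SignedSignature, path: str | Path) -> Path:
    """Write a signed signature as two-column TSV (gene, direction)."""
    path = Path(path)
    frame = pd.DataFrame(
        {"gene": signature.genes, "direction": signature.directions.to_numpy()}
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_signature_tsv(path: str | Path, name: str | None = None) -> SignedSignature:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if not {"gene", "direction"} <= set(frame.columns):
        raise ValueError("signature TSV needs 'gene' and 'direction' columns")
    directions = pd.Series(
        frame["direction"].to_numpy(dtype=np.int64),
        index=frame["gene"].astype(str),
    )
    return SignedSignature(name=name or path.stem, directions=directions)


def write_gmt(signatures: Mapping[str, SignedSignature], path: str | Path) -> Path:
    """Write signatures as GMT (direction information is not preserved)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, sig in signatures.items():
            fh.write("\t".join([name, "", *sig.genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, SignedSignature]:
    """Read a GMT file; every gene gets direction +1 (GMT is unsigned)."""
    out: dict[str, SignedSignature] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], [g for g in parts[2:] if g]
            out[name] = SignedSignature.from_genes(name, up=genes)
    return out


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV: patient_id, status, then one column per gene."""
    path = Path(path)
    frame = cohort.expression.copy()
    frame.insert(0, "status", cohort.status)
    frame.to_csv(path, index_label="patient_id")
    return path


def read_cohort_csv(path: str | Path) -> CohortTable:
    frame = pd.read_csv(path, index_col="patient_id")
    if "status" not in frame.columns:
        raise ValueError("cohort CSV needs a 'status' column")
    status = frame["status"].astype(str)
    expression = frame.drop(columns="status").astype(float)
    return CohortTable(expression=expression, status=status)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in _CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks columns: {missing}")
    path = Path(path)
    cells.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in _CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks columns: {missing}")
    return cells
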