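"""Core in-memory containers shared across the pipeline stages.

The containers are deliberately thin: a sparse count matrix with feature and
barcode identifiers (10x convention: features on rows, cells on columns), a
log-normalized expression matrix, a signed gene signature, and a patient
cohort table.  Heavy lifting lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "LogExpression",
    "SignedSignature",
    "CohortTable",
]


def _as_str_array(values: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(set(arr)) != len(arr):
        raise ValueError(f"duplicate {what} identifiers")
    return arr


@dataclass
class CountMatrix:
    """Sparse features-by-cells integer count matrix (RNA or HTO modality)."""

    matrix: sp.spmatrix
    features: np.ndarray
    barcodes: np.ndarray
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.features = _as_str_array(self.features, "feature")
        self.barcodes = _as_str_array(self.barcodes, "barcode")
        n_feat, n_cells = self.matrix.shape
        if n_feat != len(self.features) or n_cells != len(self.barcodes):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense features x barcodes DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.features, columns=self.barcodes
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.modality == other.modality
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.barcodes, other.barcodes)
            and self.matrix.shape == other.matrix.shape
            and (self.matrix != other.matrix).nnz == 0
        )


@dataclass
class LogExpression:
    """Genes-by-cells log1p-normalized expression with its scale factor."""

    matrix: sp.spmatrix
    genes: np.ndarray
    barcodes: np.ndarray
    scale_factor: float

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix, dtype=np.float64)
        self.genes = _as_str_array(self.genes, "gene")
        self.barcodes = _as_str_array(self.barcodes, "barcode")
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode identifiers")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.barcodes
        )


@dataclass
class SignedSignature:
    """Named gene set where every gene carries an up (+1) / down (-1) direction.

    The direction signs each gene's contribution to the cohort statistic:
    down-regulated members enter the average fold change with a minus sign.
    """

    name: str
    directions: pd.Series  # gene -> +1 / -1

    def __post_init__(self) -> None:
        self.directions = pd.Series(self.directions, dtype=np.int64)
        if self.directions.empty:
            raise ValueError(f"signature {self.name!r} is empty")
        if self.directions.index.has_duplicates:
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        bad = set(self.directions.unique()) - {1, -1}
        if bad:
            raise ValueError(f"signature directions must be +1 or -1, got {sorted(bad)}")

    @classmethod
    def from_genes(
        cls,
        name: str,
        up: Iterable[str] = (),
        down: Iterable[str] = (),
    ) -> "SignedSignature":
        directions: dict[str, int] = {g: 1 for g in up}
        for g in down:
            if g in directions:
                raise ValueError(f"gene {g!r} listed as both up and down")
            directions[g] = -1
        return cls(name=name, directions=pd.Series(directions, dtype=np.int64))

    @property
    def genes(self) -> list[str]:
        return list(self.directions.index)

    @property
    def up_genes(self) -> list[str]:
        return list(self.directions.index[self.directions == 1])

    @property
    def down_genes(self) -> list[str]:
        return list(self.directions.index[self.directions == -1])

    def __len__(self) -> int:
        return len(self.directions)


LIVE = "live"
DEAD = "dead"


@dataclass
class CohortTable:
    """Patients-by-genes log-scale expression with a live/dead vital status."""

    expression: pd.DataFrame  # patients x genes
    status: pd.Series  # patient -> "live" / "dead"

    def __post_init__(self) -> None:
        self.expression = pd.DataFrame(self.expression, dtype=np.float64)
        self.status = pd.Series(self.status, dtype=object)
        if not self.expression.index.equals(self.status.index):
            raise ValueError("expression rows and status index must match")
        if self.expression.columns.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        bad = set(self.status.unique()) - {LIVE, DEAD}
        if bad:
            raise ValueError(f"status must be 'live' or 'dead', got {sorted(bad)}")

    @property
    def n_patients(self) -> int:
        return len(self.status)

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    def status_counts(self) -> Mapping[str, int]:
        vc = self.status.value_counts()
        return {LIVE: int(vc.get(LIVE, 0)), DEAD: int(vc.get(DEAD, 0))}
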