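"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline can be exercised without external
data: this module generates (a) multi-state single-cell UMI counts with
planted marker structure and a controllable mitochondrial fraction, (b)
hashtag-oligo (HTO) counts with one dominant hashtag per cell, (c) plate-based
per-cell marker-intensity tables with drug-induced composition shifts, and
(d) a patient cohort with live/dead labels and an optional planted signed
signature.

All generators are pure functions of a :class:`SimConfig` (including its
seed): identical configurations produce byte-identical outputs.

Model choices
-------------
* UMI counts are negative binomial with a shared dispersion, the standard
  overdispersed count model for droplet data.  Per-state marker genes are
  elevated by ``marker_log2fc`` (log2 units) in their state.
* A designated set of mitochondrial genes (named ``MT-*``) receives a fixed,
  per-cell fraction of the cell's UMIs drawn from ``mito_fraction_range``,
  so the mitochondrial percentage is exactly controllable.
* Imaging intensities are two-component lognormals per marker; the
  separation between the negative and positive component is a configuration
  knob so both easy and hard gating regimes are testable.
* Cohort expression is Gaussian directly on the log2 scale (the survival
  statistic operates on log expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CohortTable, CountMatrix, SignedSignature
from .gating import DIFFERENTIATED, MARKERS, STATES

__all__ = [
    "WellSpec",
    "CohortConfig",
    "SimConfig",
    "simulate_counts",
    "simulate_hto",
    "simulate_plate",
    "simulate_cohort",
    "marker_genes",
    "mito_genes",
    "screen_layout",
]


class WellSpec(NamedTuple):
    """A well's treatment and its true five-state composition.

    The composition is a probability vector over :data:`myostate.gating.STATES`
    (canonical order) and must sum to 1 within 1e-9.
    """

    compound: str
    dose_um: float
    composition: tuple[float, ...]


@dataclass(frozen=True)
class CohortConfig:
    """Planted structure for a synthetic patient cohort."""

    n_live: int = 30
    n_dead: int = 30
    planted_signature: SignedSignature | None = None
    effect_log2fc: float = 1.0
    noise_sd: float = 1.0


# Marker positivity per state: (myogenin, Ki-67, MyHC).  Differentiated cells
# are drawn MyHC+ (myogenin+, post-mitotic) though only MyHC matters for the
# gate, which gives it priority.
_STATE_POSITIVITY: dict[str, tuple[bool, bool, bool]] = {
    "quiescent_musc": (False, False, False),
    "cycling_musc": (False, True, False),
    "cycling_progenitor": (True, True, False),
    "committed": (True, False, False),
    "differentiated": (True, False, True),
}

#: Negative-component (background) mean intensity per marker, arbitrary units.
_MARKER_BACKGROUND_MEAN: dict[str, float] = {
    "int_myog": 100.0,
    "int_ki67": 100.0,
    "int_myhc": 100.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all synthetic generators.

    Identical configurations (including ``seed``) yield byte-identical
    outputs from every generator.
    """

    seed: int = 0

    # --- single-cell RNA counts -------------------------------------------
    n_cells_per_state: Mapping[str, int] = field(
        default_factory=lambda: {
            "musc_like": 200,
            "cycling_progenitor": 200,
            "differentiated": 200,
        }
    )
    n_genes: int = 1000
    n_marker_genes_per_state: int = 25
    marker_log2fc: float = 2.0
    baseline_mean: float = 2.0
    dispersion: float = 1.0
    gene_mean_sigma: float = 0.5
    library_size_sigma: float = 0.75
    n_mito_genes: int = 10
    mito_fraction_range: tuple[float, float] = (0.01, 0.25)

    # --- hashtag oligos ----------------------------------------------------
    n_hashtags: int = 4
    hto_signal_to_noise: float = 20.0
    hto_background_mean: float = 10.0
    hto_dispersion: float = 10.0

    # --- imaging plate -----------------------------------------------------
    plate_layout: Mapping[str, WellSpec] | None = None
    n_cells_per_well: int = 2000
    unstained_well: str | None = "H12"
    intensity_log_separation: float = 3.0
    intensity_sigma: float = 0.35
    composition_sampling: str = "exact"  # or "multinomial"

    # --- patient cohort ----------------------------------------------------
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not self.n_cells_per_state:
            raise ValueError("n_cells_per_state must not be empty")
        for state, n in self.n_cells_per_state.items():
            if n <= 0:
                raise ValueError(f"cell count for state {state!r} must be > 0")
        for name, value in [
            ("n_genes", self.n_genes),
            ("n_marker_genes_per_state", self.n_marker_genes_per_state),
            ("n_mito_genes", self.n_mito_genes),
            ("n_hashtags", self.n_hashtags),
            ("n_cells_per_well", self.n_cells_per_well),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.hto_signal_to_noise <= 0 or self.hto_background_mean <= 0:
            raise ValueError("HTO signal-to-noise and background mean must be > 0")
        if self.hto_dispersion <= 0:
            raise ValueError("hto_dispersion must be > 0")
        if self.composition_sampling not in ("exact", "multinomial"):
            raise ValueError("composition_sampling must be 'exact' or 'multinomial'")
        if self.plate_layout is not None:
            for well, spec in self.plate_layout.items():
                comp = np.asarray(spec.composition, dtype=float)
                if comp.shape != (len(STATES),):
                    raise ValueError(
                        f"well {well!r}: composition must have {len(STATES)} entries"
                    )
                if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"well {well!r}: composition must be non-negative and sum "
                        "to 1 within 1e-9"
                    )
            if self.unstained_well is not None and self.unstained_well in self.plate_layout:
                raise ValueError(
                    f"unstained well {self.unstained_well!r} collides with a "
                    "treated well in plate_layout"
                )


def mito_genes(config: SimConfig) -> list[str]:
    """Names of the designated mitochondrial genes."""
    return [f"MT-{i + 1}" for i in range(config.n_mito_genes)]


def _nonmito_genes(config: SimConfig) -> list[str]:
    n = config.n_genes - config.n_mito_genes
    return [f"GENE{i + 1:05d}" for i in range(n)]


def marker_genes(config: SimConfig) -> dict[str, list[str]]:
    """Planted marker genes per state (deterministic function of the config)."""
    genes = _nonmito_genes(config)
    m = config.n_marker_genes_per_state
    out: dict[str, list[str]] = {}
    for i, state in enumerate(config.n_cells_per_state):
        out[state] = genes[i * m : (i + 1) * m]
    return out


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.Series]:
    """Simulate a genes-by-cells UMI count matrix with planted states.

    Returns the count matrix and the true cell-to-state labels.  Each state's
    marker genes are elevated by ``marker_log2fc`` in that state; designated
    ``MT-*`` genes carry a per-cell mitochondrial UMI fraction drawn uniformly
    from ``mito_fraction_range``.
    """
    needed = config.n_mito_genes + len(config.n_cells_per_state) * (
        config.n_marker_genes_per_state
    )
    if config.n_genes < needed:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {config.n_mito_genes} "
            f"mitochondrial + {needed - config.n_mito_genes} marker genes"
        )
    rng = np.random.default_rng(config.seed)
    states = list(config.n_cells_per_state)
    n_cells = sum(config.n_cells_per_state.values())
    cell_states = np.repeat(states, [config.n_cells_per_state[s] for s in states])
    barcodes = np.array([f"CELL{i + 1:05d}" for i in range(n_cells)], dtype=object)

    nonmito = _nonmito_genes(config)
    markers = marker_genes(config)
    gene_index = {g: i for i, g in enumerate(nonmito)}

    # per-gene baseline means with lognormal spread; per-cell library factors
    gene_means = config.baseline_mean * rng.lognormal(
        0.0, config.gene_mean_sigma, len(nonmito)
    )
    lib = rng.lognormal(0.0, config.library_size_sigma, n_cells)

    fold = np.ones((len(nonmito), n_cells))
    for state in states:
        cols = cell_states == state
        rows = [gene_index[g] for g in markers[state]]
        fold[np.ix_(rows, cols)] = 2.0 ** config.marker_log2fc

    mu = gene_means[:, None] * lib[None, :] * fold
    r = config.dispersion
    nonmito_counts = rng.negative_binomial(r, r / (r + mu))

    # mitochondrial block: fixed per-cell fraction of total UMIs
    frac = rng.uniform(*config.mito_fraction_range, n_cells)
    nonmito_totals = nonmito_counts.sum(axis=0)
    mito_totals = np.rint(frac / (1.0 - frac) * nonmito_totals).astype(np.int64)
    pvals = np.full(config.n_mito_genes, 1.0 / config.n_mito_genes)
    mito_counts = rng.multinomial(mito_totals, pvals).T  # n_mito x n_cells

    counts = np.vstack([mito_counts, nonmito_counts])
    features = np.array(mito_genes(config) + nonmito, dtype=object)
    matrix = CountMatrix(
        matrix=sp.csr_matrix(counts), features=features, barcodes=barcodes
    )
    truth = pd.Series(cell_states, index=barcodes, name="state")
    return matrix, truth


def simulate_hto(
    config: SimConfig,
    truth_sample: Mapping[str, str] | pd.Series,
    barcodes: Sequence[str] | None = None,
) -> CountMatrix:
    """Simulate a hashtags-by-cells HTO count matrix.

    ``truth_sample`` maps each cell barcode to its true hashtag (one of
    ``HTO1..HTOn``).  The true hashtag's mean count is
    ``hto_signal_to_noise`` times the background mean.
    """
    if config.n_hashtags < 2:
        raise ValueError("need at least 2 hashtags")
    truth = pd.Series(truth_sample, dtype=object)
    hashtags = [f"HTO{i + 1}" for i in range(config.n_hashtags)]
    unknown_tags = set(truth.unique()) - set(hashtags)
    if unknown_tags:
        raise ValueError(f"unknown hashtags in truth_sample: {sorted(unknown_tags)}")
    if barcodes is not None:
        unknown_cells = set(truth.index) - set(barcodes)
        if unknown_cells:
            raise ValueError(
                f"truth_sample refers to unknown cells: {sorted(unknown_cells)[:5]}"
            )
        truth = truth.reindex(barcodes)
        if truth.isna().any():
            raise ValueError("every barcode needs a true hashtag")

    rng = np.random.default_rng(config.seed + 1)
    n_cells = len(truth)
    mu = np.full((config.n_hashtags, n_cells), config.hto_background_mean)
    tag_idx = np.array([hashtags.index(t) for t in truth])
    mu[tag_idx, np.arange(n_cells)] *= config.hto_signal_to_noise
    r = config.hto_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return CountMatrix(
        matrix=sp.csr_matrix(counts),
        features=np.array(hashtags, dtype=object),
        barcodes=np.array(truth.index, dtype=object),
        modality="hto",
    )


def _exact_state_counts(comp: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of a composition vector to integer counts."""
    raw = comp * n
    base = np.floor(raw).astype(np.int64)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_plate(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a per-cell imaging table for one plate.

    Each treated well draws ``n_cells_per_well`` cells from the well's true
    state composition (exact largest-remainder counts by default, multinomial
    optionally) and gives each cell lognormal marker intensities from the
    negative or positive component dictated by its state.  One designated
    unstained well contains only negative-component intensities.

    Returns the cell table (columns ``plate, well, compound, dose_um,
    cell_id, int_myog, int_ki67, int_myhc``) and the true state per cell_id
    (unstained cells carry no truth label).
    """
    if config.plate_layout is None:
        raise ValueError("config.plate_layout is required for simulate_plate")
    rng = np.random.default_rng(config.seed + 2)
    sigma = config.intensity_sigma
    sep = config.intensity_log_separation

    rows: list[pd.DataFrame] = []
    truth_parts: list[pd.Series] = []

    def intensities(positive: np.ndarray, marker: str) -> np.ndarray:
        mu_log = math.log(_MARKER_BACKGROUND_MEAN[marker]) + sep * positive
        return rng.lognormal(mu_log, sigma)

    wells = list(config.plate_layout.items())
    if config.unstained_well is not None:
        unstained_comp = tuple(
            1.0 if s == "quiescent_musc" else 0.0 for s in STATES
        )
        wells.append(
            (config.unstained_well, WellSpec("UNSTAINED", 0.0, unstained_comp))
        )

    for well, spec in wells:
        n = config.n_cells_per_well
        comp = np.asarray(spec.composition, dtype=float)
        unstained = spec.compound == "UNSTAINED"
        if config.composition_sampling == "exact":
            counts = _exact_state_counts(comp, n)
            states = np.repeat(STATES, counts)
        else:
            states = np.array(STATES, dtype=object)[
                rng.choice(len(STATES), size=n, p=comp)
            ]
        cell_ids = np.array(
            [f"{well}_{i + 1:05d}" for i in range(n)], dtype=object
        )
        pos = np.array(
            [_STATE_POSITIVITY[s] for s in states], dtype=float
        )  # n x 3 in MARKERS order
        if unstained:
            pos[:] = 0.0
        frame = pd.DataFrame(
            {
                "plate": "plate1",
                "well": well,
                "compound": spec.compound,
                "dose_um": spec.dose_um,
                "cell_id": cell_ids,
            }
        )
        for j, marker in enumerate(MARKERS):
            frame[marker] = intensities(pos[:, j], marker)
        rows.append(frame)
        if not unstained:
            truth_parts.append(pd.Series(states, index=cell_ids))

    cells = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_parts) if truth_parts else pd.Series(dtype=object)
    truth.name = "state"
    return cells, truth


def screen_layout(
    compounds: Mapping[str, tuple[float, ...]],
    control_compound: str = "DMSO",
    control_composition: tuple[float, ...] = (0.2, 0.1, 0.4, 0.2, 0.1),
    dose_um: float = 1.0,
) -> dict[str, WellSpec]:
    """Build a one-dose screen layout: one well per compound plus a control.

    ``compounds`` maps compound name to its true composition; the untreated
    control occupies the first well.
    """
    layout: dict[str, WellSpec] = {}
    names = [control_compound] + list(compounds)
    comps = [control_composition] + [compounds[c] for c in compounds]
    for i, (name, comp) in enumerate(zip(names, comps)):
        row, col = divmod(i, 24)
        well = f"{chr(ord('A') + row)}{col + 1:02d}"
        layout[well] = WellSpec(name, 0.0 if name == control_compound else dose_um, comp)
    return layout


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Simulate a patients-by-genes log2-expression cohort with vital status.

    Without a planted signature the expression is independent of status (the
    null case).  With one, the signature's up-genes are shifted by
    ``+effect_log2fc`` and its down-genes by ``-effect_log2fc`` in deceased
    patients.
    """
    cc = config.cohort
    if cc.n_live < 2 or cc.n_dead < 2:
        raise ValueError("need at least 2 live and 2 dead patients")
    rng = np.random.default_rng(config.seed + 3)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    patients = [f"LIVE{i + 1:03d}" for i in range(cc.n_live)] + [
        f"DEAD{i + 1:03d}" for i in range(cc.n_dead)
    ]
    status = pd.Series(
        ["live"] * cc.n_live + ["dead"] * cc.n_dead, index=patients
    )
    baseline = rng.uniform(4.0, 8.0, config.n_genes)
    expr = baseline[None, :] + rng.normal(
        0.0, cc.noise_sd, (len(patients), config.n_genes)
    )
    expr = pd.DataFrame(expr, index=patients, columns=genes)
    if cc.planted_signature is not None:
        sig = cc.planted_signature
        missing = set(sig.genes) - set(genes)
        if missing:
            raise ValueError(
                f"planted signature references absent genes: {sorted(missing)[:5]}"
            )
        dead = status == "dead"
        for gene, direction in sig.directions.items():
            expr.loc[dead, gene] += direction * cc.effect_log2fc
    return CohortTable(expression=expr, status=status)
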