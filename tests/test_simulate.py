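"""Synthetic-data generators: planted structure is recovered, configuration
errors are caught, and identical seeds give identical outputs."""

import numpy as np
import pandas as pd
import pytest

import myostate as ms
from myostate.simulate import _exact_state_counts


class TestSimulateCounts:
    def test_dimensions_and_truth_counts(self, base_config, counts_and_truth):
        counts, truth = counts_and_truth
        assert counts.shape == (base_config.n_genes, 600)
        assert truth.value_counts().to_dict() == dict(base_config.n_cells_per_state)

    def test_marker_log2fc_recovered(self, base_config, counts_and_truth):
        """Empirical in-state vs rest log2 fold change of planted markers
        matches the configured effect within sampling error."""
        counts, truth = counts_and_truth
        frame = counts.to_frame()
        for state, genes in ms.marker_genes(base_config).items():
            in_cells = truth.index[truth == state]
            rest = truth.index[truth != state]
            lfc = np.log2(
                frame.loc[genes, in_cells].mean(axis=1)
                / frame.loc[genes, rest].mean(axis=1)
            )
            assert abs(lfc.mean() - base_config.marker_log2fc) < 0.3

    def test_mito_fraction_in_configured_range(self, base_config, counts_and_truth):
        counts, _ = counts_and_truth
        metrics = ms.qc_metrics(counts)
        lo, hi = base_config.mito_fraction_range
        # rounding of the mitochondrial UMI total moves the realised
        # fraction by at most one UMI
        assert metrics["mito_pct"].between(100 * lo - 1, 100 * hi + 1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_cells_per_state": {"a": 0, "b": 10}},
            {"baseline_mean": -1.0},
            {"mito_fraction_range": (0.5, 0.2)},
            {"mito_fraction_range": (-0.1, 0.2)},
            {"composition_sampling": "poisson"},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ms.SimConfig(seed=0, **kwargs)

    def test_too_few_genes_for_markers_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ms.simulate_counts(ms.SimConfig(seed=0, n_genes=50))


class TestSimulateHto:
    def test_matrix_shape(self):
        cfg = ms.SimConfig(seed=0, n_hashtags=2)
        truth = pd.Series(["HTO1"] * 5 + ["HTO2"] * 5,
                          index=[f"c{i}" for i in range(10)])
        hto = ms.simulate_hto(cfg, truth)
        assert hto.shape == (2, 10)
        assert hto.modality == "hto"

    def test_signal_dominates_background(self, base_config, hto_truth):
        hto = ms.simulate_hto(base_config, hto_truth)
        frame = hto.to_frame()
        true_signal = np.array(
            [frame.loc[tag, cell] for cell, tag in hto_truth.items()]
        )
        background = frame.to_numpy().sum(axis=0) - true_signal
        snr = true_signal.mean() / (background.mean() / (len(frame) - 1))
        assert snr == pytest.approx(base_config.hto_signal_to_noise, rel=0.2)

    def test_unknown_hashtag_rejected(self, base_config):
        with pytest.raises(ValueError, match="unknown hashtag"):
            ms.simulate_hto(base_config, pd.Series({"c0": "HTO99"}))

    def test_unknown_cell_rejected(self, base_config):
        truth = pd.Series({"c0": "HTO1", "zz": "HTO2"})
        with pytest.raises(ValueError, match="unknown cells"):
            ms.simulate_hto(base_config, truth, barcodes=["c0", "c1"])


class TestSimulatePlate:
    def test_row_count_and_columns(self):
        layout = {
            "A01": ms.WellSpec("DMSO", 0.0, (0.2, 0.2, 0.3, 0.2, 0.1)),
            "A02": ms.WellSpec("drug", 1.0, (0.2, 0.2, 0.3, 0.2, 0.1)),
        }
        cfg = ms.SimConfig(seed=0, plate_layout=layout, n_cells_per_well=100,
                           unstained_well=None)
        cells, truth = ms.simulate_plate(cfg)
        assert len(cells) == 200
        assert len(truth) == 200
        for col in ("plate", "well", "compound", "dose_um", "cell_id", *ms.MARKERS):
            assert col in cells.columns

    def test_pure_composition_draws_single_state(self):
        comp = tuple(1.0 if s == ms.DIFFERENTIATED else 0.0 for s in ms.STATES)
        layout = {"A01": ms.WellSpec("drug", 1.0, comp)}
        cfg = ms.SimConfig(seed=0, plate_layout=layout, n_cells_per_well=50,
                           unstained_well=None)
        _, truth = ms.simulate_plate(cfg)
        assert set(truth) == {ms.DIFFERENTIATED}

    def test_unstained_well_is_background_only(self, plate_sim):
        """Unstained intensities stay in the negative component for all
        three markers (positive component sits e^3 higher)."""
        cfg, cells, _ = plate_sim
        unstained = cells[cells["well"] == cfg.unstained_well]
        assert len(unstained) == cfg.n_cells_per_well
        stained = cells[cells["well"] != cfg.unstained_well]
        for marker in ms.MARKERS:
            assert unstained[marker].max() < stained[marker].max()

    def test_exact_state_counts_largest_remainder(self):
        counts = _exact_state_counts(np.array([0.2, 0.2, 0.3, 0.2, 0.1]), 10)
        assert counts.tolist() == [2, 2, 3, 2, 1]
        counts = _exact_state_counts(np.array([1 / 3, 1 / 3, 1 / 3, 0.0, 0.0]), 100)
        assert counts.tolist() == [34, 33, 33, 0, 0]

    def test_bad_composition_rejected(self):
        layout = {"A01": ms.WellSpec("drug", 1.0, (0.5, 0.5, 0.5, 0.0, 0.0))}
        with pytest.raises(ValueError, match="sum"):
            ms.SimConfig(seed=0, plate_layout=layout)

    def test_layout_required(self):
        with pytest.raises(ValueError, match="plate_layout"):
            ms.simulate_plate(ms.SimConfig(seed=0))

    def test_unstained_collision_rejected(self):
        layout = {"H12": ms.WellSpec("drug", 1.0, (0.2, 0.2, 0.3, 0.2, 0.1))}
        with pytest.raises(ValueError, match="collides"):
            ms.SimConfig(seed=0, plate_layout=layout, unstained_well="H12")


class TestSimulateCohort:
    def test_null_cohort_shape_and_status(self):
        cfg = ms.SimConfig(seed=0, n_genes=50,
                           cohort=ms.CohortConfig(n_live=5, n_dead=7))
        cohort = ms.simulate_cohort(cfg)
        assert cohort.expression.shape == (12, 50)
        assert cohort.status_counts() == {"live": 5, "dead": 7}

    def test_planted_effect_matches_statistic(self):
        """With a planted +/-1 log2 shift the signed statistic estimates the
        shift itself."""
        sig = ms.SignedSignature.from_genes(
            "planted",
            up=[f"G{i + 1:04d}" for i in range(15)],
            down=[f"G{i + 16:04d}" for i in range(15)],
        )
        cfg = ms.SimConfig(
            seed=5, n_genes=100,
            cohort=ms.CohortConfig(n_live=30, n_dead=30,
                                   planted_signature=sig, effect_log2fc=1.0),
        )
        cohort = ms.simulate_cohort(cfg)
        t = ms.signature_statistic(cohort, sig)
        assert t == pytest.approx(1.0, abs=0.2)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ms.simulate_cohort(
                ms.SimConfig(seed=0, cohort=ms.CohortConfig(n_live=0, n_dead=5))
            )

    def test_absent_signature_genes_rejected(self):
        sig = ms.SignedSignature.from_genes("bad", up=["NOPE"])
        cfg = ms.SimConfig(seed=0, n_genes=10,
                           cohort=ms.CohortConfig(planted_signature=sig))
        with pytest.raises(ValueError, match="absent genes"):
            ms.simulate_cohort(cfg)


class TestDeterminism:
    def test_counts_identical_across_calls(self, base_config):
        a, ta = ms.simulate_counts(base_config)
        b, tb = ms.simulate_counts(base_config)
        assert a.equals(b)
        pd.testing.assert_series_equal(ta, tb)

    def test_different_seeds_differ(self, base_config, counts_and_truth):
        other, _ = ms.simulate_counts(ms.SimConfig(seed=base_config.seed + 1))
        assert not counts_and_truth[0].equals(other)
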