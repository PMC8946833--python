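"""Synthetic field and Cq-table generator: geometry, calibration, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from gammahq import (
    SimExperimentParams,
    SimFieldParams,
    SimQpcrParams,
    generate_experiment,
    generate_field,
    generate_qpcr_table,
)


class TestGenerateField:
    def test_empty_field_is_pure_background(self, field_params):
        params = field_params(n_cells=0, noise_sd=0.0, background_gradient_amplitude=0.0)
        pair, truth = generate_field(params)
        assert len(truth.cells) == 0
        assert truth.true_positive_fraction == 0.0
        assert np.all(pair.dapi == params.background_level)
        assert np.all(pair.signal == params.background_level)

    def test_dapi_component_count_matches_requested_cells(self, field_params):
        # flood-fill oracle: connected components of above-background DAPI
        params = field_params(
            n_cells=5,
            noise_sd=0.0,
            background_gradient_amplitude=0.0,
            min_center_separation=4 * 8.0,
            rng_seed=3,
        )
        pair, truth = generate_field(params)
        _, n_components = ndi.label(pair.dapi > params.background_level)
        assert n_components == 5
        assert len(truth.cells) == 5

    @pytest.mark.parametrize("fraction,expected", [(1.0, True), (0.0, False)])
    def test_degenerate_positive_fraction(self, field_params, fraction, expected):
        _, truth = generate_field(field_params(positive_fraction=fraction))
        assert all(c.is_positive is expected for c in truth.cells)
        assert truth.true_positive_fraction == float(fraction)

    def test_truth_fraction_is_mean_of_labels(self, field_params):
        _, truth = generate_field(field_params(positive_fraction=0.4, rng_seed=11))
        assert truth.true_positive_fraction == pytest.approx(
            np.mean([c.is_positive for c in truth.cells])
        )

    def test_same_seed_bit_identical(self, field_params):
        params = field_params(rng_seed=42)
        a, _ = generate_field(params)
        b, _ = generate_field(params)
        assert a.dapi.tobytes() == b.dapi.tobytes()
        assert a.signal.tobytes() == b.signal.tobytes()

    def test_placement_failure_names_achievable_count(self):
        params = SimFieldParams(
            image_height=64, image_width=64, n_cells=100, min_center_separation=30.0
        )
        with pytest.raises(ValueError, match=r"only \d+ fit"):
            generate_field(params)

    def test_invalid_bit_depth_rejected(self):
        with pytest.raises(ValueError, match="bit_depth"):
            SimFieldParams(bit_depth=12)

    def test_separation_guarantee_no_disk_overlap(self, field_params):
        # min separation > 2*(radius_mean + 3 sd) implies disjoint disks
        params = field_params(
            min_center_separation=2 * (8.0 + 3 * 1.0) + 1, n_cells=30, rng_seed=5
        )
        _, truth = generate_field(params)
        cells = truth.cells
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = np.hypot(
                    cells[i].center[0] - cells[j].center[0],
                    cells[i].center[1] - cells[j].center[1],
                )
                assert d > cells[i].radius + cells[j].radius

    def test_intensities_respect_bit_range(self, field_params):
        params = field_params(bit_depth=8, pos_signal_mean=250.0, pos_signal_sd=30.0)
        pair, _ = generate_field(params)
        assert pair.signal.dtype == np.uint8
        assert pair.signal.max() <= 255


class TestGenerateExperiment:
    def test_configured_fraction_arithmetic(self):
        params = SimExperimentParams(baseline_positive_fraction=0.10)
        assert params.condition_fraction("control", "UV") == pytest.approx(0.24)

    def test_untreated_factor_must_be_one(self):
        with pytest.raises(ValueError, match="untreated"):
            SimExperimentParams(arm_effects={("control", "untreated"): 2.0})

    def test_out_of_range_fraction_warns_and_clamps(self):
        params = SimExperimentParams(
            baseline_positive_fraction=0.5,
            arm_effects={("control", "untreated"): 1.0, ("control", "UV"): 4.0},
        )
        with pytest.warns(UserWarning, match="clamped"):
            assert params.condition_fraction("control", "UV") == 1.0

    def test_manifest_covers_layout(self, field_params):
        params = SimExperimentParams(
            n_fields_per_condition=2, field_params=field_params(n_cells=4), rng_seed=1
        )
        images, truths, manifest = generate_experiment(params)
        assert len(images) == len(truths) == 2 * 6
        assert set(manifest["arm"]) == {"control", "osmotic"}
        assert manifest["image_id"].is_unique
        for img, (_, row) in zip(images, manifest.iterrows()):
            assert img.image_id == row["image_id"]
            assert (img.arm, img.treatment) == (row["arm"], row["treatment"])

    def test_pooled_fraction_within_binomial_error(self, field_params):
        # all effects 1: realized positives pool to the baseline fraction
        p = 0.2
        params = SimExperimentParams(
            baseline_positive_fraction=p,
            arm_effects={("control", "untreated"): 1.0, ("osmotic", "untreated"): 1.0},
            n_fields_per_condition=12,
            field_params=field_params(n_cells=60),
            rng_seed=9,
        )
        _, truths, _ = generate_experiment(params)
        flags = [c.is_positive for t in truths for c in t.cells]
        n = len(flags)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(flags) - p) < 3 * se

    def test_same_seed_identical_outputs(self, field_params, tmp_path):
        params = SimExperimentParams(
            n_fields_per_condition=1, field_params=field_params(n_cells=5), rng_seed=3
        )
        _, _, m1 = generate_experiment(params, outdir=tmp_path / "a")
        _, _, m2 = generate_experiment(params, outdir=tmp_path / "b")
        assert m1.drop(columns=["dapi_path", "signal_path"]).equals(
            m2.drop(columns=["dapi_path", "signal_path"])
        )
        for p1, p2 in zip(sorted((tmp_path / "a").glob("*.tif")),
                          sorted((tmp_path / "b").glob("*.tif"))):
            assert p1.read_bytes() == p2.read_bytes()


class TestGenerateQpcrTable:
    def test_table_structure(self):
        params = SimQpcrParams(n_replicates=3, n_technical=2, rng_seed=0)
        table = generate_qpcr_table(params)
        # 2 conditions x 3 samples x 5 genes x 2 technical replicates
        assert len(table) == 2 * 3 * 5 * 2
        counts = table.groupby(["sample_id", "gene"]).size()
        assert (counts == 2).all()

    def test_noise_free_treated_shift_equals_log2_fc(self):
        params = SimQpcrParams(cq_noise_sd=0.0, rng_seed=0)
        table = generate_qpcr_table(params)
        for gene, true_fc in params.true_log2_fc.items():
            ctrl = table.query("gene == @gene and condition == 'control'")["cq"].mean()
            trt = table.query("gene == @gene and condition == 'treated'")["cq"].mean()
            assert trt - ctrl == pytest.approx(-true_fc, abs=1e-12)

    def test_reference_gene_condition_independent(self):
        params = SimQpcrParams(cq_noise_sd=0.0, rng_seed=0)
        table = generate_qpcr_table(params)
        ref = table[table["gene"] == params.reference_gene]
        assert ref["cq"].nunique() == 1

    def test_reference_gene_with_nonzero_fc_rejected(self):
        with pytest.raises(ValueError, match="reference gene"):
            SimQpcrParams(true_log2_fc={"18S": 1.0, **SimQpcrParams().true_log2_fc})

    def test_determinism(self):
        params = SimQpcrParams(rng_seed=5)
        assert generate_qpcr_table(params).equals(generate_qpcr_table(params))
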