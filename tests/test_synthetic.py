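import filecmp

import numpy as np
import pytest

from plsde.errors import ParameterError
from plsde.network import filter_by_support
from plsde.survival import km_curve
from plsde.synthetic import (SimulationConfig, generate_bundle,
                             generate_expression,
                             generate_predictions_and_annotations,
                             generate_survival, write_bundle)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_spiked": 10, "n_features": 5},
        {"effect_size": -1.0},
        {"noise_sd": 0.0},
        {"hazard_ratio": 0.0},
        {"share_fraction": 1.5},
        {"planted_term_size": 400, "n_gene_features": 300},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimulationConfig(**kwargs)


class TestGenerateExpression:
    def test_no_spikes_means_empty_truth(self):
        cfg = SimulationConfig(n_features=4, n_spiked=0, seed=7)
        _, truth = generate_expression(cfg)
        assert truth.empty

    def test_zero_effect_size_gives_no_shift(self):
        cfg = SimulationConfig(n_features=50, n_spiked=2, effect_size=0.0, seed=3)
        matrix, truth = generate_expression(cfg)
        is_b = (matrix.class_labels == "gradeIV").to_numpy()
        for f in truth["feature_id"]:
            row = matrix.values.loc[f].to_numpy()
            diff = row[is_b].mean() - row[~is_b].mean()
            se = cfg.noise_sd * np.sqrt(1 / cfg.n_class_a + 1 / cfg.n_class_b)
            assert abs(diff) < 4 * se

    def test_spiked_shifts_within_monte_carlo_error(self):
        cfg = SimulationConfig(n_features=500, n_spiked=20, effect_size=1.5,
                               n_class_a=24, n_class_b=50, seed=1)
        matrix, truth = generate_expression(cfg)
        is_b = (matrix.class_labels == "gradeIV").to_numpy()
        se = np.sqrt(1 / 24 + 1 / 50)
        for f, eff in zip(truth["feature_id"], truth["effect"]):
            row = matrix.values.loc[f].to_numpy()
            observed = (row[is_b].mean() - row[~is_b].mean()) / cfg.noise_sd
            assert observed == pytest.approx(eff / cfg.noise_sd, abs=3 * se)

    def test_alternating_spike_signs(self):
        cfg = SimulationConfig(n_features=30, n_spiked=4, seed=5)
        _, truth = generate_expression(cfg)
        signs = np.sign(truth["effect"].to_numpy())
        np.testing.assert_array_equal(signs, [1, -1, 1, -1])

    def test_truth_consistency(self):
        cfg = SimulationConfig(n_features=40, n_spiked=7, seed=2)
        matrix, truth = generate_expression(cfg)
        assert len(truth) == 7
        assert set(truth["feature_id"]) <= set(matrix.feature_ids)


class TestGenerateSurvival:
    def test_no_censoring_means_all_events(self):
        cfg = SimulationConfig(n_features=20, n_spiked=2, censor_rate=0.0, seed=4)
        matrix, truth = generate_expression(cfg)
        pheno = generate_survival(matrix, truth, cfg)
        assert (pheno["event"] == 1).all()
        assert (pheno["time"] > 0).all()

    def test_phenotype_matches_expression_samples(self):
        cfg = SimulationConfig(n_features=20, n_spiked=2, seed=4)
        matrix, truth = generate_expression(cfg)
        pheno = generate_survival(matrix, truth, cfg)
        assert list(pheno["sample"]) == matrix.sample_ids

    def test_empty_truth_with_hazard_ratio_errors(self):
        cfg = SimulationConfig(n_features=20, n_spiked=0, hazard_ratio=4.0, seed=4)
        matrix, truth = generate_expression(cfg)
        with pytest.raises(ParameterError):
            generate_survival(matrix, truth, cfg)

    def test_high_stratum_dies_sooner(self):
        cfg = SimulationConfig(n_features=20, n_spiked=2, hazard_ratio=4.0,
                               baseline_hazard=0.05, censor_rate=0.0, seed=2)
        matrix, truth = generate_expression(cfg)
        pheno = generate_survival(matrix, truth, cfg)
        x = matrix.values.loc[truth["feature_id"].iloc[0]].to_numpy()
        high = x > np.median(x)
        t = pheno["time"].to_numpy()
        e = pheno["event"].to_numpy()

        def km_median(mask):
            c = km_curve(t[mask], e[mask])
            return c.event_times[np.searchsorted(-c.survival, -0.5)]

        assert km_median(high) < km_median(~high)


class TestPredictionsAndAnnotations:
    def test_share_zero_yields_no_supported_pairs(self):
        cfg = SimulationConfig(share_fraction=0.0, seed=9)
        preds, _, _ = generate_predictions_and_annotations(["m1", "m2"], cfg)
        assert filter_by_support(preds, 2).empty

    def test_share_one_supports_every_pair(self):
        cfg = SimulationConfig(share_fraction=1.0, seed=9)
        preds, _, _ = generate_predictions_and_annotations(["m1", "m2"], cfg)
        pairs = set(zip(preds["mirna"], preds["gene"]))
        supported = filter_by_support(preds, 2)
        assert set(zip(supported["mirna"], supported["gene"])) == pairs

    def test_every_predicted_gene_in_universe(self):
        cfg = SimulationConfig(seed=9)
        preds, coll, _ = generate_predictions_and_annotations(["m1", "m2", "m3"], cfg)
        assert set(preds["gene"]) <= set(coll.universe)

    def test_universe_smaller_than_term_rejected(self):
        cfg = SimulationConfig(seed=9)
        with pytest.raises(ParameterError):
            generate_predictions_and_annotations(["m1"], cfg,
                                                 universe=[f"g{i}" for i in range(5)])


class TestBundle:
    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_features=60, n_spiked=4, n_class_a=8,
                               n_class_b=10, n_gene_features=80, seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_bundle(generate_bundle(cfg), d1)
        p2 = write_bundle(generate_bundle(cfg), d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_bundle_invariants(self, small_bundle):
        b = small_bundle
        assert set(b.truth["feature_id"]) <= set(b.expression.feature_ids)
        assert list(b.phenotype["sample"]) == b.expression.sample_ids
        assert set(b.predictions["gene"]) <= set(b.annotations.universe)
        assert set(b.gene_truth["feature_id"]) <= set(b.gene_expression.feature_ids)
        # spiked genes are supported targets of spiked miRNAs
        supported = filter_by_support(b.predictions, 2)
        assert set(b.gene_truth["feature_id"]) <= set(supported["gene"])
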