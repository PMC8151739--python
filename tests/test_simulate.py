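"""Synthetic-data generators: determinism, calibration bands, comfort
response, expert panels, contour nodes and stiffness calibrations."""

import numpy as np
import pytest

from pillowfit import (
    GeneratorConfig,
    fit_power_law,
    generate_calibration,
    generate_contour_nodes,
    generate_expert_panel,
    generate_pressure_matrix,
    generate_trial_cohort,
    template_matrix,
)
from pillowfit import reference
from pillowfit.core import average_pressure, mean_gradient, peak_pressure
from pillowfit.fahp import aggregate_experts, fahp_weights, to_complementary


class TestPressureMatrices:
    def test_zero_noise_is_exact_template_for_any_seed(self):
        cfg = GeneratorConfig(noise_sd_kpa=0.0)
        t = template_matrix("supine", cfg)
        for seed in (0, 1, 99):
            m = generate_pressure_matrix("supine", cfg, seed=seed)
            assert np.array_equal(m.values, t.values)

    def test_same_seed_bit_identical(self, gen_config):
        a = generate_pressure_matrix("lateral", gen_config, seed=5)
        b = generate_pressure_matrix("lateral", gen_config, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self, gen_config):
        a = generate_pressure_matrix("lateral", gen_config, seed=5)
        b = generate_pressure_matrix("lateral", gen_config, seed=6)
        assert not np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("posture,pm_band", [("supine", (7.5, 9.2)), ("lateral", (7.3, 8.7))])
    def test_template_peak_in_calibration_band(self, posture, pm_band):
        t = template_matrix(posture)
        assert pm_band[0] <= peak_pressure(t) <= pm_band[1]

    def test_template_index_magnitudes(self):
        # order-of-magnitude calibration bands around the published
        # top-comfort recordings
        for posture in ("supine", "lateral"):
            t = template_matrix(posture)
            assert 0.8 <= average_pressure(t) <= 3.0
            assert 0.2 <= mean_gradient(t, mode="pointwise") <= 0.4


class TestCohorts:
    def test_same_seed_identical_cohort(self, gen_config):
        a = generate_trial_cohort(gen_config, "supine", seed=3)
        b = generate_trial_cohort(gen_config, "supine", seed=3)
        assert len(a) == len(b) == 42
        assert all(np.array_equal(x.matrix.values, y.matrix.values) for x, y in zip(a, b))
        assert all(x.comfort == y.comfort for x, y in zip(a, b))

    def test_default_design_is_seven_by_six(self, gen_config):
        trials = generate_trial_cohort(gen_config, "lateral", seed=0)
        assert len(trials) == 42
        assert len({t.pillow_id for t in trials}) == 7
        assert len({t.subject_id for t in trials}) == 6
        assert all(t.emg_valid for t in trials)

    def test_truncation_to_n_trials(self, gen_config):
        assert len(generate_trial_cohort(gen_config, "supine", seed=0, n_trials=40)) == 40

    def test_unperturbed_pillow_scores_highest_on_average(self, gen_config):
        trials = generate_trial_cohort(gen_config, "supine", seed=11)
        by_pillow = {}
        for t in trials:
            by_pillow.setdefault(t.pillow_id, []).append(t.comfort.total)
        means = {p: np.mean(v) for p, v in by_pillow.items()}
        assert means["P1"] == max(means.values())
        assert means["P1"] > means["P7"]


class TestExpertPanels:
    def test_zero_noise_recovers_reference_ranking(self):
        panel = generate_expert_panel(1, noise_sd=0.0, seed=0)
        w = fahp_weights(to_complementary(panel[0]))
        order = sorted(w.weights, key=w.weights.get, reverse=True)
        assert order == ["B3", "B2", "B1", "A1", "B4", "A2", "A3"]

    def test_equal_sensitivities_give_uniform_weights(self):
        panel = generate_expert_panel(3, {"a": 1.0, "b": 1.0, "c": 1.0}, noise_sd=0.0, seed=0)
        for jm in panel:
            w = fahp_weights(to_complementary(jm))
            assert w.as_array() == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_group_weights_recovered_exactly_without_noise_or_rounding(self):
        sens = {p: reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.LATERAL_PARTITIONS}
        total = sum(sens.values())
        panel = generate_expert_panel(1, sens, noise_sd=0.0, seed=0, discretize=False)
        w = fahp_weights(to_complementary(panel[0]))
        for p in sens:
            assert w[p] == pytest.approx(sens[p] / total, abs=1e-9)

    def test_noisy_panel_weight_recovery(self):
        """Monte-Carlo: 10 noisy experts recover the generating weights with
        small mean absolute error (per posture group)."""
        sens = {p: reference.PARTITION_SENSITIVITY_WEIGHTS[p] for p in reference.LATERAL_PARTITIONS}
        total = sum(sens.values())
        errs = []
        for rep in range(25):
            panel = generate_expert_panel(10, sens, noise_sd=0.5, seed=rep)
            w = aggregate_experts([fahp_weights(to_complementary(jm)) for jm in panel])
            errs.append(np.mean([abs(w[p] - sens[p] / total) for p in sens]))
        assert np.mean(errs) < 0.02

    def test_determinism(self):
        a = generate_expert_panel(3, noise_sd=0.5, seed=4)
        b = generate_expert_panel(3, noise_sd=0.5, seed=4)
        assert all(np.array_equal(x.entries, y.entries) for x, y in zip(a, b))


class TestNodesAndCalibration:
    def test_larger_group_sinks_deeper_at_every_node(self):
        ms = generate_contour_nodes("MS", seed=1)
        ml = generate_contour_nodes("ML", seed=1)
        for part in ms.nodes:
            assert ml.depth(part) >= ms.depth(part)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            generate_contour_nodes("XL")

    def test_depths_within_foam(self):
        for group in reference.SUBJECT_GROUPS:
            nodes = generate_contour_nodes(group, seed=2)
            assert all(0 < nodes.depth(p) < reference.FOAM_HEIGHT_MM for p in nodes.nodes)

    def test_noiseless_calibration_round_trips_exactly(self):
        cal = generate_calibration(a=3.0, b=-0.8, noise_sd=0.0)
        assert cal.a == pytest.approx(3.0, abs=1e-9)
        assert cal.b == pytest.approx(-0.8, abs=1e-9)

    def test_noisy_calibration_is_still_valid_and_monotone(self):
        cal = generate_calibration(noise_sd=0.08, seed=3)
        ks = [k for _, k in cal.pairs]
        assert all(k2 < k1 for k1, k2 in zip(ks, ks[1:]))

    def test_reference_pairs_load_as_valid_calibration(self):
        from pillowfit import ElasticCalibration

        cal = ElasticCalibration.from_reference()
        assert [p[0] for p in cal.pairs] == [6.0, 9.0, 12.0, 15.0, 18.0, 21.0]
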