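"""Head geometry, forward model, and cohort simulation."""

import numpy as np
import pytest

from meg_seqmem.megsim import (CONDITIONS, CohortConfig, Effect, GroundTruth,
                               cohort_geometry, compute_lead_field,
                               default_ground_truth, iter_subjects,
                               make_sensor_array, make_source_grid, sarvas_field,
                               simulate_subject, _pink_noise)


class TestSensorArray:
    def test_full_array_has_306_channels(self):
        sens = make_sensor_array(102)
        assert sens.n_channels == 306
        assert len(sens.grad_indices) == 204
        assert len(sens.mag_indices) == 102

    def test_positions_on_shell(self):
        sens = make_sensor_array(32, head_radius=0.08, sensor_shell_radius=0.1)
        assert np.allclose(np.linalg.norm(sens.positions, axis=1), 0.1)

    def test_layout_is_injective(self):
        sens = make_sensor_array(102)
        cells = sens.layout[:, 0] * sens.layout_shape[1] + sens.layout[:, 1]
        assert len(np.unique(cells)) == sens.n_positions

    def test_gradiometer_pair_orientations_orthogonal(self):
        sens = make_sensor_array(16)
        assert np.allclose((sens.tangent1 * sens.tangent2).sum(axis=1), 0, atol=1e-12)
        assert np.allclose((sens.tangent1 * sens.radial).sum(axis=1), 0, atol=1e-12)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            make_sensor_array(3)

    def test_deterministic(self):
        a, b = make_sensor_array(24), make_sensor_array(24)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.layout, b.layout)


class TestSourceGrid:
    def test_count_matches_bruteforce_lattice(self):
        spacing, radius = 8.0, 40.0
        grid = make_source_grid(spacing, radius, roi_spec=[("all", (0, 0, 0), 99.0)])
        count = 0
        n = int(radius // spacing)
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                for k in range(-n, n + 1):
                    if (i * i + j * j + k * k) * spacing**2 < radius**2:
                        count += 1
        assert grid.n_dipoles == count

    def test_huge_spacing_keeps_origin(self):
        grid = make_source_grid(200.0, 76.0, roi_spec=[("all", (0, 0, 0), 99.0)])
        assert grid.n_dipoles == 1
        assert np.allclose(grid.positions, 0)

    def test_single_covering_patch_labels_everything(self):
        grid = make_source_grid(24.0, 76.0, roi_spec=[("everything", (0, 0, 0), 100.0)])
        assert set(grid.labels) == {"everything"}

    def test_overlapping_patches_first_wins_with_warning(self):
        spec = [("a", (0.0, 0.0, 0.0), 30.0), ("b", (10.0, 0.0, 0.0), 30.0)]
        with pytest.warns(UserWarning, match="overlaps"):
            grid = make_source_grid(12.0, 76.0, roi_spec=spec)
        assert "a" in grid.labels and "b" in grid.labels

    def test_atlas_partitions_whole_grid(self):
        grid = make_source_grid(12.0, 76.0)
        assert grid.atlas is not None
        assert "none" not in set(grid.atlas)
        # atlas agrees with compact patches at the patch centers
        for lab in np.unique(grid.labels):
            if lab == "none":
                continue
            idx = grid.roi_indices(lab)
            assert (grid.atlas[idx] == lab).mean() > 0.5


class TestForwardModel:
    def test_radial_dipole_is_silent(self, tiny_geometry):
        sens, grid, _ = tiny_geometry
        pos = np.array([[0.0, 0.0, 0.05]])
        tangential = sarvas_field(sens.positions, pos, np.array([[1e-8, 0, 0]]))
        radial = sarvas_field(sens.positions, pos, np.array([[0, 0, 1e-8]]))
        assert np.abs(radial).max() < 1e-6 * np.abs(tangential).max()

    def test_linearity_superposition(self, tiny_geometry):
        sens, grid, lead = tiny_geometry
        a = lead.column(3, [1.0, 0.0])
        b = lead.column(3, [0.0, 1.0])
        combo = lead.column(3, [2.0, -0.5])
        assert np.allclose(combo, 2 * a - 0.5 * b, rtol=1e-12)

    def test_doubling_moment_doubles_reading(self, tiny_geometry):
        _, grid, lead = tiny_geometry
        amps = np.ones((1, 10))
        once = lead.project(np.array([2]), np.array([[0.6, 0.8]]), amps)
        twice = lead.project(np.array([2]), np.array([[0.6, 0.8]]), 2 * amps)
        assert np.allclose(twice, 2 * once)

    def test_shallow_dipole_stronger_than_deep(self):
        sens = make_sensor_array(32)
        deep = sarvas_field(sens.positions, np.array([[0, 0, 0.02]]),
                            np.array([[1e-8, 0, 0]]))
        shallow = sarvas_field(sens.positions, np.array([[0, 0, 0.06]]),
                               np.array([[1e-8, 0, 0]]))
        assert np.abs(deep).max() < np.abs(shallow).max()

    def test_dipole_outside_head_rejected(self):
        sens = make_sensor_array(8, head_radius=0.05, sensor_shell_radius=0.1)
        grid = make_source_grid(24.0, 76.0)
        with pytest.raises(ValueError):
            compute_lead_field(grid, sens)

    def test_gradiometer_is_finite_difference_of_radial_field(self, tiny_geometry):
        sens, grid, lead = tiny_geometry
        d, pos_i, dip = sens.grad_baseline, 0, 5
        orient = np.array([1.0, 0.0])
        moments = lead.dipole_tangents[dip, 0][None, :]
        p_plus = sens.positions[pos_i] + 0.5 * d * sens.tangent1[pos_i]
        p_minus = sens.positions[pos_i] - 0.5 * d * sens.tangent1[pos_i]
        B = sarvas_field(np.stack([p_plus, p_minus]), grid.positions[[dip]], moments)
        expected = (B[0, 0] - B[1, 0]) @ sens.radial[pos_i] / d
        assert lead.column(dip, orient)[0] == pytest.approx(expected, rel=1e-12)


class TestSimulation:
    def test_zero_noise_recovers_pure_projection(self, tiny_cfg, tiny_geometry):
        sens, grid, lead = tiny_geometry
        cfg = CohortConfig(**{**tiny_cfg.__dict__, "noise_sd_grad": 0.0,
                              "noise_sd_mag": 0.0, "pink_sd_grad": 0.0,
                              "pink_sd_mag": 0.0, "inter_subject_amp_sd": 0.0,
                              "trial_amp_jitter_sd": 0.0})
        gt = default_ground_truth()
        rec, _, _ = simulate_subject(gt, cfg, grid, sens, lead, 7, 0)
        from meg_seqmem.megsim import _condition_templates
        tmpl = _condition_templates(gt, grid, lead, cfg.sfreq, 0)
        s0 = rec.event_samples[0]
        cond = rec.event_conditions[0]
        n = tmpl[cond].shape[1]
        assert np.allclose(rec.data[:, s0:s0 + n], tmpl[cond].astype(np.float32),
                           rtol=1e-5)

    def test_same_seed_bit_identical(self, tiny_cfg, tiny_geometry):
        sens, grid, lead = tiny_geometry
        gt = default_ground_truth()
        a, beh_a, fam_a = simulate_subject(gt, tiny_cfg, grid, sens, lead, 9, 0)
        b, beh_b, fam_b = simulate_subject(gt, tiny_cfg, grid, sens, lead, 9, 0)
        assert np.array_equal(a.data, b.data)
        assert beh_a.equals(beh_b) and fam_a == fam_b

    def test_default_event_count_and_baseline_headroom(self, tiny_cfg, tiny_geometry):
        sens, grid, lead = tiny_geometry
        rec, beh, fam = simulate_subject(default_ground_truth(), tiny_cfg,
                                         grid, sens, lead, 1, 0)
        assert len(rec.event_samples) == 160
        assert rec.event_samples[0] >= 0.1 * rec.sfreq
        assert beh["n_trials"].sum() == 160
        assert 1 <= fam <= 7

    def test_cohort_subject_seeds_distinct(self, tiny_cfg, tiny_geometry):
        recs = [rec for rec, _, _ in iter_subjects(tiny_cfg, geometry=tiny_geometry)]
        assert len(recs) == tiny_cfg.n_subjects
        first_samples = {rec.data[0, :50].tobytes() for rec in recs}
        assert len(first_samples) == len(recs)

    def test_accuracy_ordering_matches_configuration(self, tiny_geometry):
        """Memorized-atonal is configured lowest; it should come out lowest in
        nearly all simulated cohorts."""
        wins = 0
        n_cohorts = 10
        for seed in range(n_cohorts):
            cfg = CohortConfig(n_subjects=12, n_sensor_positions=8,
                               grid_spacing_mm=24.0, seed=seed)
            rows = [beh for _, beh, _ in iter_subjects(cfg, geometry=tiny_geometry)]
            import pandas as pd
            df = pd.concat(rows)
            means = df.groupby("condition")["n_correct"].mean()
            wins += means.idxmin() == "memorized_atonal"
        assert wins >= 8

    def test_cohort_mean_accuracy_within_3se(self, tiny_geometry):
        cfg = CohortConfig(n_subjects=40, n_sensor_positions=8,
                           grid_spacing_mm=24.0, seed=77)
        import pandas as pd
        df = pd.concat([b for _, b, _ in iter_subjects(cfg, geometry=tiny_geometry)])
        for cond, mean, sd in zip(CONDITIONS, cfg.accuracy_means, cfg.accuracy_sds):
            got = df.loc[df["condition"] == cond, "n_correct"].mean()
            se = np.sqrt(sd**2 + 40 * (mean / 40) * (1 - mean / 40)) / np.sqrt(40)
            assert abs(got - mean) < 3 * se, cond


class TestConfigValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(noise_sd_grad=-1.0)

    def test_accuracy_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(accuracy_means=(41.0, 30.0, 30.0, 30.0))

    def test_familiarity_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(familiarity_probs=(0.5, 0.5, 0, 0, 0, 0, 0.1))

    def test_effect_validation(self):
        with pytest.raises(ValueError):
            Effect("auditory_L", "gamma", (1,) * 5)
        with pytest.raises(ValueError):
            Effect("auditory_L", "slow", (1, 2, 3))
        with pytest.raises(ValueError):
            GroundTruth(effects={"bogus_condition": ()})


def test_pink_noise_spectrum_and_rms(rng):
    x = _pink_noise(rng, 4, 30_000, 150.0, rms=2.0, corner_hz=0.03)
    assert np.allclose(x.std(axis=1), 2.0, rtol=1e-6)
    freqs = np.fft.rfftfreq(30_000, 1 / 150.0)
    power = np.abs(np.fft.rfft(x, axis=1))**2
    low = power[:, (freqs > 0.1) & (freqs < 1)].mean()
    high = power[:, (freqs > 10) & (freqs < 30)].mean()
    assert low > 10 * high
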