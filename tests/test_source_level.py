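"""Beamformer inverse and two-level group statistics in source space."""

import numpy as np
import pytest
from scipy import linalg, stats

from meg_seqmem.preprocess import EpochSet
from meg_seqmem.source_level import (TONE_WINDOWS, SourceEstimate, band_contrast,
                                     data_covariance, familiarity_correlation,
                                     first_level, group_level, lcmv_weights,
                                     memorized_piece_contrast, reconstruct,
                                     tone_window_mcs, window_means)


class TestDataCovariance:
    def test_white_noise_near_diagonal(self, rng):
        X = rng.normal(size=(20, 50_000))
        C = data_covariance(X, lam_fraction=0.0)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05 * np.diag(C).min()

    def test_rank_deficient_without_regularization_detected(self, rng):
        row = rng.normal(size=(1, 500))
        X = np.repeat(row, 8, axis=0)              # rank 1
        with pytest.raises(linalg.LinAlgError):
            data_covariance(X, lam_fraction=0.0)

    def test_duplicated_epochs_equal_covariance(self, rng):
        ep = rng.normal(size=(4, 6, 100))
        C1 = data_covariance(EpochSet(ep, 150.0, -0.1,
                                      np.array(["memorized_tonal"] * 4),
                                      np.ones(4, bool)))
        C2 = data_covariance(EpochSet(np.concatenate([ep, ep]), 150.0, -0.1,
                                      np.array(["memorized_tonal"] * 8),
                                      np.ones(8, bool)))
        assert np.allclose(C1, C2, rtol=1e-2)

    def test_non_finite_rejected(self):
        X = np.full((3, 100), np.nan)
        with pytest.raises(ValueError):
            data_covariance(X)


class TestLcmv:
    def test_unit_gain_for_all_active_dipoles(self, tiny_geometry, rng):
        _, grid, lead = tiny_geometry
        C = np.cov(rng.normal(size=(lead.n_channels, 2000)))
        bf = lcmv_weights(lead, C)
        for d in np.flatnonzero(bf.active)[::7]:
            l = lead.column(d, bf.orientations[d])
            assert bf.weights[d] @ l == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_round_trip(self, desk_geometry):
        """Forward-project a single dipole, invert, recover amplitude within
        1% and localize exactly."""
        _, grid, lead = desk_geometry
        g, orient = 310, np.array([0.28, 0.96])
        amp = 3e-8 * np.sin(2 * np.pi * 3 * np.arange(1500) / 150.0)
        data = np.outer(lead.column(g, orient), amp)
        C = np.cov(data)
        C += 1e-8 * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
        bf = lcmv_weights(lead, C)
        est = bf.weights @ data
        assert np.abs(est[g]).max() == pytest.approx(np.abs(amp).max(), rel=0.01)
        power = (est**2).mean(axis=1)
        assert power.argmax() == g

    def test_localization_at_20db_snr_within_two_grid_steps(self, desk_geometry, rng):
        _, grid, lead = desk_geometry
        g, orient = 310, np.array([0.28, 0.96])
        amp = 3e-8 * np.sin(2 * np.pi * 3 * np.arange(1500) / 150.0)
        clean = np.outer(lead.column(g, orient), amp)
        noise = rng.normal(0, clean.std() * 10**(-20 / 20), size=clean.shape)
        data = clean + noise
        C = np.cov(data)
        C += 0.05 * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
        bf = lcmv_weights(lead, C)
        power = (bf.weights @ data) ** 2
        best = power.mean(axis=1).argmax()
        dist = np.linalg.norm(grid.positions[best] - grid.positions[g])
        assert dist <= 2 * grid.spacing + 1e-12

    def test_center_dipole_skipped_not_crashed(self, desk_geometry, rng):
        _, grid, lead = desk_geometry
        center = np.linalg.norm(grid.positions, axis=1).argmin()
        C = np.cov(rng.normal(size=(lead.n_channels, 1000)))
        bf = lcmv_weights(lead, C)
        if not bf.active[center]:
            assert np.allclose(bf.weights[center], 0.0)


class TestReconstruct:
    def test_zero_in_zero_out(self, tiny_geometry, rng):
        _, _, lead = tiny_geometry
        bf = lcmv_weights(lead, np.cov(rng.normal(size=(lead.n_channels, 1000))))
        out = reconstruct(bf, np.zeros((lead.n_channels, 10)), sfreq=150.0)
        assert np.allclose(out.data, 0.0)

    def test_linearity(self, tiny_geometry, rng):
        _, _, lead = tiny_geometry
        bf = lcmv_weights(lead, np.cov(rng.normal(size=(lead.n_channels, 1000))))
        a = rng.normal(size=(lead.n_channels, 10))
        b = rng.normal(size=(lead.n_channels, 10))
        ra = reconstruct(bf, a, sfreq=150.0).data
        rb = reconstruct(bf, b, sfreq=150.0).data
        rab = reconstruct(bf, a + b, sfreq=150.0).data
        assert np.allclose(rab, ra + rb)

    def test_channel_mismatch_rejected(self, tiny_geometry, rng):
        _, _, lead = tiny_geometry
        bf = lcmv_weights(lead, np.cov(rng.normal(size=(lead.n_channels, 1000))))
        with pytest.raises(ValueError):
            reconstruct(bf, np.zeros((lead.n_channels + 1, 5)), sfreq=150.0)


class TestWindowMeans:
    def test_five_contiguous_windows_cover_excerpt(self):
        lo = [w[0] for w in TONE_WINDOWS]
        hi = [w[1] for w in TONE_WINDOWS]
        assert lo[0] == 0.0 and hi[-1] == 1.25
        assert all(a == b for a, b in zip(hi[:-1], lo[1:]))

    def test_known_step_signal(self):
        sfreq = 150.0
        n = 203
        times = -0.1 + np.arange(n) / sfreq
        sig = np.zeros((1, n))
        for k in range(5):
            sel = (times >= k * 0.25) & (times < (k + 1) * 0.25)
            sig[0, sel] = k + 1
        sig[0, times >= 1.25] = 5
        wm = window_means(sig, sfreq=sfreq, tmin=-0.1)
        assert np.allclose(wm[0], [1, 2, 3, 4, 5])


class TestFirstAndGroupLevel:
    def _est(self, data):
        return SourceEstimate(np.asarray(data, float), 150.0, -0.1)

    def test_identical_conditions_zero_contrast(self, rng):
        x = rng.normal(size=(20, 30))
        con = first_level(self._est(x), self._est(x))
        assert np.allclose(con.data, 0.0)

    def test_known_offset_recovered(self, rng):
        base = rng.normal(size=(10, 50))
        con = first_level(self._est(base + 2.0), self._est(base))
        # alignment may flip a whole dipole's sign; magnitude of the mean
        # offset is preserved
        assert np.allclose(np.abs(con.data.mean(axis=1)), 2.0, atol=0.2)

    def test_orientation_sign_flip_leaves_abs_contrast_unchanged(self, rng):
        m = rng.normal(size=(6, 40)) + 1.0
        n = rng.normal(size=(6, 40))
        con = first_level(self._est(m), self._est(n)).data
        flip = np.ones((6, 1))
        flip[2] = -1
        con_f = first_level(self._est(m * flip), self._est(n * flip)).data
        assert np.allclose(np.abs(con), np.abs(con_f))

    def test_group_level_needs_two_subjects(self):
        with pytest.raises(ValueError):
            group_level(np.zeros((1, 5, 3)))

    def test_null_cohort_false_positive_rate_near_alpha(self, rng):
        contrasts = rng.normal(size=(25, 400, 4))
        _, pos, neg = group_level(contrasts, voxel_alpha=0.05)
        frac = (pos.n_ones + neg.n_ones) / (400 * 4)
        assert 0.02 < frac < 0.09

    def test_injected_roi_effect_concentrates_ones(self, rng):
        contrasts = rng.normal(size=(15, 200, 2))
        contrasts[:, 40:60, :] += 2.0
        smap, pos, neg = group_level(contrasts, voxel_alpha=0.05)
        assert pos.data[40:60].mean() > 0.9
        assert pos.data[:40].mean() < 0.15

    def test_zero_variance_cells_degenerate_not_inf(self):
        contrasts = np.ones((8, 10, 2))
        smap, pos, neg = group_level(contrasts)
        assert np.isfinite(smap.t).all()


class TestWindowedMcsFamilies:
    def test_adjusted_alpha_is_001_over_ten(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        con = rng.normal(size=(8, grid.n_dipoles, 203))
        con[:, grid.roi_indices("cingulate"), :] += 3.0
        tab = tone_window_mcs(con, grid, 150.0, tmin=-0.1, band_count=2,
                              n_perm=200, seed=0)
        assert len(tab) > 0
        assert np.allclose(tab["mcs_alpha"], 0.01 / 10)

    def test_null_contrasts_give_no_significant_clusters(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        con = rng.normal(size=(10, grid.n_dipoles, 60))
        tab = tone_window_mcs(con, grid, 48.0, tmin=0.0, n_perm=300, seed=1)
        if len(tab):
            assert not tab["significant"].any()

    def test_injected_roi_effect_recovered_in_correct_windows(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        sfreq = 150.0
        n = 203
        times = -0.1 + np.arange(n) / sfreq
        con = rng.normal(size=(10, grid.n_dipoles, n))
        roi = grid.roi_indices("cingulate")
        effect_window = (times >= 0.5) & (times <= 1.25)   # tones 3-5
        con[:, roi[:, None], np.flatnonzero(effect_window)[None, :]] += 3.0
        tab = tone_window_mcs(con, grid, sfreq, tmin=-0.1, n_perm=500, seed=2)
        sig = tab[(tab["significant"] == True)  # noqa: E712
                  & (tab["direction"] == "memorized>novel")]
        hit_windows = set(sig[sig["roi_majority"] == "cingulate"]["window"])
        assert {3, 4, 5} <= hit_windows
        assert not (set(sig[sig["roi_majority"] == "cingulate"]["window"]) & {1})

    def test_piece_contrast_identical_pieces_empty(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        x = rng.normal(size=(8, grid.n_dipoles, 60))
        tab = memorized_piece_contrast(x, x.copy(), grid, 48.0, n_perm=200, seed=3)
        if len(tab):
            assert not tab["significant"].any()

    def test_band_contrast_invariant_to_global_gain(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        slow = rng.normal(size=(8, grid.n_dipoles, 60))
        fast = rng.normal(size=(8, grid.n_dipoles, 60))
        a = band_contrast(slow, fast, grid, 48.0, n_perm=150, seed=4)
        b = band_contrast(slow, fast * 10.0, grid, 48.0, n_perm=150, seed=4)
        assert a.equals(b)


class TestFamiliarityCorrelation:
    def test_perfectly_linear_pair_r_one(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        ratings = np.array([1, 2, 3, 4, 5, 6, 7, 2, 4, 6], dtype=float)
        X = rng.normal(size=(10, grid.n_dipoles, 5)) * 0.0
        X[:, 0, 0] = ratings
        X += rng.normal(size=X.shape) * 1e-9
        r, tab = familiarity_correlation(ratings, X, grid, n_perm=100, seed=0)
        assert r[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_independent_ratings_calibrated(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        ratings = rng.integers(1, 8, size=20).astype(float)
        X = rng.normal(size=(20, grid.n_dipoles, 5))
        r, tab = familiarity_correlation(ratings, X, grid, n_perm=200, seed=5)
        frac = np.mean(np.abs(r) > 0)
        p_emp = 2 * stats.t.sf(np.abs(r * np.sqrt(18 / (1 - r**2))), df=18)
        assert 0.02 < (p_emp < 0.05).mean() < 0.09

    def test_coupled_roi_yields_positive_cluster_there(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        n_subj = 16
        ratings = rng.integers(1, 8, size=n_subj).astype(float)
        X = rng.normal(size=(n_subj, grid.n_dipoles, 5))
        roi = grid.roi_indices("auditory_L")
        X[:, roi, :] += 1.0 * ratings[:, None, None]
        r, tab = familiarity_correlation(ratings, X, grid, n_perm=300, seed=6)
        sig = tab[(tab["significant"] == True)  # noqa: E712
                  & (tab["direction"] == "positive")]
        assert len(sig) >= 1
        assert (sig["roi_majority"] == "auditory_L").any()

    def test_zero_variance_ratings_rejected(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        with pytest.raises(ValueError, match="zero variance"):
            familiarity_correlation(np.full(10, 4.0),
                                    rng.normal(size=(10, grid.n_dipoles, 5)),
                                    grid)

    def test_out_of_scale_ratings_rejected(self, desk_geometry, rng):
        _, grid, _ = desk_geometry
        with pytest.raises(ValueError):
            familiarity_correlation(np.array([0.0, 3.0, 9.0]),
                                    rng.normal(size=(3, grid.n_dipoles, 5)), grid)
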