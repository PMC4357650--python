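"""Baseline subtraction, normalisation, reduction, recalibration, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycomsi.io import ImagingDataset, PeakList, RawProfile, SpotMeta
from glycomsi.preprocess import (
    RmsNormalizer,
    TicNormalizer,
    apply_recalibration,
    bin_spectra,
    fit_recalibration,
    normalize_rms,
    normalize_tic,
    occupancy_filter,
    reduce_profile,
    tophat_baseline,
)


def brute_force_opening(y: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window erosion then dilation with edge replication."""
    half = window // 2
    n = len(y)
    padded = np.concatenate([np.full(half, y[0]), y, np.full(half, y[-1])])
    eroded = np.array([padded[i : i + window].min() for i in range(n)])
    padded_e = np.concatenate(
        [np.full(half, eroded[0]), eroded, np.full(half, eroded[-1])]
    )
    return np.array([padded_e[i : i + window].max() for i in range(n)])


def _profile(intensity):
    intensity = np.asarray(intensity, dtype=float)
    return RawProfile(1000.0 + np.arange(len(intensity)), intensity)


class TestTopHat:
    def test_constant_profile_maps_to_zero(self):
        out = tophat_baseline(_profile(np.full(50, 7.0)), window=5)
        np.testing.assert_allclose(out.intensity, 0.0)

    def test_isolated_spike_preserved(self):
        y = np.zeros(31)
        y[15] = 10.0
        out = tophat_baseline(_profile(y), window=5)
        assert out.intensity[15] == pytest.approx(10.0)

    def test_ramp_matches_brute_force(self):
        y = np.arange(10.0)
        out = tophat_baseline(_profile(y), window=3)
        np.testing.assert_allclose(
            out.intensity, y - brute_force_opening(y, 3), atol=1e-12
        )

    @given(
        seed=st.integers(0, 2**16),
        n=st.integers(10, 200),
        window=st.sampled_from([3, 5, 7, 9]),
    )
    @settings(max_examples=60, deadline=None)
    def test_equals_brute_force_min_max_filter(self, seed, n, window):
        """The morphological opening equals explicit erosion + dilation."""
        rng = np.random.default_rng(seed)
        y = rng.random(n) * 100
        out = tophat_baseline(_profile(y), window=window)
        np.testing.assert_allclose(
            out.intensity, y - brute_force_opening(y, window), atol=1e-9
        )
        assert (out.intensity >= 0).all()

    @pytest.mark.parametrize("window", [2, 1, 4, 101])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            tophat_baseline(_profile(np.zeros(50)), window=window)


class TestNormalization:
    def test_tic_simple(self):
        out = normalize_tic(_profile([1.0, 3.0]))
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])

    def test_tic_idempotent_and_conserving(self, rng):
        p = _profile(rng.random(100))
        once = normalize_tic(p)
        twice = normalize_tic(once)
        assert once.intensity.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(once.intensity, twice.intensity, atol=1e-12)

    def test_rms_reference_values(self):
        out = normalize_rms(_profile([3.0, 4.0]))
        np.testing.assert_allclose(out.intensity, [0.84853, 1.13137], atol=1e-5)

    def test_rms_unit_output(self, rng):
        out = normalize_rms(_profile(rng.random(64)))
        assert np.sqrt(np.mean(out.intensity**2)) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_tic(_profile(np.zeros(5)))
        with pytest.raises(ValueError):
            normalize_rms(_profile(np.zeros(5)))

    def test_peaklist_normalization_keeps_mz_and_snr(self):
        p = PeakList([1100.0, 1200.0], [2.0, 6.0], [5.0, 5.0])
        out = normalize_tic(p)
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])
        np.testing.assert_allclose(out.snr, p.snr)

    def test_matrix_normalizers(self, rng):
        X = rng.random((8, 20)) + 0.01
        tic = TicNormalizer().fit_transform(X)
        np.testing.assert_allclose(tic.sum(axis=1), 1.0, atol=1e-12)
        rms = RmsNormalizer().fit_transform(X)
        np.testing.assert_allclose(
            np.sqrt((rms**2).mean(axis=1)), 1.0, atol=1e-12
        )


class TestReduceProfile:
    def test_short_profile_unchanged(self):
        p = _profile(np.arange(100.0))
        assert reduce_profile(p, 200) is p

    def test_spike_maximum_retained(self, rng):
        y = rng.random(500)
        y[237] = 50.0
        out = reduce_profile(_profile(y), 10)
        assert out.intensity.max() == pytest.approx(50.0)

    def test_monotone_profile_stays_monotone(self):
        y = np.linspace(0, 1, 1000) ** 2
        out = reduce_profile(_profile(y), 50)
        assert (np.diff(out.intensity) >= 0).all()

    def test_interval_max_oracle(self, rng):
        y = rng.random(300)
        p = _profile(y)
        out = reduce_profile(p, 7)
        edges = np.linspace(p.mz[0], p.mz[-1], 8)
        for i in range(7):
            inside = (p.mz >= edges[i]) & (
                (p.mz < edges[i + 1]) if i < 6 else (p.mz <= edges[i + 1])
            )
            expected = y[inside].max() if inside.any() else 0.0
            assert out.intensity[i] == pytest.approx(expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            reduce_profile(_profile(np.zeros(10)), 1)


class TestRecalibration:
    def test_exact_interpolation_with_three_pairs(self):
        obs = np.array([1000.0, 1500.0, 2000.0])
        model = fit_recalibration(obs, obs + 0.5)
        assert model.a == pytest.approx(0.0, abs=1e-12)
        assert model.b == pytest.approx(1.0, abs=1e-9)
        assert model.c == pytest.approx(0.5, abs=1e-6)
        np.testing.assert_allclose(model.residuals_ppm, 0.0, atol=1e-6)

    def test_planted_quadratic_recovered_at_held_out_point(self):
        a, b, c = 1e-8, 1.00002, -0.3
        ref = np.array([1100.0, 1500.0, 1900.0, 2300.0])
        # observed masses are the pre-image of the distortion, found via
        # the (monotone) quadratic itself on a fine inversion
        def invert(r):
            from scipy.optimize import brentq
            return brentq(lambda m: a * m * m + b * m + c - r, 500.0, 4000.0)
        obs = np.array([invert(r) for r in ref])
        model = fit_recalibration(obs[:3], ref[:3])
        assert model(obs[3]) == pytest.approx(ref[3], abs=1e-9)

    def test_two_pairs_insufficient(self):
        with pytest.raises(ValueError):
            fit_recalibration([1000.0, 1500.0], [1000.1, 1500.1])

    def test_calibrant_matching_within_tolerance(self):
        # full peak list containing the calibrants plus clutter
        obs = np.array([1000.2, 1234.9, 1257.40, 1542.57, 2393.80, 2500.0])
        ref = np.array([1257.4225, 1542.5551, 2393.8457])
        model = fit_recalibration(obs, ref, match_tol_ppm=100)
        assert len(model.observed) == 3

    def test_apply_identity_and_shift(self, small_phantom):
        ds, _ = small_phantom
        ident = fit_recalibration(
            np.array([1000.0, 1500.0, 2000.0]), np.array([1000.0, 1500.0, 2000.0])
        )
        same = apply_recalibration(ident, ds)
        sid = ds.spot_ids[0]
        np.testing.assert_allclose(
            same.peaklists[sid].mz, ds.peaklists[sid].mz, atol=1e-9
        )
        shift = fit_recalibration(
            np.array([1000.0, 1500.0, 2000.0]),
            np.array([1000.5, 1500.5, 2000.5]),
        )
        moved = apply_recalibration(shift, ds)
        np.testing.assert_allclose(
            moved.peaklists[sid].mz, ds.peaklists[sid].mz + 0.5, atol=1e-6
        )

    def test_quadratic_apply_matches_per_peak_polynomial(self, small_phantom):
        ds, _ = small_phantom
        a, b, c = 1e-9, 1.0001, -0.2
        obs = np.array([1000.0, 1600.0, 2200.0])
        model = fit_recalibration(obs, a * obs**2 + b * obs + c)
        out = apply_recalibration(model, ds)
        sid = next(s for s in ds.spot_ids if len(ds.peaklists[s]) > 0)
        mz = ds.peaklists[sid].mz
        np.testing.assert_allclose(
            out.peaklists[sid].mz, a * mz**2 + b * mz + c, atol=1e-9
        )

    def test_non_monotone_model_rejected(self, small_phantom):
        ds, _ = small_phantom
        from glycomsi.preprocess import CalibrationModel

        # decreasing map over the acquisition range
        model = CalibrationModel(
            0.0, -1.0, 3000.0, np.array([]), np.array([]), np.array([])
        )
        with pytest.raises(ValueError, match="monotone"):
            apply_recalibration(model, ds)


class TestBinning:
    def _two_spot_dataset(self):
        spots = [SpotMeta("a", 0, 0, "treated"), SpotMeta("b", 1, 0, "control")]
        pl = {
            "a": PeakList([1000.2, 1000.4], [1.0, 2.0], [3.0, 3.0]),
            "b": PeakList([1000.5], [4.0], [3.0]),
        }
        return ImagingDataset(spots, pl)

    def test_half_open_bins(self):
        ds = self._two_spot_dataset()
        binned = bin_spectra(ds, width=0.5, mz_range=(1000.0, 1001.0))
        # spot a: both peaks in [1000.0, 1000.5) -> 3.0
        assert binned.intensities[0, 0] == pytest.approx(3.0)
        assert binned.intensities[0, 1] == pytest.approx(0.0)
        # spot b: edge peak 1000.5 goes to the upper bin
        assert binned.intensities[1, 0] == pytest.approx(0.0)
        assert binned.intensities[1, 1] == pytest.approx(4.0)

    def test_total_intensity_conserved(self, small_phantom):
        ds, _ = small_phantom
        binned = bin_spectra(ds, width=0.5)
        lo, hi = binned.bin_edges[0], binned.bin_edges[-1]
        total = sum(
            p.intensity[(p.mz >= lo) & (p.mz < hi)].sum()
            for p in ds.peaklists.values()
        )
        assert binned.intensities.sum() == pytest.approx(total, rel=1e-9)

    def test_occupancy_filter_keeps_dense_bins(self, small_phantom):
        ds, truth = small_phantom
        binned = bin_spectra(ds, width=0.5)
        reduced = occupancy_filter(binned, min_spectra=30)
        assert 0 < reduced.intensities.shape[1] < binned.intensities.shape[1]
        # every planted sodiated mass lands in a surviving bin
        for m in truth.table["sodiated_mz"]:
            assert np.min(np.abs(reduced.bin_centers - m)) <= 0.25 + 1e-9

    def test_invalid_width(self, small_phantom):
        ds, _ = small_phantom
        with pytest.raises(ValueError):
            bin_spectra(ds, width=0.0, mz_range=(1000.0, 2000.0))
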