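"""Morlet CWT, smoothing, cone of influence, and coherence properties."""

import numpy as np
import pytest

import interbrain as ib
from interbrain.exceptions import DegenerateInputError, GridError
from interbrain.wavelet import WtcEngine, fourier_factor


def cwt_time_domain(x, grid):
    """Independent oracle: direct time-domain sum with the sampled Morlet."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = x.size
    out = np.empty((len(grid), n), complex)
    m = np.arange(n)
    for i, s in enumerate(grid.scales):
        for t0 in range(n):
            eta = (m - t0) * grid.dt / s
            psi = np.pi**-0.25 * np.exp(1j * grid.omega0 * eta - eta**2 / 2)
            out[i, t0] = np.sum(x * np.sqrt(grid.dt / s) * np.conj(psi))
    return out


class TestScaleGrid:
    @pytest.mark.parametrize(
        "f_min,f_max,voices,dt,expected",
        [
            (0.0039, 0.2894, 12, 1.5, 75),  # the study grid
            (0.01, 0.08, 12, 1.5, 37),  # floor(12*log2(8)) + 1
            (0.05, 0.05, 12, 1.5, 1),  # zero octaves
        ],
    )
    def test_scale_count(self, f_min, f_max, voices, dt, expected):
        grid = ib.build_scale_grid(f_min, f_max, voices, dt)
        assert len(grid) == expected

    def test_geometric_spacing_and_frequency_map(self, grid_study):
        ratios = grid_study.scales[1:] / grid_study.scales[:-1]
        assert np.allclose(ratios, 2 ** (1 / 12))
        # frequencies descend and match the Fourier-factor reciprocal
        assert np.all(np.diff(grid_study.frequencies) < 0)
        assert np.allclose(
            grid_study.frequencies * grid_study.scales * fourier_factor(), 1.0
        )

    @pytest.mark.parametrize(
        "f_min,f_max,dt",
        [(0.0, 0.1, 1.0), (-0.01, 0.1, 1.0), (0.01, 0.5, 1.0), (0.01, 0.6, 1.0)],
    )
    def test_invalid_bounds_raise(self, f_min, f_max, dt):
        with pytest.raises(GridError):
            ib.build_scale_grid(f_min, f_max, 12, dt)


class TestCwt:
    def test_zero_signal_gives_zero_field(self, grid_small):
        field = ib.cwt_morlet(np.zeros(64), grid_small)
        assert np.allclose(field.coeffs, 0.0)

    def test_sinusoid_peaks_at_matching_scale(self, grid_small):
        t = np.arange(512)
        x = np.sin(2 * np.pi * 0.05 * t)
        field = ib.cwt_morlet(x, grid_small)
        coi = ib.cone_of_influence(grid_small, 512)
        power = np.where(coi, np.abs(field.coeffs), np.nan)
        peak_scale = np.nanargmax(np.nanmean(power, axis=1))
        assert peak_scale == grid_small.nearest_index(0.05)

    def test_matches_time_domain_convolution(self, grid_small):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(64)
        fast = ib.cwt_morlet(x, grid_small).coeffs
        slow = cwt_time_domain(x, grid_small)
        rel = np.abs(fast - slow).max() / np.abs(slow).max()
        assert rel < 1e-8

    def test_rejects_bad_input(self, grid_small):
        with pytest.raises(ValueError):
            ib.cwt_morlet(np.r_[np.ones(32), np.nan], grid_small)
        with pytest.raises(ValueError):
            ib.cwt_morlet(np.ones(4), grid_small)


class TestConeOfInfluence:
    def test_edges_and_symmetry(self, grid_small):
        n = 400
        coi = ib.cone_of_influence(grid_small, n)
        # mid-record point inside at all scales with sqrt(2)*s < T/2
        mid_ok = np.sqrt(2) * grid_small.scales < (n - 1) * grid_small.dt / 2
        assert np.array_equal(coi[:, n // 2], mid_ok)
        # record edge outside everywhere the e-folding time exceeds dt
        edge_out = np.sqrt(2) * grid_small.scales > grid_small.dt
        assert not coi[edge_out, 0].any()
        assert np.array_equal(coi, coi[:, ::-1])


class TestSmoothField:
    def test_constant_field_unchanged(self, grid_small):
        field = np.full((len(grid_small), 100), 3.7)
        out = ib.smooth_field(field, grid_small, 6)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_impulse_mass_conserved(self, grid_small):
        # interior impulse at a small scale: kernel support well inside
        field = np.zeros((len(grid_small), 600))
        field[2, 300] = 1.0
        out = ib.smooth_field(field, grid_small, 1)
        assert abs(out[2].sum() - 1.0) < 1e-9

    def test_width_one_is_identity_across_scales(self, grid_small):
        # field constant in time, varying over scale: time smoothing is
        # exact on constants, so width-1 scale smoothing must be identity
        profile = np.linspace(0.0, 1.0, len(grid_small))
        field = np.repeat(profile[:, None], 50, axis=1)
        out = ib.smooth_field(field, grid_small, 1)
        assert np.allclose(out, field, atol=1e-10)

    def test_linearity(self, grid_small):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((len(grid_small), 80))
        b = rng.standard_normal((len(grid_small), 80))
        lhs = ib.smooth_field(a + 2 * b, grid_small, 6)
        rhs = ib.smooth_field(a, grid_small, 6) + 2 * ib.smooth_field(
            b, grid_small, 6
        )
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestWtc:
    def test_self_coherence_is_one(self, grid_small):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        m = ib.wtc(x, x, grid_small)
        assert np.abs(m.r2 - 1.0).max() < 1e-6
        assert np.allclose(m.phase, 0.0, atol=1e-6)

    def test_symmetry_and_bound(self, grid_small):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(256)
        y = rng.standard_normal(256)
        mxy = ib.wtc(x, y, grid_small)
        myx = ib.wtc(y, x, grid_small)
        assert np.allclose(mxy.r2, myx.r2, atol=1e-12)
        assert np.allclose(mxy.phase, -myx.phase, atol=1e-10)
        assert mxy.r2.min() >= 0.0
        assert mxy.r2.max() <= 1.0 + 1e-9

    def test_amplitude_invariance(self, grid_small):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(256)
        y = rng.standard_normal(256)
        base = ib.wtc(x, y, grid_small)
        scaled = ib.wtc(-4.2 * x + 11.0, y, grid_small)
        assert np.abs(base.r2 - scaled.r2).max() < 1e-8

    def test_phase_tracks_pure_delay(self, grid_small):
        f0 = 0.05
        tau = 3.0  # samples = seconds at dt 1
        t = np.arange(700.0)
        x = np.sin(2 * np.pi * f0 * t)
        y = np.sin(2 * np.pi * f0 * (t - tau))
        m = ib.wtc(x, y, grid_small)
        row = grid_small.nearest_index(f0)
        incoi = m.coi_mask[row]
        expected = 2 * np.pi * f0 * tau
        assert np.abs(m.phase[row, incoi] - expected).max() < 0.05

    def test_white_noise_pairs_stay_below_self_coherence(self, grid_small):
        rng = np.random.default_rng(4)
        means = []
        for _ in range(50):
            x = rng.standard_normal(512)
            y = rng.standard_normal(512)
            m = ib.wtc(x, y, grid_small)
            means.append(m.r2[m.coi_mask].mean())
        assert np.mean(means) < 0.5

    def test_degenerate_and_mismatched_inputs(self, grid_small):
        with pytest.raises(DegenerateInputError):
            ib.wtc(np.ones(64), np.random.default_rng(0).standard_normal(64), grid_small)
        with pytest.raises(ValueError):
            ib.wtc(np.zeros(64), np.zeros(32), grid_small)


class TestEngineRowSubset:
    def test_band_rows_match_full_grid(self, grid_study):
        """Restricting the engine to band rows must reproduce the full-grid
        coherence exactly on those rows (the surrogate fast path)."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        full = ib.wtc(x, y, grid_study)
        idx = grid_study.band_indices(0.08, 0.15)
        rows = (int(idx.min()), int(idx.max()) + 1)
        eng = WtcEngine(grid_study, 300, 12, rows=rows)
        wa, wb = eng.transform(x), eng.transform(y)
        r2, phase = eng.coherence(wa, eng.smoothed_power(wa), wb, eng.smoothed_power(wb))
        assert np.abs(r2 - full.r2[rows[0] : rows[1]]).max() < 1e-9
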