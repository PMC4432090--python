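import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coanafor import (
    GuidePeak,
    GuidePeakList,
    Interferogram,
    ReconstructionConfig,
    TimeGrid,
    anafor_replace,
    build_basis,
    coanafor_extend,
    reconstruct_2d,
    select_signals_for_column,
    solve_amplitudes,
    synthesize,
    zero_fill,
)

from conftest import damped_fid


@pytest.fixture
def truncated_pair(grid128):
    """Two signals 66 Hz apart, 25% coverage."""
    freqs = [100.0, 166.0]
    data = damped_fid(freqs, [1.0, 0.8 + 0.1j], 20.0, grid128)
    rng = np.random.default_rng(3)
    data = data + 0.01 * (rng.normal(size=128) + 1j * rng.normal(size=128))
    return Interferogram.from_prefix(data, grid128, 32), freqs


class TestInterferogram:
    def test_prefix_mask(self, grid128):
        fid = Interferogram.from_prefix(np.zeros(128), grid128, 32)
        assert fid.n_recorded == 32
        assert fid.coverage == 0.25
        assert np.array_equal(fid.recorded_indices, np.arange(32))

    def test_length_mismatch(self, grid128):
        with pytest.raises(ValueError):
            Interferogram(np.zeros(64), grid128, np.ones(64, bool))


class TestCoanafor:
    def test_exact_continuation(self, grid128):
        f, r = 150.0, 18.0
        data = damped_fid([f], [2.0 - 1.0j], r, grid128)
        fid = Interferogram.from_prefix(data, grid128, 32)
        cfg = ReconstructionConfig(reg_factor=0.0, relax_rate=r, target_n_points=128)
        out = coanafor_extend(fid, [f], cfg)
        np.testing.assert_allclose(out.data, data, rtol=1e-8)

    def test_empty_peaks_degenerates_to_zero_fill(self, truncated_pair):
        fid, _ = truncated_pair
        cfg = ReconstructionConfig(target_n_points=128)
        out = coanafor_extend(fid, [], cfg)
        zf = zero_fill(fid, 128)
        assert np.array_equal(out.data, zf.data)

    def test_compositional_oracle(self, truncated_pair):
        # independent two-step reimplementation: fit then insert
        fid, freqs = truncated_pair
        cfg = ReconstructionConfig(reg_factor=0.01, relax_rate="auto", target_n_points=128)
        out = coanafor_extend(fid, freqs, cfg)
        # recorded prefix bit-identical
        assert np.array_equal(out.data[:32], fid.data[:32])
        # inserted tail equals synthesize(solve_amplitudes(...))
        grid = fid.grid
        relax = 1.0 / grid.t_max
        basis = build_basis(freqs, relax, grid, range(32))
        amps = solve_amplitudes(basis, fid.data[:32], reg_factor=0.01)
        tail = synthesize(freqs, relax, amps, grid, range(32, 128))
        np.testing.assert_allclose(out.data[32:], tail, rtol=1e-12)

    def test_target_shorter_than_recorded(self, truncated_pair):
        fid, freqs = truncated_pair
        cfg = ReconstructionConfig(target_n_points=16)
        with pytest.raises(ValueError, match="shorter"):
            coanafor_extend(fid, freqs, cfg)

    def test_interior_gap_mask(self, grid128):
        data = damped_fid([90.0], [1.0], 15.0, grid128)
        mask = np.zeros(128, bool)
        mask[:20] = True
        mask[40:60] = True
        fid = Interferogram(data, grid128, mask)
        cfg = ReconstructionConfig(reg_factor=0.0, relax_rate=15.0, target_n_points=128)
        out = coanafor_extend(fid, [90.0], cfg)
        assert np.array_equal(out.data[mask], fid.data[mask])
        np.testing.assert_allclose(out.data, data, rtol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000), n_rec=st.integers(8, 64), j=st.integers(0, 5))
    def test_conservation_property(self, seed, n_rec, j):
        rng = np.random.default_rng(seed)
        grid = TimeGrid(128, 5e-4)
        data = rng.normal(size=128) + 1j * rng.normal(size=128)
        fid = Interferogram.from_prefix(data, grid, n_rec)
        freqs = rng.uniform(-900, 900, j)
        cfg = ReconstructionConfig(reg_factor=0.01, target_n_points=128)
        out = coanafor_extend(fid, freqs, cfg)
        assert np.array_equal(out.data[:n_rec], data[:n_rec])

    def test_crowded_solve_never_raises_with_regularization(self):
        # J up to 2x recorded points, reg_factor > 0
        rng = np.random.default_rng(0)
        grid = TimeGrid(64, 1e-3)
        data = rng.normal(size=64) + 1j * rng.normal(size=64)
        fid = Interferogram.from_prefix(data, grid, 16)
        freqs = rng.uniform(-450, 450, 32)
        cfg = ReconstructionConfig(reg_factor=0.01, target_n_points=64)
        out = coanafor_extend(fid, freqs, cfg)
        assert np.all(np.isfinite(out.data))


class TestAnafor:
    def test_consistency_with_coanafor_when_noiseless(self, grid128):
        freqs = [100.0, 166.0]
        r = 1.0 / grid128.t_max
        data = damped_fid(freqs, [1.0, 0.7], r, grid128)
        fid = Interferogram.from_prefix(data, grid128, 32)
        cfg = ReconstructionConfig(
            reg_factor=0.0, anafor_reg_factor=0.0, relax_rate=r, target_n_points=128
        )
        a = anafor_replace(fid, freqs, cfg)
        c = coanafor_extend(fid, freqs, cfg)
        np.testing.assert_allclose(a.data, c.data, rtol=1e-7, atol=1e-10)
        np.testing.assert_allclose(a.data, data, rtol=1e-7, atol=1e-10)

    def test_misinformation_distorts_recorded_region(self, grid128):
        freqs = [100.0, 166.0]
        r = 20.0
        data = damped_fid(freqs, [1.0, 0.7], r, grid128)
        fid = Interferogram.from_prefix(data, grid128, 64)
        cfg = ReconstructionConfig(
            reg_factor=0.01, anafor_reg_factor=0.0, relax_rate=r, target_n_points=128
        )
        wrong = [100.0, 169.0]  # +3 Hz misinformation on signal 2
        a = anafor_replace(fid, wrong, cfg)
        c = coanafor_extend(fid, wrong, cfg)
        # ANAFOR's recorded region deviates from the measurement ...
        assert np.max(np.abs(a.data[:64] - data[:64])) > 1e-3
        # ... while Co-ANAFOR's recorded region is conserved exactly
        assert np.array_equal(c.data[:64], data[:64])

    def test_rank_deficiency_rejected(self, grid128):
        fid = Interferogram.from_prefix(np.ones(128, complex), grid128, 4)
        freqs = np.linspace(-400, 400, 8)
        cfg = ReconstructionConfig(anafor_reg_factor=0.0, target_n_points=128)
        with pytest.raises(ValueError, match="rank-deficient"):
            anafor_replace(fid, freqs, cfg)


class TestZeroFill:
    def test_full_coverage_unchanged(self, single_signal_fid):
        out = zero_fill(single_signal_fid, 128)
        assert np.array_equal(out.data, single_signal_fid.data)

    def test_append_zeros(self, grid128):
        fid = Interferogram.from_prefix(np.ones(128, complex), grid128, 32)
        out = zero_fill(fid, 128)
        assert np.array_equal(out.data[:32], np.ones(32))
        assert np.array_equal(out.data[32:], np.zeros(96))

    def test_interior_gaps_zeroed(self, grid128):
        mask = np.ones(128, bool)
        mask[10:20] = False
        fid = Interferogram(np.ones(128, complex), grid128, mask)
        out = zero_fill(fid, 128)
        expected = np.ones(128, complex)
        expected[10:20] = 0
        assert np.array_equal(out.data, expected)


class TestSelectSignals:
    PEAKS = GuidePeakList(
        [
            GuidePeak("p1", -100.0, direct_ppm=8.00),
            GuidePeak("p2", 50.0, direct_ppm=8.03),
            GuidePeak("p3", 200.0, direct_ppm=8.05),
        ]
    )

    def test_no_peak_in_window(self):
        assert select_signals_for_column(self.PEAKS, 9.5, 0.02).size == 0

    def test_boundary_included(self):
        # |8.00 - 8.02| == window -> included (closed interval)
        freqs = select_signals_for_column(self.PEAKS, 8.02, 0.02)
        assert -100.0 in freqs

    def test_hand_checked_selection(self):
        freqs = select_signals_for_column(self.PEAKS, 8.02, 0.02)
        assert sorted(freqs) == [-100.0, 50.0]

    def test_merge_near_duplicates(self):
        peaks = GuidePeakList(
            [
                GuidePeak("a", 100.0, direct_ppm=8.0),
                GuidePeak("b", 100.5, direct_ppm=8.0),
                GuidePeak("c", 300.0, direct_ppm=8.0),
            ]
        )
        freqs = select_signals_for_column(peaks, 8.0, 0.02, t_max=0.1)  # tol = 5 Hz
        assert freqs.size == 2
        assert freqs[0] == pytest.approx(100.25)


class TestReconstruct2D:
    def _setup(self):
        grid = TimeGrid(64, 1e-3)
        peaks = GuidePeakList(
            [
                GuidePeak("x", 120.0, direct_ppm=8.0),
                GuidePeak("y", -200.0, direct_ppm=8.5),
            ]
        )
        t = grid.times
        col0 = np.exp((2j * np.pi * 120.0 - 12.0) * t)
        col1 = np.exp((2j * np.pi * -200.0 - 12.0) * t)
        columns = np.vstack([col0, col1])
        mask = np.zeros(64, bool)
        mask[:16] = True
        return grid, peaks, columns, mask

    def test_single_column_reduces_to_1d(self):
        grid, peaks, columns, mask = self._setup()
        cfg = ReconstructionConfig(reg_factor=0.01, target_n_points=64)
        out = reconstruct_2d(columns[:1], [8.0], peaks, cfg, "coanafor", grid, mask)
        fid = Interferogram(columns[0], grid, mask)
        freqs = select_signals_for_column(peaks, 8.0, 0.02, t_max=grid.t_max)
        expected = coanafor_extend(fid, freqs, cfg)
        np.testing.assert_array_equal(out[0], expected.data)

    def test_empty_peaklist_zero_fills(self):
        grid, _, columns, mask = self._setup()
        cfg = ReconstructionConfig(target_n_points=64)
        out = reconstruct_2d(columns, [8.0, 8.5], GuidePeakList([]), cfg, "coanafor", grid, mask)
        for i in range(2):
            zf = zero_fill(Interferogram(columns[i], grid, mask), 64)
            np.testing.assert_array_equal(out[i], zf.data)

    def test_per_column_equality_with_1d_calls(self):
        grid, peaks, columns, mask = self._setup()
        cfg = ReconstructionConfig(reg_factor=0.01, target_n_points=64)
        ppm = [8.0, 8.5]
        for method in ("coanafor", "anafor", "zerofill", "lp", "sift"):
            out = reconstruct_2d(columns, ppm, peaks, cfg, method, grid, mask)
            assert out.shape == (2, 64)
            assert np.all(np.isfinite(out))

    def test_unknown_method(self):
        grid, peaks, columns, mask = self._setup()
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct_2d(columns, [8.0, 8.5], peaks, ReconstructionConfig(), "magic", grid, mask)
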