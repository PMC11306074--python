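"""Frequency-domain feature fusion: DFT oracles, pooling, fusion, DSC,
spatial attention, and the assembled block."""

import numpy as np
import pytest

import kiwidet.autograd as ag
from kiwidet.autograd import Tensor
from kiwidet import fdff, nn
from kiwidet.fdff import (FDFF, FDFFConfig, DSC, SpatialAttention,
                          channel_max_mean, conv_param_count, dsc_param_count,
                          fft2d, ifft2d, freq_maxpool, fuse_multiply,
                          spectrum_to_real)


def naive_dft2(x: np.ndarray) -> np.ndarray:
    """O(N^4) double-loop 2-D DFT oracle (per batch/channel slice)."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, h, w), dtype=np.complex128)
    for u in range(h):
        for v in range(w):
            acc = np.zeros((n, c), dtype=np.complex128)
            for a in range(h):
                for b in range(w):
                    acc += x[:, :, a, b] * np.exp(-2j * np.pi * (u * a / h + v * b / w))
            out[:, :, u, v] = acc
    return out


class TestFFT:
    def test_constant_slice_concentrates_at_dc(self):
        c = 2.5
        s = fft2d(np.full((1, 1, 4, 4), c))
        assert s[0, 0, 0, 0] == pytest.approx(16 * c)
        rest = s.copy()
        rest[0, 0, 0, 0] = 0
        assert np.abs(rest).max() == pytest.approx(0.0, abs=1e-12)

    def test_impulse_gives_flat_spectrum(self):
        x = np.zeros((1, 1, 4, 4))
        x[0, 0, 0, 0] = 1.0
        s = fft2d(x)
        np.testing.assert_allclose(s, np.ones((1, 1, 4, 4), complex), atol=1e-12)

    @pytest.mark.parametrize("h,w", [(4, 4), (5, 7), (8, 8)])
    def test_matches_naive_dft_oracle(self, h, w, rng):
        x = rng.integers(-5, 6, size=(2, 2, h, w)).astype(np.float64)
        np.testing.assert_allclose(fft2d(x), naive_dft2(x), rtol=1e-9, atol=1e-9)

    def test_inversion_reconstructs(self, rng):
        x = rng.standard_normal((2, 3, 8, 8))
        rec = ifft2d(fft2d(x))
        assert np.abs(rec - x).max() / np.abs(x).max() < 1e-6

    def test_conjugate_symmetry_for_real_input(self, rng):
        x = rng.standard_normal((1, 1, 6, 6))
        s = fft2d(x)[0, 0]
        for u in range(6):
            for v in range(6):
                assert s[u, v] == pytest.approx(np.conj(s[-u % 6, -v % 6]), abs=1e-9)

    def test_parseval(self, rng):
        x = rng.standard_normal((2, 2, 8, 8))
        s = fft2d(x)
        lhs = (np.abs(x) ** 2).sum(axis=(2, 3))
        rhs = (np.abs(s) ** 2).sum(axis=(2, 3)) / (8 * 8)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_nonfinite_input_rejected(self):
        x = np.zeros((1, 1, 4, 4))
        x[0, 0, 1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fft2d(x)


class TestSpectrumProjection:
    def test_real_only_of_constant(self):
        s = fft2d(np.full((1, 1, 4, 4), 3.0))
        r = spectrum_to_real(s, "real_only")
        assert r[0, 0, 0, 0] == pytest.approx(48.0)
        assert np.abs(r).sum() == pytest.approx(48.0)

    def test_imag_only_even_symmetric_input_is_zero(self):
        # x[n] = x[-n mod N] in both axes -> purely real spectrum
        base = np.array([4.0, 1.0, 2.0, 1.0])
        x = np.outer(base, base)[None, None]
        s = fft2d(x)
        np.testing.assert_allclose(spectrum_to_real(s, "imag_only"), 0.0, atol=1e-10)

    def test_real_and_imag_stacks_channels(self, rng):
        x = rng.standard_normal((1, 8, 4, 4))
        s = fft2d(x)
        both = spectrum_to_real(s, "real_and_imag")
        assert both.shape == (1, 16, 4, 4)
        np.testing.assert_array_equal(both[:, :8], spectrum_to_real(s, "real_only"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            spectrum_to_real(fft2d(np.ones((1, 1, 2, 2))), "phase_only")


class TestFreqMaxpool:
    def test_constant_map_unchanged_including_borders(self):
        x = np.full((1, 1, 5, 5), 7.0)
        np.testing.assert_array_equal(freq_maxpool(x, 3, 1), x)

    def test_single_max_center_dominates_all_windows(self):
        x = np.arange(9, dtype=float).reshape(1, 1, 3, 3) / 10.0
        x[0, 0, 1, 1] = 5.0
        out = freq_maxpool(x, 3, 1)
        # hand enumeration: every 3x3 window contains the centre
        np.testing.assert_array_equal(out, np.full((1, 1, 3, 3), 5.0))

    def test_positive_homogeneity(self, rng):
        x = rng.standard_normal((1, 2, 6, 6))
        a = 3.7
        np.testing.assert_allclose(freq_maxpool(a * x), a * freq_maxpool(x),
                                   rtol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            freq_maxpool(np.ones((1, 1, 4, 4)), kernel=2)


class TestFuseMultiply:
    def test_identity_and_annihilator(self, rng):
        xs = rng.standard_normal((1, 2, 3, 3))
        np.testing.assert_array_equal(fuse_multiply(np.ones_like(xs), xs), xs)
        np.testing.assert_array_equal(fuse_multiply(np.zeros_like(xs), xs), 0 * xs)

    def test_hand_hadamard(self):
        xm = np.array([[1.0, 2.0], [3.0, 4.0]])[None, None]
        xs = np.array([[5.0, 6.0], [7.0, 8.0]])[None, None]
        np.testing.assert_array_equal(
            fuse_multiply(xm, xs),
            np.array([[5.0, 12.0], [21.0, 32.0]])[None, None])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_multiply(np.ones((1, 1, 2, 2)), np.ones((1, 1, 3, 3)))


class TestDSC:
    def test_param_count_formulas(self):
        assert conv_param_count(3, 3, 64, 64) == 36864
        assert dsc_param_count(3, 3, 64, 64) == 4672
        for c in (1, 3, 17, 64):
            assert dsc_param_count(1, 1, c, c) == c + c * c
        # separable beats dense once C exceeds 9/8 (equality never holds)
        for c in (2, 3, 17, 64):
            assert dsc_param_count(3, 3, c, c) < conv_param_count(3, 3, c, c)

    def test_param_ratio(self):
        # ratio of separable to dense weights: 1/C_O + 1/9 for 3x3 kernels
        for c in (8, 64, 256):
            ratio = dsc_param_count(3, 3, c, c) / conv_param_count(3, 3, c, c)
            assert ratio == pytest.approx(1 / c + 1 / 9)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            dsc_param_count(3, 3, 0, 4)
        with pytest.raises(ValueError):
            DSC(4, 0)

    def test_identity_construction(self, rng):
        c = 3
        m = DSC(c, c, kernel=3)
        m.dw.w.data[:] = 0
        m.dw.w.data[:, 1, 1] = 1.0          # centre tap
        m.pw.w.data[:] = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
        m.pw.b.data[:] = 0
        m.eval()                             # identity BN (fresh running stats)
        x = rng.standard_normal((1, c, 5, 5)).astype(np.float32)
        out = m(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=2e-2, rtol=1e-2)

    def test_equivalence_with_dense_composition_oracle(self, rng):
        """depthwise (x) pointwise composed into one dense kernel."""
        c_in, c_out, k = 2, 3, 3
        m = DSC(c_in, c_out, kernel=k, rng=rng)
        m.eval()
        x = rng.standard_normal((1, c_in, 5, 5)).astype(np.float32)
        got = m(Tensor(x)).data
        dense = np.zeros((c_out, c_in, k, k), np.float32)
        for o in range(c_out):
            for i in range(c_in):
                dense[o, i] = m.pw.w.data[o, i, 0, 0] * m.dw.w.data[i]
        ref = ag.conv2d(Tensor(x), Tensor(dense), Tensor(m.pw.b.data), 1, k // 2)
        # fresh eval-mode BN is identity up to its eps (1e-3) scale factor
        np.testing.assert_allclose(got, ref.data, rtol=2e-3, atol=1e-3)


class TestSpatialAttention:
    def test_output_in_unit_interval_and_shape(self, rng):
        sa = SpatialAttention(7, rng=rng)
        sa.eval()
        x = rng.standard_normal((2, 5, 6, 6)).astype(np.float32)
        a = sa(Tensor(x)).data
        assert a.shape == (2, 1, 6, 6)
        assert (a > 0).all() and (a < 1).all()

    def test_spatially_constant_input_gives_constant_map(self, rng):
        sa = SpatialAttention(7, rng=rng)
        sa.eval()
        x = np.broadcast_to(np.arange(5, dtype=np.float32)[None, :, None, None],
                            (1, 5, 16, 16)).copy()
        a = sa(Tensor(x)).data
        # translation equivariance holds away from the zero-padded border
        assert np.ptp(a[:, :, 3:-3, 3:-3]) < 1e-6

    def test_descriptor_matches_hand_loop(self, rng):
        x = rng.standard_normal((1, 3, 2, 2)).astype(np.float32)
        d = channel_max_mean(Tensor(x)).data
        for i in range(2):
            for j in range(2):
                assert d[0, 0, i, j] == pytest.approx(max(x[0, :, i, j]))
                assert d[0, 1, i, j] == pytest.approx(np.mean(x[0, :, i, j]))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SpatialAttention(4)


class TestFDFFBlock:
    @pytest.mark.parametrize("mode,c,cout", [
        ("real_only", 8, 8), ("imag_only", 8, 8),
        ("real_and_imag", 8, 8), ("real_only", 6, 12),
    ])
    def test_shape_contract(self, mode, c, cout, rng):
        blk = FDFF(c, cout, FDFFConfig(spectrum_mode=mode), rng=rng)
        blk.eval()
        x = rng.standard_normal((2, c, 6, 6)).astype(np.float32)
        assert blk(Tensor(x)).shape == (2, cout, 6, 6)

    def test_calibrated_parameter_budget(self):
        """The default block at 64 channels costs exactly 25,618 parameters,
        the published insertion delta of the nano detector at P3."""
        blk = FDFF(64)
        assert blk.deploy_params() == 25618
        assert blk.hidden == 126

    def test_reduces_to_fuse_multiply_under_ablation(self, rng):
        """Attention forced to 1, fusion conv set to identity on the first C
        channels -> output equals the multiplicative fusion X_M * X_S."""
        c = 4
        blk = FDFF(c, c, FDFFConfig(act=False), rng=rng)
        h = blk.hidden
        blk.expand.w.data[:] = 0
        for i in range(c):
            blk.expand.w.data[i, i, 0, 0] = 1.0   # select X_MS channels
        blk.dw.w.data[:] = 0
        blk.dw.w.data[:, 1, 1] = 1.0
        blk.project.w.data[:] = 0
        for i in range(c):
            blk.project.w.data[i, i, 0, 0] = 1.0
        blk.project.b.data[:] = 0
        blk.eval()                                # identity BN
        # force the attention gate to 1 by monkeypatching its forward
        blk.attn.forward = lambda x: Tensor(np.ones((1, 1, 1, 1), np.float32))
        x = rng.standard_normal((1, c, 5, 5)).astype(np.float32)
        got = blk(Tensor(x)).data
        xf = spectrum_to_real(fft2d(x.astype(np.float64)), "real_only")
        expected = fuse_multiply(freq_maxpool(xf.astype(np.float32)), x)
        np.testing.assert_allclose(got, expected, rtol=2e-2, atol=2e-2)

    def test_deterministic_given_fixed_weights(self, rng):
        blk = FDFF(8, rng=np.random.default_rng(3))
        blk.eval()
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        a = blk(Tensor(x)).data
        b = blk(Tensor(x)).data
        np.testing.assert_array_equal(a, b)

    def test_stride_changing_pool_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            FDFF(8, cfg=FDFFConfig(pool_stride=2))
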