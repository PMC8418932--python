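import numpy as np
import pytest
from scipy.optimize import fsolve

from eegfocus.tqwt import (
    SubbandSet,
    TQWTDesignError,
    _stage_lengths,
    _stage_windows,
    decompose,
    design_params,
    load_subbands,
    max_levels,
    reconstruct,
    save_subbands,
    subband_freq,
    theta,
)


def _invert_qr_numerically(Q, r):
    """Independent oracle: solve r = beta/(1-alpha), Q = (2-beta)/beta."""

    def eqs(v):
        alpha, beta = v
        return [beta / (1.0 - alpha) - r, (2.0 - beta) / beta - Q]

    alpha, beta = fsolve(eqs, [0.8, 0.5], full_output=False)
    return alpha, beta


class TestDesignParams:
    @pytest.mark.parametrize(
        "Q,r,beta_expected,alpha_expected",
        [(3, 3, 0.5, 5.0 / 6.0), (2, 2, 2.0 / 3.0, 2.0 / 3.0)],
    )
    def test_against_numeric_inversion(self, Q, r, beta_expected, alpha_expected):
        p = design_params(Q, r, 1)
        assert p.beta == pytest.approx(beta_expected, abs=1e-12)
        assert p.alpha == pytest.approx(alpha_expected, abs=1e-12)
        alpha_o, beta_o = _invert_qr_numerically(Q, r)
        assert p.alpha == pytest.approx(alpha_o, abs=1e-9)
        assert p.beta == pytest.approx(beta_o, abs=1e-9)

    @pytest.mark.parametrize("Q,r", [(1, 1.5), (1.5, 2), (3, 3), (5, 4), (10, 5)])
    def test_roundtrip_identities(self, Q, r):
        p = design_params(Q, r, 2)
        assert (2.0 - p.beta) / p.beta == pytest.approx(Q, abs=1e-12)
        assert p.beta / (1.0 - p.alpha) == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("Q,r,J", [(0.5, 3, 1), (3, 1.0, 1), (3, 3, 0)])
    def test_invalid_parameters_rejected(self, Q, r, J):
        with pytest.raises((TQWTDesignError, ValueError)):
            design_params(Q, r, J)


class TestTheta:
    def test_endpoint_values(self):
        assert theta(0.0) == pytest.approx(1.0, abs=1e-15)
        assert theta(np.pi) == pytest.approx(0.0, abs=1e-15)
        assert theta(np.pi / 2) == pytest.approx(np.sqrt(2) / 2, abs=1e-5)

    def test_power_complementarity_dense_grid(self):
        w = np.linspace(0.0, np.pi, 10001)
        np.testing.assert_allclose(
            theta(w) ** 2 + theta(np.pi - w) ** 2, 1.0, atol=1e-12
        )

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            theta(-0.5)
        with pytest.raises(ValueError):
            theta(3.5)


class TestMaxLevels:
    def test_paper_record_length(self):
        # 20 s at 512 Hz minus one differencing sample
        assert max_levels(10239, 3, 3) == 35
        assert max_levels(10240, 3, 3) == 35

    @pytest.mark.parametrize("Q,r", [(1.5, 2), (2, 2), (3, 3), (5, 4)])
    @pytest.mark.parametrize("n", [64, 100, 1023, 4096])
    def test_iterative_oracle(self, Q, r, n):
        """Count low-pass stages until the branch is too short to filter."""
        p = design_params(Q, r, 1)
        length, j = float(n), 0
        while p.beta * p.alpha * length >= 8.0:
            length *= p.alpha
            j += 1
        assert max_levels(n, Q, r) == j

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            max_levels(8, 3, 3)


class TestFilterBank:
    def test_power_complementary_stage_windows(self):
        """|F0|^2 + |F1|^2 == 1 on the transition band of one stage."""
        for N in (64, 256, 1024):
            p = design_params(3, 3, 1)
            N0, N1 = _stage_lengths(N, p.alpha, p.beta)
            g0, g1, P = _stage_windows(N, N0, N1)
            # the high-pass window sits on input bins P..P+N1-1
            full0 = np.zeros(N)
            full1 = np.zeros(N)
            full0[: N0 // 2 + 1] = g0[: N0 // 2 + 1]
            full1[P : P + N1 // 2 + 1] = g1[: N1 // 2 + 1]
            np.testing.assert_allclose(
                full0[: N // 2 + 1] ** 2 + full1[: N // 2 + 1] ** 2,
                1.0,
                atol=1e-10,
            )

    def test_dc_signal_has_no_detail_energy(self):
        sb = decompose(np.ones(1024), design_params(3, 3, 6))
        for d in sb.details:
            assert np.max(np.abs(d)) < 1e-10
        assert np.sum(sb.approximation**2) == pytest.approx(1024.0, rel=1e-10)

    def test_near_nyquist_tone_lands_in_detail_one(self):
        n = 4096
        x = np.cos(0.98 * np.pi * np.arange(n))
        sb = decompose(x, design_params(3, 3, 5))
        total = sum(np.sum(s**2) for s in sb.subbands)
        assert np.sum(sb.details[0] ** 2) / total > 0.95


class TestPerfectReconstruction:
    @pytest.mark.parametrize("Q", [1.5, 2, 3, 5])
    @pytest.mark.parametrize("r", [2, 3, 4])
    @pytest.mark.parametrize("n", [100, 1023, 4096])
    def test_roundtrip_over_grid(self, Q, r, n, rng):
        for J in sorted({1, 3, max_levels(n, Q, r)}):
            params = design_params(Q, r, J)
            x = rng.standard_normal(n)
            y = reconstruct(decompose(x, params)).samples
            assert np.linalg.norm(y - x) / np.linalg.norm(x) < 1e-8

    def test_many_seeds_odd_length(self):
        params = design_params(3, 3, 8)
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(1023)
            y = reconstruct(decompose(x, params)).samples
            assert np.linalg.norm(y - x) / np.linalg.norm(x) < 1e-8

    def test_zero_subbands_give_zero_signal(self, rng):
        sb = decompose(rng.standard_normal(512), design_params(2, 3, 4))
        for d in sb.details:
            d[:] = 0.0
        sb.approximation[:] = 0.0
        assert np.max(np.abs(reconstruct(sb).samples)) == 0.0

    def test_zeroed_details_leave_lowpass_only(self, rng):
        n = 2048
        x = rng.standard_normal(n)
        params = design_params(3, 3, 6)
        sb = decompose(x, params)
        for d in sb.details:
            d[:] = 0.0
        y = reconstruct(sb).samples
        # spectral energy above the approximation band must be negligible
        Y = np.abs(np.fft.rfft(y)) ** 2
        edge = params.alpha**params.J * np.pi
        cut = int(np.ceil(edge / np.pi * (len(Y) - 1)))
        assert Y[2 * cut :].sum() / Y.sum() < 0.01

    def test_linearity(self, rng):
        params = design_params(3, 2, 4)
        s, t = rng.standard_normal(500), rng.standard_normal(500)
        a, b = 2.5, -1.25
        sb = decompose(a * s + b * t, params)
        sb_s = decompose(s, params)
        sb_t = decompose(t, params)
        for combined, ds, dt in zip(sb.subbands, sb_s.subbands, sb_t.subbands):
            np.testing.assert_allclose(combined, a * ds + b * dt, atol=1e-10)


class TestSubbandBookkeeping:
    @pytest.mark.parametrize("J", [1, 5, 12])
    def test_subband_count_is_j_plus_one(self, J, rng):
        sb = decompose(rng.standard_normal(4096), design_params(3, 3, J))
        assert len(sb) == J + 1
        assert len(sb.details) == J
        assert all(len(s) > 0 for s in sb.subbands)

    def test_levels_beyond_max_rejected(self, rng):
        n = 256
        jmax = max_levels(n, 3, 3)
        with pytest.raises(TQWTDesignError, match="max_levels"):
            decompose(rng.standard_normal(n), design_params(3, 3, jmax + 1))

    def test_subband_freq_q_ratio_and_ordering(self):
        params = design_params(3, 3, 10)
        fs = 512.0
        centers = []
        for j in range(1, params.J + 1):
            fc, bw = subband_freq(j, params, fs)
            assert fc / bw == pytest.approx(params.Q, abs=1e-9)
            centers.append(fc)
        fc_approx, _ = subband_freq(params.J + 1, params, fs)
        centers.append(fc_approx)
        assert all(a > b for a, b in zip(centers, centers[1:]))
        # top detail sits in the highest band [beta*fs/4, fs/2]
        fc1, _ = subband_freq(1, params, fs)
        assert params.beta * fs / 4 <= fc1 <= fs / 2
        with pytest.raises(IndexError):
            subband_freq(params.J + 2, params, fs)

    def test_save_load_roundtrip(self, tmp_path, rng):
        sb = decompose(rng.standard_normal(300), design_params(2, 2, 3), fs=256.0)
        back = load_subbands(save_subbands(sb, tmp_path / "rec.npz"))
        assert back.params == sb.params
        assert back.n_original == sb.n_original
        assert back.fs == sb.fs
        for a, b in zip(sb.subbands, back.subbands):
            np.testing.assert_array_equal(a, b)

    def test_reconstruct_rejects_inconsistent_lengths(self, rng):
        sb = decompose(rng.standard_normal(512), design_params(3, 3, 4))
        sb.details[1] = sb.details[1][:-2]
        with pytest.raises(ValueError, match="length"):
            reconstruct(sb)
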