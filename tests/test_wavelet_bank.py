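import numpy as np
import pytest

from eegstates import wavelet_bank as wb

TRANSFORMS = {
    "mdwt": (wb.mdwt_decompose, wb.mdwt_reconstruct, wb.MDWTParams()),
    "tqwt": (wb.tqwt_decompose, wb.tqwt_reconstruct, wb.TQWTParams()),
    "fawt": (wb.fawt_decompose, wb.fawt_reconstruct, wb.FAWTParams()),
}


def _rand(seed, n=3840):
    return np.random.default_rng(seed).standard_normal(n)


class TestSubbandCounts:
    def test_reference_configurations(self):
        x = _rand(0)
        assert wb.mdwt_decompose(x, wb.MDWTParams(levels=4)).n_subbands == 5
        assert wb.tqwt_decompose(x, wb.TQWTParams(B=7)).n_subbands == 8
        assert wb.fawt_decompose(x, wb.FAWTParams(B=6)).n_subbands == 7

    @pytest.mark.parametrize("levels", [1, 2, 3, 5])
    def test_mdwt_levels_plus_one(self, levels):
        assert wb.mdwt_decompose(_rand(1), wb.MDWTParams(levels=levels)).n_subbands == levels + 1

    @pytest.mark.parametrize("B", [1, 3, 9])
    def test_tqwt_levels_plus_one(self, B):
        assert wb.tqwt_decompose(_rand(1), wb.TQWTParams(B=B)).n_subbands == B + 1

    @pytest.mark.parametrize("B", [1, 4, 7])
    def test_fawt_levels_plus_one(self, B):
        assert wb.fawt_decompose(_rand(1), wb.FAWTParams(B=B)).n_subbands == B + 1


class TestPerfectReconstruction:
    @pytest.mark.parametrize("name", list(TRANSFORMS))
    def test_roundtrip_random_signals(self, name):
        dec, rec, params = TRANSFORMS[name]
        tol = 1e-6 if name == "fawt" else 1e-8
        for seed in range(10):
            x = _rand(seed)
            err = np.linalg.norm(rec(dec(x, params)) - x) / np.linalg.norm(x)
            assert err < tol

    @pytest.mark.parametrize("name", ["tqwt", "fawt"])
    def test_odd_length_padding_roundtrip(self, name):
        dec, rec, params = TRANSFORMS[name]
        x = _rand(2, 3841)
        sbs = dec(x, params)
        assert sbs.padded == 1
        out = rec(sbs)
        assert out.size == 3841
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-8

    @pytest.mark.parametrize("name", list(TRANSFORMS))
    def test_zero_in_zero_out(self, name):
        dec, rec, params = TRANSFORMS[name]
        sbs = dec(np.zeros(3840), params)
        assert all(np.allclose(b, 0) for b in sbs.subbands)
        assert np.allclose(rec(sbs), 0)

    @pytest.mark.parametrize("name", list(TRANSFORMS))
    def test_linearity_subband_wise(self, name):
        dec, _, params = TRANSFORMS[name]
        x, y = _rand(3), _rand(4)
        a, b = 2.5, -0.7
        sx, sy, sxy = dec(x, params), dec(y, params), dec(a * x + b * y, params)
        for bx, by, bxy in zip(sx.subbands, sy.subbands, sxy.subbands):
            np.testing.assert_allclose(bxy, a * bx + b * by, atol=1e-10)

    def test_tqwt_tampered_lengths_rejected(self):
        sbs = wb.tqwt_decompose(_rand(5))
        sbs.subbands[2] = sbs.subbands[2][:-2]
        with pytest.raises(ValueError, match="tampered"):
            wb.tqwt_reconstruct(sbs)

    def test_mdwt_single_subband_reconstructions_sum_to_signal(self):
        x = _rand(6)
        sbs = wb.mdwt_decompose(x)
        total = np.zeros_like(x)
        for i in range(sbs.n_subbands):
            parts = [
                b if j == i else np.zeros_like(b)
                for j, b in enumerate(sbs.subbands)
            ]
            total += wb.mdwt_reconstruct(
                wb.SubbandSet("mdwt", parts, sbs.original_length, sbs.params)
            )
        np.testing.assert_allclose(total, x, atol=1e-8)

    def test_mdwt_lowpass_projection_energy(self):
        x = _rand(7)
        sbs = wb.mdwt_decompose(x)
        for i in range(sbs.n_subbands - 1):
            sbs.subbands[i] = np.zeros_like(sbs.subbands[i])
        lp = wb.mdwt_reconstruct(sbs)
        assert np.sum(lp**2) <= np.sum(x**2)


class TestTQWTDesign:
    def test_reference_values_exact(self):
        beta, a = wb.tqwt_design(2, 5)
        assert beta == 2.0 / 3.0
        assert a == 13.0 / 15.0

    def test_q1_nonoscillatory(self):
        beta, _ = wb.tqwt_design(1, 3)
        assert beta == 1.0

    def test_roundtrip_identity_over_grid(self):
        for q in (1.0, 1.5, 2.0, 3.0, 5.0):
            for R in (3.0, 4.0, 5.0, 8.0):
                beta, a = wb.tqwt_design(q, R)
                assert (2 - beta) / beta == pytest.approx(q, rel=1e-14)
                assert beta / (1 - a) == pytest.approx(R, rel=1e-14)

    @pytest.mark.parametrize("q,R", [(0.5, 5), (2, 2.9)])
    def test_out_of_range_parameters(self, q, R):
        with pytest.raises(wb.ParameterError):
            wb.tqwt_design(q, R)


class TestFAWTDesign:
    def test_worked_example_edges(self):
        p = wb.FAWTParams(p=3, q=5, r=2, s=3, beta=2 / 3, eps=np.pi / 4)
        wp, ws, *_ = wb.fawt_design(p)
        assert ws == pytest.approx(np.pi / 5, rel=1e-14)
        assert wp == pytest.approx(((1 / 3) * np.pi + np.pi / 4) / 3, rel=1e-14)

    def test_degenerate_transition_start(self):
        p = wb.FAWTParams(beta=1.0, eps=0.0)
        wp = wb.fawt_design(p)[0]
        assert wp == pytest.approx(0.0, abs=1e-15)

    def test_default_parameters_pass_ordering(self):
        wp, ws, w0, w1, w2, w3 = wb.fawt_design(wb.FAWTParams())
        assert wp < ws and w0 <= w1 <= w2 < w3

    def test_ordering_violation_names_inequality(self):
        with pytest.raises(wb.ParameterError, match="wp < ws"):
            wb.FAWTParams(p=4, q=5, beta=0.1, eps=1.5)


class TestErrors:
    def test_mdwt_signal_too_short(self):
        with pytest.raises(wb.ParameterError, match="too short"):
            wb.mdwt_decompose(np.ones(32), wb.MDWTParams(levels=4))

    def test_tqwt_signal_too_short(self):
        with pytest.raises(wb.ParameterError):
            wb.tqwt_decompose(np.ones(16), wb.TQWTParams(B=7))

    def test_fawt_signal_too_short(self):
        with pytest.raises(wb.ParameterError, match="too short"):
            wb.fawt_decompose(np.ones(64), wb.FAWTParams(B=6))

    def test_wrong_container_rejected(self):
        sbs = wb.tqwt_decompose(_rand(0))
        with pytest.raises(ValueError, match="expected"):
            wb.mdwt_reconstruct(sbs)


class TestRhythmMap:
    def test_mdwt_reference_spans(self):
        sbs = wb.mdwt_decompose(_rand(0), wb.MDWTParams(levels=4))
        spans = wb.subband_rhythm_map(sbs, fs=128)
        expected = [(1, 32, 64), (2, 16, 32), (3, 8, 16), (4, 4, 8), (5, 0, 4)]
        assert [(b, lo, hi) for b, lo, hi in spans] == expected

    def test_fs_scaling_doubles_spans(self):
        sbs = wb.mdwt_decompose(_rand(0))
        s128 = wb.subband_rhythm_map(sbs, 128)
        s256 = wb.subband_rhythm_map(sbs, 256)
        for (b1, lo1, hi1), (b2, lo2, hi2) in zip(s128, s256):
            assert (lo2, hi2) == (2 * lo1, 2 * hi1)

    def test_tqwt_spans_shrink_geometrically(self):
        params = wb.TQWTParams(q=2, R=5, B=7)
        sbs = wb.tqwt_decompose(_rand(0), params)
        spans = wb.subband_rhythm_map(sbs, 128)
        highs = [hi for _, _, hi in spans[:-1]]
        ratios = np.diff(np.log(highs))
        np.testing.assert_allclose(np.exp(ratios), params.a, rtol=1e-12)


class TestFrequencyLocalization:
    fs = 128.0
    t = np.arange(3840) / 128.0

    def _fraction_in_band(self, sbs, f):
        spans = wb.subband_rhythm_map(sbs, self.fs)
        e = sbs.energies()
        idx = [i for i, (_, lo, hi) in enumerate(spans) if lo <= f <= hi]
        return sum(e[i] for i in idx) / e.sum()

    @pytest.mark.parametrize("f", [2.0, 6.0, 10.0, 20.0, 40.0])
    @pytest.mark.parametrize("name", ["tqwt", "fawt"])
    def test_tone_energy_concentrated(self, name, f):
        dec, _, params = TRANSFORMS[name]
        sbs = dec(np.sin(2 * np.pi * f * self.t), params)
        assert self._fraction_in_band(sbs, f) >= 0.8

    @pytest.mark.parametrize("f", [2.0, 6.0, 11.0, 22.0, 45.0])
    def test_mdwt_tone_energy_with_selective_wavelet(self, f):
        # db2's 4-tap filters leak across dyadic bands; the dyadic machinery
        # itself localises tones once the filters are selective enough
        sbs = wb.mdwt_decompose(
            np.sin(2 * np.pi * f * self.t), wb.MDWTParams(wavelet_name="db8")
        )
        assert self._fraction_in_band(sbs, f) >= 0.8

    @pytest.mark.parametrize("f", [2.0, 6.0, 11.0, 22.0, 45.0])
    def test_mdwt_db2_nominal_band_dominates(self, f):
        sbs = wb.mdwt_decompose(np.sin(2 * np.pi * f * self.t))
        spans = wb.subband_rhythm_map(sbs, self.fs)
        e = sbs.energies()
        target = [i for i, (_, lo, hi) in enumerate(spans) if lo <= f <= hi]
        assert int(np.argmax(e)) in target


class TestEnergyAdditivity:
    @pytest.mark.parametrize("name", ["tqwt", "fawt"])
    def test_tight_frame_parseval(self, name):
        dec, _, params = TRANSFORMS[name]
        x = _rand(8)
        sbs = dec(x, params)
        assert sbs.energies().sum() == pytest.approx(np.sum(x**2), rel=1e-10)

    def test_fawt_real_export_shapes(self):
        sbs = wb.fawt_decompose(_rand(9))
        for raw, real in zip(sbs.subbands[:-1], sbs.real_subbands[:-1]):
            assert np.iscomplexobj(raw)
            assert not np.iscomplexobj(real)
            np.testing.assert_allclose(real, 2 * raw.real)
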