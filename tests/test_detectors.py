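"""Unit tests of the CCA / FBCCA / MEC detectors."""

import numpy as np
import pytest
from scipy import linalg, signal

from ssvep_assess.detectors import (
    Detector,
    DegenerateSignalError,
    FilterBankSpec,
    build_reference,
    canonical_correlation,
    cca_detect,
    design_filter_bank,
    fbcca_detect,
    fbcca_score,
    mec_detect,
    mec_fit,
    mec_power,
)
from ssvep_assess.recording_io import extract_epochs
from ssvep_assess.synthetic_data import (
    SyntheticConfig,
    generate_session,
)


def cca_oracle(X, Y):
    """Independent QR/SVD canonical-correlation oracle."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Qx, _ = np.linalg.qr(Xc.T)
    Qy, _ = np.linalg.qr(Yc.T)
    return float(np.linalg.svd(Qx.T @ Qy, compute_uv=False)[0])


class TestReference:
    def test_rows_and_start_phase(self):
        t = build_reference(15.0, 4, 256.0, 512)
        assert t.Y.shape == (8, 512)
        assert t.n_harmonics == 4
        # at t = 0 every sin row is 0 and every cos row is 1
        assert np.allclose(t.Y[0::2, 0], 0.0)
        assert np.allclose(t.Y[1::2, 0], 1.0)
        # whole-period rows have norm sqrt(Nt/2)
        assert np.allclose(np.linalg.norm(t.Y[2 * 0], ),
                           np.sqrt(512 / 2), rtol=1e-2)

    def test_harmonics_dropped_at_nyquist(self):
        t = build_reference(50.0, 4, 256.0, 512)
        assert t.n_harmonics == 2  # 150/200 Hz >= 128 Hz dropped

    def test_fundamental_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_reference(130.0, 4, 256.0, 512)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_reference(15.0, 4, 256.0, 10)

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError):
            build_reference(-1.0, 4, 256.0, 512)
        with pytest.raises(ValueError):
            build_reference(15.0, 0, 256.0, 512)


class TestCanonicalCorrelation:
    def test_identical_signals_give_unit_rho(self, rng):
        X = rng.standard_normal((4, 300))
        assert canonical_correlation(X, X).rho == pytest.approx(1.0, abs=1e-6)

    def test_invertible_mixing_gives_unit_rho(self, rng):
        Y = rng.standard_normal((4, 300))
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        assert canonical_correlation(A @ Y, Y).rho == pytest.approx(1.0,
                                                                    abs=1e-6)

    def test_matches_qr_svd_oracle(self, rng):
        for _ in range(20):
            X = rng.standard_normal((2, 128))
            Y = rng.standard_normal((4, 128))
            got = canonical_correlation(X, Y).rho
            assert got == pytest.approx(cca_oracle(X, Y), abs=1e-8)

    def test_rho_bounded(self, rng):
        X = rng.standard_normal((8, 256))
        Y = rng.standard_normal((8, 256))
        r = canonical_correlation(X, Y)
        assert 0.0 <= r.rho <= 1.0 + 1e-9
        assert r.w_p.shape == (8,) and r.w_q.shape == (8,)

    def test_invariant_to_channel_offset_and_scale(self, rng):
        X = rng.standard_normal((4, 300))
        Y = rng.standard_normal((4, 300))
        base = canonical_correlation(X, Y).rho
        D = np.diag([0.5, 2.0, 7.0, 0.1])
        shifted = canonical_correlation(D @ X + np.arange(4)[:, None], Y).rho
        assert shifted == pytest.approx(base, abs=1e-7)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="same number"):
            canonical_correlation(rng.standard_normal((2, 100)),
                                  rng.standard_normal((2, 99)))

    def test_needs_more_samples_than_variables(self, rng):
        with pytest.raises(ValueError, match="samples"):
            canonical_correlation(rng.standard_normal((10, 10)),
                                  rng.standard_normal((2, 10)))

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            canonical_correlation(np.ones((2, 100)),
                                  np.zeros((2, 100)) + 3.0)


class TestCcaDetect:
    def test_noiseless_recovery_all_targets(self, stimulus):
        cfg = SyntheticConfig(seed=1, background_rms=0.0, target_snr_db=None)
        from ssvep_assess.synthetic_data import gen_evoked
        for f in stimulus.frequencies:
            X = gen_evoked(cfg, f, 2.0)
            f_hat, scores = cca_detect(X, stimulus)
            assert f_hat == f
            assert scores.shape == (5,)

    def test_tie_breaks_to_lowest_frequency(self, stimulus):
        from ssvep_assess.detectors import _argmax_lowest_freq
        idx = _argmax_lowest_freq(stimulus.frequencies, np.ones(5))
        assert stimulus.frequencies[idx] == min(stimulus.frequencies)


class TestFilterBank:
    def test_default_bank_realized_and_stable(self):
        sos_list = design_filter_bank(FilterBankSpec(), 256.0)
        assert len(sos_list) == 5
        for sos in sos_list:
            _, poles, _ = signal.sos2zpk(sos)
            assert np.all(np.abs(poles) < 1.0)

    def test_high_edge_clipped_at_low_fs(self):
        sos_list = design_filter_bank(
            FilterBankSpec(bands=((6.0, 90.0),)), 100.0)
        assert len(sos_list) == 1  # clipped to 47.5 Hz, still valid

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            design_filter_bank(FilterBankSpec(bands=((60.0, 90.0),)), 100.0)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError, match="at least one band"):
            FilterBankSpec(bands=())

    def test_weights_formula(self):
        w = FilterBankSpec().weights
        n = np.arange(1, 6)
        assert np.allclose(w, n ** -1.25 + 0.25)
        assert w[0] == pytest.approx(1.25)

    def _band_ratio(self, freq):
        sos = design_filter_bank(FilterBankSpec(), 256.0)[0]  # 6-90 Hz
        t = np.arange(4 * 256) / 256.0
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = signal.sosfiltfilt(sos, x, axis=1)
        sl = slice(256, -256)
        return np.sqrt(np.mean(y[0, sl] ** 2) / np.mean(x[0, sl] ** 2))

    def test_passband_tone_preserved(self):
        # zero-phase application doubles the 0.5-dB Chebyshev ripple, so a
        # tone at a ripple trough can lose up to ~1 dB (~11% in amplitude)
        assert self._band_ratio(30.0) > 0.88

    def test_stopband_tone_attenuated(self):
        assert 20 * np.log10(self._band_ratio(4.0)) < -15.0


class TestFbcca:
    def test_score_combination_formula(self, rng):
        X = rng.standard_normal((4, 512))
        bank = FilterBankSpec()
        s = fbcca_score(X, 15.0, bank)
        assert s.per_band.shape == (5,)
        assert s.combined == pytest.approx(
            float(np.sum(bank.weights * s.per_band ** 2)), abs=1e-12)

    def test_reduces_to_squared_cca(self, rng):
        """SB=1, unit weight, all-pass band: combined score == rho^2."""
        bank = FilterBankSpec(bands=((1.0, 120.0),), weight_b=0.0)
        assert np.allclose(bank.weights, [1.0])
        for _ in range(5):
            X = rng.standard_normal((8, 256))
            rho = canonical_correlation(
                X, build_reference(15.0, 4, 256.0, 256).Y).rho
            s = fbcca_score(X, 15.0, bank, subbands=X[None])
            assert abs(s.combined - rho ** 2) < 1e-10

    def test_detect_on_clean_harmonics(self, stimulus):
        cfg = SyntheticConfig(seed=1, background_rms=0.0, target_snr_db=None)
        from ssvep_assess.synthetic_data import gen_evoked
        for f in stimulus.frequencies:
            f_hat, _ = fbcca_detect(gen_evoked(cfg, f, 2.0), stimulus)
            assert f_hat == f


class TestMec:
    def test_eigenvalue_energy_identity(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0)
        assert m.eigvals.sum() == pytest.approx(
            np.sum(m.residual ** 2), rel=1e-10)

    def test_unit_filtered_noise_energy(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0)
        energies = np.sum((m.residual.T @ m.W) ** 2, axis=0)
        assert np.allclose(energies, 1.0, atol=1e-6)

    def test_noiseless_residual_vanishes(self):
        t = build_reference(15.0, 4, 256.0, 512)
        A = np.arange(1, 65).reshape(8, 8).astype(float)
        X = A @ t.Y
        m = mec_fit(X, 15.0)
        assert np.linalg.norm(m.residual) <= 1e-8 * np.linalg.norm(X)
        assert m.n_filters == 1  # degenerate single-filter fallback

    def test_retention_rule_keeps_smallest(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0, retention=0.10)
        kept = m.eigvals[:m.n_filters]
        assert np.all(np.diff(m.eigvals) >= -1e-9)  # ascending
        # smallest count whose cumulative sum first exceeds 10% of the total
        assert kept.sum() >= 0.10 * m.eigvals.sum()
        if m.n_filters > 1:
            assert kept[:-1].sum() < 0.10 * m.eigvals.sum()

    def test_power_quadratic_in_signal(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0)
        t = build_reference(15.0, 4, 256.0, 512)
        assert mec_power(2.0 * X, m, t) == pytest.approx(
            4.0 * mec_power(X, m, t), rel=1e-9)

    def test_noise_power_near_unity(self, rng):
        """On pure noise, the 1/sqrt(lambda) scaling makes the expected
        score dimensionless and close to 1 (see methods note)."""
        ps = []
        for _ in range(20):
            X = rng.standard_normal((8, 256))
            m = mec_fit(X, 15.0)
            ps.append(mec_power(X, m, build_reference(15.0, 4, 256.0, 256)))
        assert 1.0 / 3.0 < np.mean(ps) < 3.0

    def test_literal_mode_differs(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0)
        t = build_reference(15.0, 4, 256.0, 512)
        assert mec_power(X, m, t, literal=True) != pytest.approx(
            mec_power(X, m, t))

    def test_template_mismatch_rejected(self, rng):
        X = rng.standard_normal((8, 512))
        m = mec_fit(X, 15.0)
        with pytest.raises(ValueError, match="template"):
            mec_power(X, m, build_reference(20.0, 4, 256.0, 512))

    def test_all_zero_window_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            mec_fit(np.zeros((8, 512)), 15.0)


class TestDetectorApi:
    def test_unknown_name_rejected(self, stimulus):
        with pytest.raises(ValueError, match="unknown detector"):
            Detector(name="lda", stimulus=stimulus)

    def test_uniform_call_contract(self, stimulus, stim_epochs_0db):
        e = stim_epochs_0db[0]
        for name in ("cca", "fbcca", "mec"):
            det = Detector(name=name, stimulus=stimulus)
            f_hat, scores = det(e.X)
            assert f_hat in stimulus.frequencies
            assert scores.shape == (5,)

    def test_fbcca_caches_filters(self, stimulus):
        det = Detector(name="fbcca", stimulus=stimulus)
        assert det._sos is not None and len(det._sos) == 5

    def test_all_detectors_correct_at_0db(self, stimulus, stim_epochs_0db):
        for name in ("cca", "fbcca", "mec"):
            det = Detector(name=name, stimulus=stimulus)
            hits = sum(det(e.X)[0] == e.target_frequency
                       for e in stim_epochs_0db[:5])
            assert hits == 5

    def test_low_snr_method_ordering(self, stimulus, timing):
        """On matched low-SNR 1-s windows the harmonic-aware filter bank
        beats plain CCA, which beats MEC."""
        cfg = SyntheticConfig(seed=5, target_snr_db=-18.0)
        rec = generate_session(cfg, stimulus, timing, trials_per_frequency=8,
                               paradigms=("OOR",))["OOR"]
        epochs = extract_epochs(rec, "stimulation")
        acc = {}
        for name in ("cca", "fbcca", "mec"):
            det = Detector(name=name, stimulus=stimulus)
            acc[name] = np.mean([det(e.X[:, :256])[0] == e.target_frequency
                                 for e in epochs])
        assert acc["fbcca"] >= acc["cca"] >= acc["mec"]
        assert acc["fbcca"] > 0.5  # well above the 0.2 chance level

    def test_mec_detect_scores_positive(self, stimulus, stim_epochs_0db):
        _, scores = mec_detect(stim_epochs_0db[0].X, stimulus)
        assert np.all(scores > 0)
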