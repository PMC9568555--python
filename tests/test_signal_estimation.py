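import numpy as np
import pytest

import metfref as m
from metfref.signal_estimation import render_measurement


def _pure_tone_spec(bin_index=10, fs=25600.0, block=1024):
    f = bin_index * fs / block
    return m.ExcitationSpec(frequencies_hz=(f,), sample_rate_hz=fs,
                            block_size=block, n_averages=1)


class TestMultisine:
    def test_single_tone_spectrally_pure(self):
        spec = _pure_tone_spec(bin_index=10)
        sig = m.generate_multisine(spec, seed=0)
        mag = np.abs(np.fft.rfft(sig))
        peak = mag[10]
        others = np.delete(mag, 10)
        assert others.max() < 1e-10 * peak

    def test_audiological_tones_are_exact_bins(self, excitation_spec):
        width = excitation_spec.bin_width_hz
        assert width == 25.0
        for f in excitation_spec.frequencies_hz:
            assert f % width == 0

    def test_non_bin_frequency_rejected(self):
        with pytest.raises(ValueError, match="exact FFT bin"):
            m.ExcitationSpec(frequencies_hz=(130.0,), sample_rate_hz=25600.0,
                             block_size=1024)

    def test_seeds_change_phase_not_magnitude(self, excitation_spec):
        a = np.fft.rfft(m.generate_multisine(excitation_spec, seed=1))
        b = np.fft.rfft(m.generate_multisine(excitation_spec, seed=2))
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)
        bins = list(excitation_spec.bins)
        assert not np.allclose(np.angle(a[bins]), np.angle(b[bins]))


class TestSpectra:
    def test_pure_gain_recovered(self, excitation_spec):
        sig = m.generate_multisine(excitation_spec, seed=3)
        x = np.tile(sig, 4)
        pair = m.TimeSeriesPair(mic_v=x, ldv_v=2.0 * x,
                                sample_rate_hz=25600.0)
        sp = m.estimate_spectra(pair, 1024, 4)
        bins = list(excitation_spec.bins)
        ratio = np.abs(sp.sxy[bins]) / sp.sxx[bins]
        assert np.allclose(ratio, 2.0, atol=1e-9)

    def test_single_average_coherence_identity(self):
        rng = np.random.default_rng(0)
        pair = m.TimeSeriesPair(mic_v=rng.standard_normal(1024),
                                ldv_v=rng.standard_normal(1024),
                                sample_rate_hz=25600.0)
        sp = m.estimate_spectra(pair, 1024, 1)
        assert np.allclose(np.abs(sp.sxy) ** 2, sp.sxx * sp.syy, rtol=1e-9)
        with pytest.raises(ValueError, match="n_averages"):
            m.coherence(sp)

    def test_cauchy_schwarz_on_noise(self):
        rng = np.random.default_rng(7)
        n_avg, block = 20, 256
        pair = m.TimeSeriesPair(
            mic_v=rng.standard_normal(n_avg * block),
            ldv_v=rng.standard_normal(n_avg * block),
            sample_rate_hz=8192.0)
        sp = m.estimate_spectra(pair, block, n_avg)
        assert (np.abs(sp.sxy) ** 2 <= sp.sxx * sp.syy * (1 + 1e-9)).all()

    def test_too_short_signal_rejected(self):
        pair = m.TimeSeriesPair(mic_v=np.zeros(100), ldv_v=np.zeros(100),
                                sample_rate_hz=1000.0)
        with pytest.raises(ValueError, match="too short"):
            m.estimate_spectra(pair, 64, 2)


class TestTransferFunction:
    def test_noiseless_gain_and_calibration(self, excitation_spec):
        truth = {f: -20.0 for f in excitation_spec.frequencies_hz}
        pair = render_measurement(truth, excitation_spec,
                                  snr_db=np.inf, seed=0)
        sp = m.estimate_spectra(pair, 1024, 20)
        est = m.transfer_function(sp, excitation_spec)
        assert np.allclose(est.magnitude, 0.1, atol=1e-9)
        est2 = m.transfer_function(sp, excitation_spec, a_k=2.0, b_k=1.0)
        assert np.allclose(est2.magnitude, 0.2, atol=1e-9)

    def test_zero_input_power_rejected(self, excitation_spec):
        pair = m.TimeSeriesPair(mic_v=np.zeros(1024 * 20),
                                ldv_v=np.zeros(1024 * 20),
                                sample_rate_hz=25600.0)
        sp = m.estimate_spectra(pair, 1024, 20)
        with pytest.raises(ValueError, match="zero input power"):
            m.transfer_function(sp, excitation_spec)

    def test_h1_invariant_to_common_phase_shift(self, excitation_spec):
        truth = {f: -30.0 for f in excitation_spec.frequencies_hz}
        pair = render_measurement(truth, excitation_spec, snr_db=np.inf,
                                  seed=1)
        shift = 17  # samples applied to both channels
        rolled = m.TimeSeriesPair(mic_v=np.roll(pair.mic_v, shift),
                                  ldv_v=np.roll(pair.ldv_v, shift),
                                  sample_rate_hz=pair.sample_rate_hz)
        est_a = m.transfer_function(
            m.estimate_spectra(pair, 1024, 20), excitation_spec)
        est_b = m.transfer_function(
            m.estimate_spectra(rolled, 1024, 20), excitation_spec)
        assert np.allclose(est_a.magnitude, est_b.magnitude, rtol=1e-9)


class TestCoherence:
    def test_identity_channels(self, excitation_spec):
        sig = np.tile(m.generate_multisine(excitation_spec, seed=5), 20)
        pair = m.TimeSeriesPair(mic_v=sig, ldv_v=sig.copy(),
                                sample_rate_hz=25600.0)
        sp = m.estimate_spectra(pair, 1024, 20)
        bins = list(excitation_spec.bins)
        assert np.allclose(m.coherence(sp)[bins], 1.0, atol=1e-12)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(11)
        n_avg, block = 50, 256
        pair = m.TimeSeriesPair(
            mic_v=rng.standard_normal(n_avg * block),
            ldv_v=rng.standard_normal(n_avg * block),
            sample_rate_hz=8192.0)
        sp = m.estimate_spectra(pair, block, n_avg)
        gamma2 = m.coherence(sp)[1:-1]  # skip DC/Nyquist
        assert np.nanmean(gamma2) < 0.2

    def test_scaling_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(20 * 256)
        y = x + 0.5 * rng.standard_normal(len(x))
        base = m.coherence(m.estimate_spectra(
            m.TimeSeriesPair(x, y, 8192.0), 256, 20))
        scaled = m.coherence(m.estimate_spectra(
            m.TimeSeriesPair(3.0 * x, 0.1 * y, 8192.0), 256, 20))
        assert np.allclose(base, scaled, rtol=1e-9, equal_nan=True)

    def test_matches_analytic_snr_relation(self, excitation_spec):
        """With output noise at 0 dB SNR per bin, γ² = SNR/(1+SNR) = 0.5."""
        rng = np.random.default_rng(17)
        block, n_avg = 1024, 400
        sig = np.tile(m.generate_multisine(excitation_spec, seed=9), n_avg)
        # white noise whose per-bin power equals each tone's bin power:
        # tone amplitude 1 -> |FFT| = block/2 -> power (block/2)^2;
        # noise sigma^2 -> E|FFT|^2 = block*sigma^2
        sigma = np.sqrt((block / 2) ** 2 / block)
        noisy = sig + sigma * rng.standard_normal(len(sig))
        sp = m.estimate_spectra(
            m.TimeSeriesPair(sig, noisy, 25600.0), block, n_avg)
        gamma2 = m.coherence(sp)[list(excitation_spec.bins)]
        # per-bin sampling SD of the coherence estimate at 400 averages
        # is ~0.035; allow 3 SD per bin and 0.03 on the mean
        assert np.allclose(gamma2, 0.5, atol=0.11)
        assert gamma2.mean() == pytest.approx(0.5, abs=0.03)


class TestSnr:
    def test_peak_over_flat_floor(self):
        mags = np.ones(100)
        mags[50] = 100.0
        snr = m.snr_adjacent_bins(mags, [50])
        assert snr[0] == pytest.approx(40.0)

    def test_peak_equal_to_floor(self):
        mags = np.ones(100)
        snr = m.snr_adjacent_bins(mags, [50])
        assert snr[0] == pytest.approx(0.0)

    def test_collision_uses_next_nearest(self):
        mags = np.ones(100)
        mags[50] = 100.0
        mags[51] = 100.0  # adjacent excited bin must be skipped
        snr = m.snr_adjacent_bins(mags, [50, 51])
        assert snr[0] == pytest.approx(40.0)

    def test_simulated_snr_recovered(self, excitation_spec):
        truth = {f: -30.0 for f in excitation_spec.frequencies_hz}
        pair = render_measurement(truth, excitation_spec, snr_db=20.0,
                                  seed=21)
        sp = m.estimate_spectra(pair, 1024, 20)
        est = m.transfer_function(sp, excitation_spec)
        # flat curve: every tone sits at the configured 20 dB
        assert np.all(np.abs(est.snr_db - 20.0) <= 3.0)


class TestQualityGate:
    def _estimate(self, coh, snr, freqs=(500.0, 2000.0)):
        n = len(freqs)
        return m.TransferEstimate(
            frequencies_hz=np.array(freqs), magnitude=np.ones(n),
            coherence=np.full(n, coh), snr_db=np.full(n, snr),
            a_k=np.ones(n), b_k=np.ones(n))

    def test_dresden_strict_inequality(self):
        est = self._estimate(coh=0.8, snr=30.0)
        assert not m.quality_gate(est, "dresden").any()
        est = self._estimate(coh=0.81, snr=30.0)
        assert m.quality_gate(est, "dresden").all()

    def test_shanghai_threshold_split_at_1khz(self):
        est = self._estimate(coh=1.0, snr=15.0, freqs=(500.0, 2000.0))
        mask = m.quality_gate(est, "shanghai")
        assert mask.tolist() == [True, False]

    def test_hannover_threshold(self):
        assert m.quality_gate(self._estimate(1.0, 12.0), "hannover").sum() == 0
        assert m.quality_gate(self._estimate(1.0, 12.1), "hannover").all()

    def test_perfect_estimate_all_valid(self):
        est = self._estimate(coh=1.0, snr=60.0)
        for profile in ("dresden", "hannover", "shanghai"):
            assert m.quality_gate(est, profile).all()

    def test_unknown_profile(self):
        with pytest.raises(ValueError, match="unknown quality profile"):
            m.quality_gate(self._estimate(1.0, 60.0), "oldenburg")

    def test_masks_monotone_in_noise(self, excitation_spec):
        """Lowering the simulation SNR never turns an invalid frequency
        valid, across a seeded SNR ladder."""
        truth = {f: -30.0 for f in excitation_spec.frequencies_hz}
        prev_masks = None
        for snr in (40.0, 25.0, 14.0, 5.0):
            pair = render_measurement(truth, excitation_spec, snr_db=snr,
                                      seed=33)
            est = m.transfer_function(
                m.estimate_spectra(pair, 1024, 20), excitation_spec)
            masks = {p: m.quality_gate(est, p)
                     for p in ("dresden", "hannover", "shanghai")}
            if prev_masks is not None:
                for p in masks:
                    assert not np.any(masks[p] & ~prev_masks[p])
            prev_masks = masks


class TestEndToEnd:
    def test_curve_recovered_within_half_db(self, excitation_spec):
        """Synthetic curve -> signals at >= 30 dB SNR -> gated estimate
        reproduces the curve within 0.5 dB at every gated frequency."""
        ref = m.packaged_reference("velocity")
        truth = {f: s.mean_db for f, s in ref.stats.items()}
        pair = render_measurement(truth, excitation_spec, snr_db=30.0,
                                  seed=8)
        sp = m.estimate_spectra(pair, 1024, 20)
        est = m.transfer_function(sp, excitation_spec)
        mask = m.quality_gate(est, "dresden")
        assert mask.any()
        err = est.magnitude_db() - np.array(
            [truth[f] for f in est.frequencies_hz])
        assert np.abs(err[mask]).max() < 0.5
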