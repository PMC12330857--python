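import numpy as np
import pytest
from scipy.signal import welch
from scipy.stats import spearmanr

from vigilfc import synthetic as syn
from vigilfc.synthetic import ALERT, DROWSY, EffectSpec, ParameterError


class TestGenerateLatent:
    def test_zero_rate_stays_alert(self):
        lat = syn.generate_latent(100, 0.0, seed=0, start=ALERT)
        assert np.all(lat.states == ALERT)

    def test_deterministic(self):
        a = syn.generate_latent(500, 0.05, seed=7)
        b = syn.generate_latent(500, 0.05, seed=7)
        assert np.array_equal(a.states, b.states)

    def test_switch_count_binomial_oracle(self):
        # rate 0.05 over 3600 steps: ~Binomial(3599, 0.05)
        lat = syn.generate_latent(3600, 0.05, seed=1)
        switches = int(np.sum(np.diff(lat.states) != 0))
        n, p = 3599, 0.05
        sd = np.sqrt(n * p * (1 - p))
        assert abs(switches - n * p) < 3 * sd

    def test_length_and_values(self):
        lat = syn.generate_latent(250, 0.1, seed=2)
        assert lat.duration_s == 250 and len(lat.states) == 250
        assert set(np.unique(lat.states)) <= {ALERT, DROWSY}

    def test_asymmetric_occupancy(self):
        lat = syn.generate_latent(20000, 0.02, seed=3, rate_to_alert=0.08)
        # stationary drowsy occupancy = 0.02 / (0.02 + 0.08) = 0.2
        assert np.mean(lat.states == DROWSY) == pytest.approx(0.2, abs=0.05)

    @pytest.mark.parametrize("dur,rate", [(0, 0.1), (-5, 0.1), (100, 1.5),
                                          (100, -0.1), (100, np.nan)])
    def test_rejects_bad_params(self, dur, rate):
        with pytest.raises(ParameterError):
            syn.generate_latent(dur, rate, seed=0)


def _band_power(x, sfreq, f0, f1):
    f, p = welch(x, fs=sfreq, nperseg=int(sfreq * 2))
    sel = (f >= f0) & (f < f1)
    return p[..., sel].sum(axis=-1)


class TestGenerateEeg:
    def test_all_alert_occipital_alpha_dominant(self):
        lat = syn.generate_latent(60, 0.0, seed=0, start=ALERT)
        eeg = syn.generate_eeg(lat, seed=1)
        occ = [i for i, (_, r) in enumerate(syn.DEFAULT_MONTAGE)
               if r == "occipital"]
        alpha = _band_power(eeg[occ], 250.0, 8, 12).mean()
        theta = _band_power(eeg[occ], 250.0, 4, 8).mean()
        assert alpha > 2 * theta

    def test_all_drowsy_theta_dominant_every_channel(self):
        lat = syn.generate_latent(60, 0.0, seed=0, start=DROWSY)
        eeg = syn.generate_eeg(lat, seed=1)
        alpha = _band_power(eeg, 250.0, 8, 12)
        theta = _band_power(eeg, 250.0, 4, 8)
        assert np.all(alpha / theta < 1.0)

    def test_noise_free_spectrum_only_programmed_bands(self):
        lat = syn.generate_latent(30, 0.0, seed=0, start=ALERT)
        eeg = syn.generate_eeg(lat, snr=None, seed=1)
        inband = _band_power(eeg, 250.0, 1, 13).sum()
        outband = _band_power(eeg, 250.0, 20, 100).sum()
        assert outband < 1e-6 * inband

    def test_rejects_low_sfreq(self):
        lat = syn.generate_latent(10, 0.0, seed=0)
        with pytest.raises(ParameterError):
            syn.generate_eeg(lat, sfreq=32.0, seed=0)

    def test_requires_occipital_and_frontal(self):
        lat = syn.generate_latent(10, 0.0, seed=0)
        with pytest.raises(ParameterError):
            syn.generate_eeg(lat, channels=(("Cz", "other"),), seed=0)

    def test_deterministic(self):
        lat = syn.generate_latent(20, 0.1, seed=4)
        assert np.array_equal(syn.generate_eeg(lat, seed=9),
                              syn.generate_eeg(lat, seed=9))


class TestGenerateBold:
    def test_null_effect_no_state_difference(self):
        lat = syn.generate_latent(30000, 0.005, seed=0)
        es = EffectSpec.null(10)
        bold = syn.generate_bold(lat, 10, 1.0, es, seed=1,
                                 seed_parcels=(0,), lag_s=0.0)
        st = lat.states[np.clip(((np.arange(bold.shape[1]) + 0.5)
                                 ).astype(int), 0, lat.duration_s - 1)]
        seed_ts = bold[0]
        for p in range(1, 10):
            za = np.arctanh(np.corrcoef(seed_ts[st == 0], bold[p][st == 0])[0, 1])
            zd = np.arctanh(np.corrcoef(seed_ts[st == 1], bold[p][st == 1])[0, 1])
            assert abs(zd - za) < 0.06  # ~3 SE at this n

    def test_planted_shift_monte_carlo_oracle(self):
        # 100 replicate sessions; empirical mean Fisher-z difference on the
        # support within 3 SE of the planted 0.2
        n_parcels, n_sup = 8, 4
        es = EffectSpec.planted(n_parcels, np.arange(2, 2 + n_sup), 0.2)
        diffs = []
        for rep in range(100):
            lat = syn.generate_latent(4000, 0.0, seed=rep, start=ALERT)
            lat_d = syn.generate_latent(4000, 0.0, seed=rep, start=DROWSY)
            kw = dict(seed_parcels=(0, 1), lag_s=0.0)
            ba = syn.generate_bold(lat, n_parcels, 2.0, es, seed=rep, **kw)
            bd = syn.generate_bold(lat_d, n_parcels, 2.0, es, seed=rep + 10_000,
                                   **kw)
            for p in range(2, 2 + n_sup):
                za = np.arctanh(np.corrcoef(ba[:2].mean(0), ba[p])[0, 1])
                zd = np.arctanh(np.corrcoef(bd[:2].mean(0), bd[p])[0, 1])
                diffs.append(zd - za)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - 0.2) < 3 * se

    def test_deterministic(self):
        lat = syn.generate_latent(100, 0.01, seed=0)
        es = EffectSpec.null(5)
        a = syn.generate_bold(lat, 5, 2.0, es, seed=3, seed_parcels=(0,))
        b = syn.generate_bold(lat, 5, 2.0, es, seed=3, seed_parcels=(0,))
        assert np.array_equal(a, b)

    def test_rejects_unattainable_shift(self):
        lat = syn.generate_latent(100, 0.0, seed=0)
        es = EffectSpec.planted(5, [2], 10.0)  # pushes |r| past the seed gain
        with pytest.raises(ParameterError):
            syn.generate_bold(lat, 5, 2.0, es, seed=0, seed_parcels=(0,))

    def test_rejects_nonfinite_effect(self):
        with pytest.raises(ParameterError):
            EffectSpec(np.array([0.0, np.inf]))

    def test_volume_count_matches_duration(self):
        lat = syn.generate_latent(900, 0.0, seed=0)
        bold = syn.generate_bold(lat, 4, 2.1, EffectSpec.null(4), seed=0,
                                 seed_parcels=(0,))
        assert bold.shape == (4, int(900 / 2.1))


class TestGeneratePhysio:
    def test_no_dropout_when_zero(self):
        lat = syn.generate_latent(60, 0.0, seed=0)
        resp, _, _ = syn.generate_physio(lat, dropout_frac=0.0, seed=1)
        assert not np.any(np.isnan(resp))

    def test_dropout_fraction(self):
        lat = syn.generate_latent(600, 0.0, seed=0)
        resp, _, _ = syn.generate_physio(lat, dropout_frac=0.1, seed=1)
        assert np.isnan(resp).mean() == pytest.approx(0.1, abs=0.03)

    def test_jitter_free_train_has_constant_ibi(self):
        from vigilfc.physio import detect_beats
        lat = syn.generate_latent(120, 0.0, seed=0)
        _, pulse, _ = syn.generate_physio(lat, mean_ibi_s=1.0, seed=1,
                                          ibi_jitter_s=0.0, outlier_rate=0.0)
        beats = detect_beats(pulse, 100.0)
        assert np.allclose(beats.ibi_s, 1.0, atol=0.02)

    def test_pupil_zeros_track_drowsiness(self):
        alert = syn.generate_latent(300, 0.0, seed=0, start=ALERT)
        drowsy = syn.generate_latent(300, 0.0, seed=0, start=DROWSY)
        _, _, pa = syn.generate_physio(alert, seed=5)
        _, _, pd_ = syn.generate_physio(drowsy, seed=5)
        assert np.mean(pd_ == 0) > np.mean(pa == 0)

    def test_rejects_bad_dropout(self):
        lat = syn.generate_latent(10, 0.0, seed=0)
        with pytest.raises(ParameterError):
            syn.generate_physio(lat, dropout_frac=0.9, seed=0)


class TestStudy:
    def test_study_deterministic(self):
        cfg = syn.StudyConfig(n_subjects=2, duration_s=200)
        a = syn.generate_study(cfg, seed=9)
        b = syn.generate_study(cfg, seed=9)
        for sa, sb in zip(a.sessions, b.sessions):
            assert np.array_equal(sa.bold, sb.bold)
            assert np.array_equal(sa.eeg, sb.eeg)
            assert np.array_equal(sa.pupil, sb.pupil)

    def test_consistent_parcel_count(self, tiny_study):
        counts = {s.bold.shape[0] for s in tiny_study.sessions}
        assert counts == {tiny_study.layout.n_parcels}

    def test_effect_support_inside_gm(self, tiny_study):
        assert set(tiny_study.effect_spec.support) <= set(
            tiny_study.layout.gm_ids)

    def test_cross_signal_consistency(self):
        """Per-minute alpha/theta ratio, pupil closure and BOLD global
        coupling all track the same latent trajectory."""
        from vigilfc import staging
        cfg = syn.StudyConfig(n_subjects=1, duration_s=1800,
                              transition_rate=0.01)
        study = syn.generate_study(cfg, seed=21)
        sess = study.sessions[0]
        lat = sess.latent.states
        n_min = sess.latent.duration_s // 60
        drowsy_frac = lat[:n_min * 60].reshape(n_min, 60).mean(axis=1)

        tags = [r for _, r in sess.montage]
        frames = staging.epoch_band_powers(sess.eeg, sess.eeg_sfreq, tags)
        occ = frames.region_mask("occipital")
        at = (frames.alpha[:, occ].mean(1) / frames.theta[:, occ].mean(1))
        at_min = at[:n_min * 60].reshape(n_min, 60).mean(axis=1)

        pupil_zero = (sess.pupil == 0).astype(float)
        spm = int(60 * sess.pupil_sfreq)
        closure_min = pupil_zero[:n_min * spm].reshape(n_min, spm).mean(axis=1)

        seed_ts = sess.bold[list(study.layout.seed_ids)].mean(axis=0)
        gm = sess.bold[list(study.layout.gm_ids)]
        vpm = int(round(60 / sess.tr_s))
        coupling = []
        for m in range(n_min):
            sl = slice(m * vpm, (m + 1) * vpm)
            r = np.corrcoef(np.vstack([seed_ts[sl][None, :], gm[:, sl]]))[0, 1:]
            coupling.append(np.mean(r))
        coupling = np.asarray(coupling)

        assert spearmanr(drowsy_frac, -at_min).statistic > 0
        assert spearmanr(drowsy_frac, closure_min).statistic > 0
        assert spearmanr(drowsy_frac, coupling).statistic > 0
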