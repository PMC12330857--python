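import numpy as np
import pytest
from scipy.stats import norm, rankdata

from vigilfc import staging
from vigilfc.staging import (
    InsufficientEpochError,
    MontageError,
    StageSeries,
    StageThresholds,
    assign_epoch_states,
    classify_stage,
    epoch_band_powers,
    signed_rank_z,
    stage_series,
)


def _tone(freq, sfreq=250.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t)


class TestEpochBandPowers:
    def test_pure_alpha_tone(self):
        eeg = np.vstack([_tone(10.0), _tone(10.0)])
        frames = epoch_band_powers(eeg, 250.0, ["occipital", "frontal"])
        assert np.all(frames.alpha > 10 * frames.theta)
        assert np.all(frames.delta < 0.05 * frames.alpha)

    def test_pure_theta_tone(self):
        eeg = _tone(6.0)[None, :]
        frames = epoch_band_powers(eeg, 250.0, ["occipital"])
        assert np.all(frames.theta > 10 * frames.alpha)
        assert np.all(frames.theta > 10 * frames.delta)

    def test_white_noise_flat_spectrum_oracle(self, rng):
        # band powers proportional to bandwidths (3:4:4 Hz) for white noise
        eeg = rng.normal(size=(1, 250 * 600))
        frames = epoch_band_powers(eeg, 250.0, ["occipital"])
        d, t, a = (frames.delta.mean(), frames.theta.mean(),
                   frames.alpha.mean())
        assert t / d == pytest.approx(4.0 / 3.0, rel=0.05)
        assert a / t == pytest.approx(1.0, rel=0.05)

    def test_rejects_untagged_channel(self):
        with pytest.raises(MontageError):
            epoch_band_powers(np.zeros((1, 250)), 250.0, ["parietal"])

    def test_one_frame_per_second(self):
        frames = epoch_band_powers(np.zeros((2, 250 * 7 + 100)), 250.0,
                                   ["occipital", "frontal"])
        assert frames.n_seconds == 7


class TestClassifyStage:
    # hand application of the documented rule
    def _cls(self, alpha, theta, delta, regions=("occipital", "frontal")):
        return classify_stage(np.array(alpha), np.array(theta),
                              np.array(delta), regions)

    def test_occipital_alpha_gives_a1(self):
        assert self._cls([10.0, 1.0], [0.5, 0.5], [0.2, 0.2]) == 5

    def test_frontal_dominant_alpha_gives_a3(self):
        # alpha-dominant, occ/frontal < 2, frontal share >= 0.5 -> A3
        assert self._cls([1.0, 4.0], [0.5, 0.5], [0.2, 0.2]) == 3

    def test_balanced_alpha_gives_a2(self):
        # occ/frontal = 1.5 < 2 but frontal share 0.4 < 0.5 -> A2
        assert self._cls([3.0, 2.0], [0.5, 0.5], [0.2, 0.2]) == 4

    def test_theta_dominant_low_slow_gives_b1(self):
        # slow/alpha = 3 < 4 -> B1
        assert self._cls([1.0, 1.0], [2.0, 2.0], [1.0, 1.0]) == 2

    def test_heavy_slow_gives_b23(self):
        assert self._cls([0.5, 0.5], [3.0, 3.0], [3.0, 3.0]) == 1

    def test_stage_series_wraps_rule(self):
        eeg = np.vstack([_tone(10.0, amp=3.0), _tone(10.0, amp=0.3)])
        frames = epoch_band_powers(eeg, 250.0, ["occipital", "frontal"])
        ss = stage_series(frames)
        assert np.all(ss.stages == 5)
        assert set(ss.labels) == {"A1"}


def _exact_moment_z(values, center=2.75):
    """Brute-force oracle: moments of W+ over all 2^n sign assignments."""
    d = np.asarray(values, float) - center
    r = rankdata(np.abs(d))
    n = len(r)
    combos = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
    W = combos @ r
    w = r[d > 0].sum()
    return (w - W.mean()) / W.std(ddof=0)


def _exact_midp_z(values, center=2.75):
    """Exact mid-p enumeration z."""
    d = np.asarray(values, float) - center
    r = rankdata(np.abs(d))
    n = len(r)
    combos = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
    W = combos @ r
    w = r[d > 0].sum()
    p_lower = (W < w).mean() + 0.5 * (W == w).mean()
    return norm.ppf(p_lower)


class TestSignedRankZ:
    def test_all_max_stage_exceeds_threshold(self):
        assert signed_rank_z([5] * 63) > 1.5

    def test_all_min_stage_mirror(self):
        assert signed_rank_z([1] * 63) < -1.5

    def test_mirror_symmetry(self):
        vals = [5, 4, 3, 2, 1, 5, 4, 3, 2, 1, 4, 2]
        mirrored = [6 - v for v in vals]  # reflects around 3; center 2.75->3.25
        z1 = signed_rank_z(vals, center=2.75)
        z2 = signed_rank_z(mirrored, center=3.25)
        assert z1 == pytest.approx(-z2)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 13))
            vals = rng.integers(1, 6, n)
            z = signed_rank_z(vals)
            assert z == pytest.approx(_exact_moment_z(vals), abs=1e-10)

    def test_midp_agreement_in_label_range(self, rng):
        # exact mid-p z agrees within 0.15 where labeling is at stake
        checked = 0
        for _ in range(400):
            n = int(rng.integers(10, 13))
            vals = rng.integers(1, 6, n)
            z = signed_rank_z(vals)
            if abs(z) <= 2.0:
                assert abs(z - _exact_midp_z(vals)) <= 0.15
                checked += 1
        assert checked > 200

    def test_no_zero_differences_possible(self, rng):
        # integer stages vs fractional center: d == 0 cannot occur
        vals = rng.integers(1, 6, 1000)
        assert np.all(vals - 2.75 != 0)

    def test_too_few_values(self):
        with pytest.raises(InsufficientEpochError):
            signed_rank_z([5] * 9)


class TestAssignEpochStates:
    def test_all_alert_epochs_merge(self):
        # 19 x 30-volume stage-5 epochs -> one 570-volume alert epoch pre-shift
        stages = StageSeries(np.full(19 * 63, 5))
        eps = assign_epoch_states(stages, tr_s=2.1, shift_s=0.0,
                                  n_volumes=570)
        assert len(eps) == 1
        assert eps[0].state == "alert"
        assert (eps[0].start_volume, eps[0].end_volume) == (0, 570)

    def test_shift_is_two_volumes_at_tr_2p1(self):
        stages = StageSeries(np.full(19 * 63, 5))
        eps = assign_epoch_states(stages, tr_s=2.1, shift_s=5.0,
                                  n_volumes=570)
        assert eps[0].start_volume == 2  # round(5 / 2.1) = 2
        assert eps[0].end_volume == 570  # truncated at scan end

    def test_cyclic_stage_pattern_intermediate(self):
        # the repeating 1,4,4 pattern balances signed rank mass: |z| < 1.5
        pattern = np.tile([1, 4, 4], 21)
        z = signed_rank_z(pattern[:63])
        assert abs(z) < 1.5  # oracle on the explicit vector
        stages = StageSeries(np.tile([1, 4, 4], 19 * 21))
        eps = assign_epoch_states(stages, tr_s=2.1, shift_s=0.0,
                                  n_volumes=570)
        assert all(ep.state == "intermediate" for ep in eps)

    def test_alternating_2_3_is_drowsy_by_rank_mass(self):
        # stage 2 sits 0.75 below the 2.75 center, stage 3 only 0.25 above:
        # the negative differences dominate the rank mass
        z = signed_rank_z(np.tile([2, 3], 32)[:63])
        assert z < -1.5

    def test_trailing_partial_epoch_dropped(self):
        stages = StageSeries(np.full(200, 5))
        eps = assign_epoch_states(stages, tr_s=1.0, epoch_volumes=63,
                                  shift_s=0.0, n_volumes=200)
        # 200 // 63 = 3 epochs; 11 trailing volumes dropped
        assert eps[-1].end_volume == 189

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(3)
        block = rng.integers(1, 6, 63)
        base = np.concatenate([np.full(63, 5), block, np.full(63, 1),
                               block[::-1]])
        tiled = np.tile(base, 3)
        a = assign_epoch_states(StageSeries(tiled), tr_s=2.1, shift_s=0.0,
                                n_volumes=12 * 30)
        # shifting the stage series by one epoch shifts the labels
        shifted = np.concatenate([tiled[63:], tiled[:63]])
        b = assign_epoch_states(StageSeries(shifted), tr_s=2.1, shift_s=0.0,
                                n_volumes=12 * 30)
        labels_a = []
        for ep in a:
            labels_a += [ep.state] * ((ep.end_volume - ep.start_volume) // 30)
        labels_b = []
        for ep in b:
            labels_b += [ep.state] * ((ep.end_volume - ep.start_volume) // 30)
        assert labels_a[1:] == labels_b[:-1]

    def test_states_consistent_with_z(self):
        rng = np.random.default_rng(4)
        stages = StageSeries(rng.integers(1, 6, 19 * 63))
        for ep in assign_epoch_states(stages, tr_s=2.1, shift_s=0.0,
                                      n_volumes=570):
            if ep.state == "alert":
                assert ep.z_stat >= 1.5
            elif ep.state == "drowsy":
                assert ep.z_stat <= -1.5


class TestAlphaThetaRatio:
    def _frames(self, alpha, theta, n_sec=120):
        a = np.full((n_sec, 1), alpha, dtype=float)
        t = np.full((n_sec, 1), theta, dtype=float)
        return staging.BandPowerFrames(delta=np.zeros((n_sec, 1)), theta=t,
                                       alpha=a, regions=("occipital",))

    def _epoch(self, state="alert"):
        return [staging.StateEpoch(0, 30, state, 2.0)]

    def test_equal_powers_unity(self):
        r = staging.alpha_theta_ratio(self._frames(2.0, 2.0), self._epoch(),
                                      tr_s=2.0)
        assert r[0] == pytest.approx(1.0)

    def test_zero_alpha(self):
        r = staging.alpha_theta_ratio(self._frames(0.0, 2.0), self._epoch(),
                                      tr_s=2.0)
        assert r[0] == 0.0

    def test_zero_theta_missing(self):
        r = staging.alpha_theta_ratio(self._frames(1.0, 0.0), self._epoch(),
                                      tr_s=2.0)
        assert np.isnan(r[0])

    def test_alert_epochs_exceed_drowsy(self):
        from vigilfc import synthetic as syn
        from scipy.stats import ranksums
        lat = syn.generate_latent(1200, 0.01, seed=6)
        eeg = syn.generate_eeg(lat, seed=7)
        frames = epoch_band_powers(eeg, 250.0,
                                   [r for _, r in syn.DEFAULT_MONTAGE])
        stages = stage_series(frames)
        eps = assign_epoch_states(stages, tr_s=2.1, shift_s=0.0,
                                  n_volumes=int(1200 / 2.1))
        ratios = staging.alpha_theta_ratio(frames, eps, tr_s=2.1)
        alert = [r for r, e in zip(ratios, eps) if e.state == "alert"]
        drowsy = [r for r, e in zip(ratios, eps) if e.state == "drowsy"]
        assert alert and drowsy
        assert ranksums(alert, drowsy).statistic > 0
        assert min(alert) > max(drowsy)
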