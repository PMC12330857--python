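"""Synthetic multi-subject studies with a shared latent vigilance process.

A two-state (alert/drowsy) Markov chain at 1-s resolution drives

* EEG band powers (occipital alpha when alert, delta/theta when drowsy),
* BOLD parcel time series with a state-switched loading on a shared
  global factor (plants a known drowsy-minus-alert Fisher-z shift on a
  configurable support mask),
* a respiratory waveform with transducer-dropout (NaN) segments,
* a quasi-periodic pulse train with inter-beat-interval jitter and
  injected outlier beats,
* a pupil trace whose zero-runs (closures) preferentially cover drowsy
  time.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

ALERT = 0
DROWSY = 1

STATE_NAMES = {ALERT: "alert", DROWSY: "drowsy"}

#: default EEG montage: (channel name, region tag)
DEFAULT_MONTAGE = (
    ("O1", "occipital"),
    ("O2", "occipital"),
    ("Fz", "frontal"),
    ("Cz", "other"),
)

# per-band oscillation amplitudes by latent state
_AMP = {
    "alpha": {  # 8-12 Hz
        ALERT: {"occipital": 1.0, "frontal": 0.3, "other": 0.5},
        DROWSY: {"occipital": 0.15, "frontal": 0.1, "other": 0.1},
    },
    "theta": {  # 4-8 Hz
        ALERT: {"occipital": 0.15, "frontal": 0.15, "other": 0.15},
        DROWSY: {"occipital": 0.8, "frontal": 0.8, "other": 0.8},
    },
    "delta": {  # 1-4 Hz
        ALERT: {"occipital": 0.1, "frontal": 0.1, "other": 0.1},
        DROWSY: {"occipital": 0.8, "frontal": 0.8, "other": 0.8},
    },
}

_BAND_FREQ = {"alpha": 10.0, "theta": 5.5, "delta": 2.0}


class ParameterError(ValueError):
    """Raised when a generator parameter is out of range or non-finite."""


@dataclass(frozen=True)
class LatentVigilanceTrajectory:
    """Ground-truth alert/drowsy state sequence at 1-s resolution."""

    states: np.ndarray  # int8, 0=alert, 1=drowsy
    transition_rate: float
    duration_s: int

    def __post_init__(self):
        if len(self.states) != self.duration_s:
            raise ParameterError("states length must equal duration_s")

    @property
    def labels(self) -> list[str]:
        return [STATE_NAMES[int(s)] for s in self.states]

    def state_at(self, t_s: float) -> int:
        """State at time ``t_s`` (clipped to the trajectory span)."""
        idx = min(max(int(math.floor(t_s)), 0), self.duration_s - 1)
        return int(self.states[idx])


@dataclass(frozen=True)
class EffectSpec:
    """Planted drowsy-minus-alert correlation shift per target (z units)."""

    delta_z: np.ndarray  # one entry per parcel; nonzero defines the support

    def __post_init__(self):
        dz = np.asarray(self.delta_z, dtype=float)
        if not np.all(np.isfinite(dz)):
            raise ParameterError("effect_spec z-shifts must be finite")
        object.__setattr__(self, "delta_z", dz)

    @property
    def support(self) -> np.ndarray:
        """Indices of parcels carrying a nonzero planted shift."""
        return np.flatnonzero(self.delta_z != 0.0)

    @classmethod
    def null(cls, n_parcels: int) -> "EffectSpec":
        return cls(np.zeros(n_parcels))

    @classmethod
    def planted(cls, n_parcels: int, support: np.ndarray, delta_z: float) -> "EffectSpec":
        dz = np.zeros(n_parcels)
        dz[np.asarray(support, dtype=int)] = delta_z
        return cls(dz)


@dataclass(frozen=True)
class ParcelLayout:
    """Role assignment of parcel indices in a synthetic session."""

    seed_ids: tuple[int, ...]
    gm_ids: tuple[int, ...]
    wm_ids: tuple[int, ...] = ()
    csf_ids: tuple[int, ...] = ()
    fv_ids: tuple[int, ...] = ()

    @property
    def n_parcels(self) -> int:
        return len(self.seed_ids) + len(self.gm_ids) + len(self.wm_ids) \
            + len(self.csf_ids) + len(self.fv_ids)

    @classmethod
    def default(cls, n_seed=6, n_gm=60, n_wm=6, n_csf=4, n_fv=2) -> "ParcelLayout":
        """Seed parcels first, then GM targets, then tissue parcels."""
        idx = np.arange(n_seed + n_gm + n_wm + n_csf + n_fv)
        parts, k = [], 0
        for n in (n_seed, n_gm, n_wm, n_csf, n_fv):
            parts.append(tuple(int(i) for i in idx[k:k + n]))
            k += n
        return cls(*parts)


@dataclass
class SessionRecord:
    subject_id: str
    session_id: str
    latent: LatentVigilanceTrajectory
    eeg: np.ndarray            # channels x samples
    eeg_sfreq: float
    montage: tuple[tuple[str, str], ...]
    bold: np.ndarray           # parcels x volumes
    tr_s: float
    resp: np.ndarray           # NaN marks transducer dropout
    resp_sfreq: float
    pulse: np.ndarray
    pulse_sfreq: float
    pupil: np.ndarray          # zeros mark eye closure
    pupil_sfreq: float

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[1]


@dataclass
class SyntheticStudy:
    subjects: list[SessionRecord]
    effect_spec: EffectSpec
    layout: ParcelLayout
    rng_seed: int

    @property
    def sessions(self) -> list[SessionRecord]:
        return self.subjects


@dataclass(frozen=True)
class StudyConfig:
    """Defaults for the end-to-end synthetic study."""

    n_subjects: int = 20
    sessions_per_subject: int = 1
    duration_s: int = 900
    tr_s: float = 2.1
    transition_rate: float = 0.001
    n_gm: int = 60
    n_support: int = 24
    delta_z: float = 0.2
    seed_loading: float = 2.0
    base_loading: float = 0.15
    eeg_sfreq: float = 250.0
    eeg_snr: float = 5.0
    resp_sfreq: float = 100.0
    pulse_sfreq: float = 100.0
    pupil_sfreq: float = 60.0
    dropout_frac: float = 0.05
    mean_ibi_s: float = 1.0
    bold_lag_s: float = 5.0


def _check_param(name: str, value: float, low: float, high: float,
                 inclusive_low: bool = False) -> None:
    ok = np.isfinite(value) and (value >= low if inclusive_low else value > low) \
        and value < high
    if not ok:
        raise ParameterError(f"{name}={value!r} out of range")


def generate_latent(duration_s: int, transition_rate: float, seed,
                    rate_to_alert: float | None = None,
                    start: int | None = None) -> LatentVigilanceTrajectory:
    """Simulate the two-state vigilance Markov chain at 1-s steps.

    ``transition_rate`` is the per-second switch probability out of the
    alert state; ``rate_to_alert`` (defaults to the same value) the rate
    out of drowsy, allowing asymmetric stationary occupancy.  ``start``
    fixes the initial state; by default it is drawn from the stationary
    distribution.
    """
    if not (np.isfinite(duration_s) and duration_s > 0):
        raise ParameterError("duration_s must be positive")
    duration_s = int(duration_s)
    if not np.isfinite(transition_rate) or not 0 <= transition_rate < 1:
        raise ParameterError("transition_rate must lie in [0, 1)")
    p_ad = float(transition_rate)
    p_da = p_ad if rate_to_alert is None else float(rate_to_alert)
    if not np.isfinite(p_da) or not 0 <= p_da < 1:
        raise ParameterError("rate_to_alert must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    states = np.empty(duration_s, dtype=np.int8)
    if start is None:
        total = p_ad + p_da
        p_drowsy = 0.5 if total == 0 else p_ad / total
        state = DROWSY if rng.random() < p_drowsy else ALERT
    else:
        state = int(start)
        if state not in (ALERT, DROWSY):
            raise ParameterError("start must be ALERT (0) or DROWSY (1)")
    u = rng.random(duration_s)
    for t in range(duration_s):
        states[t] = state
        p_switch = p_ad if state == ALERT else p_da
        if u[t] < p_switch:
            state = 1 - state
    return LatentVigilanceTrajectory(states=states, transition_rate=p_ad,
                                     duration_s=duration_s)


def generate_eeg(latent: LatentVigilanceTrajectory,
                 channels=DEFAULT_MONTAGE, sfreq: float = 250.0,
                 snr: float | None = 5.0, seed=None) -> np.ndarray:
    """Synthesize multichannel EEG driven by the latent state.

    Alert seconds carry occipital-dominant alpha (10 Hz); drowsy seconds
    carry elevated delta/theta with suppressed alpha.  Broadband white
    noise is added so that the RMS of the strongest programmed band over
    the noise RMS equals ``snr``; ``snr=None`` disables noise.
    """
    if sfreq < 64:
        raise ParameterError("sfreq must be >= 64 Hz for band estimation")
    regions = [r for _, r in channels]
    if "occipital" not in regions or "frontal" not in regions:
        raise ParameterError("montage needs >= 1 occipital and 1 frontal channel")

    rng = np.random.default_rng(seed)
    n_sec = latent.duration_s
    n_samp = int(round(n_sec * sfreq))
    t = np.arange(n_samp) / sfreq
    sec_idx = np.minimum(t.astype(int), n_sec - 1)
    states = latent.states[sec_idx]  # per-sample state

    out = np.zeros((len(channels), n_samp))
    for ci, (_, region) in enumerate(channels):
        for band, freq in _BAND_FREQ.items():
            amp = np.where(states == ALERT,
                           _AMP[band][ALERT][region],
                           _AMP[band][DROWSY][region])
            phase = rng.uniform(0, 2 * np.pi)
            out[ci] += amp * np.sin(2 * np.pi * freq * t + phase)
    if snr is not None:
        if not np.isfinite(snr) or snr <= 0:
            raise ParameterError("snr must be positive or None")
        ref_rms = 1.0 / math.sqrt(2.0)  # RMS of the unit-amplitude alpha
        out += rng.normal(0.0, ref_rms / snr, size=out.shape)
    return out


def _solve_loading(r: float, kappa: float) -> float:
    """Loading b with corr(seed_mean, b*g + e) = r, given seed gain kappa."""
    q = r / kappa
    if not -1.0 < q < 1.0:
        raise ParameterError(
            f"requested correlation {r:.4f} unattainable (|r| must be < {kappa:.4f})")
    return q / math.sqrt(1.0 - q * q)


def generate_bold(latent: LatentVigilanceTrajectory, n_parcels: int,
                  tr_s: float, effect_spec: EffectSpec, seed,
                  seed_parcels=(0, 1), seed_loading: float = 1.2,
                  base_loading: float = 0.6,
                  nuisance_parcels=(), nuisance_loading: float = 0.6,
                  lag_s: float = 5.0) -> np.ndarray:
    """Parcel-by-volume BOLD with a state-switched shared global factor.

    Every parcel is ``loading * g_k + noise`` with unit-variance factor
    and noise.  Seed parcels keep a fixed loading; target loadings are
    solved so the correlation between the extracted seed mean and each
    target equals its alert-state baseline, shifted by the planted
    Fisher-z ``effect_spec.delta_z`` during drowsy volumes.  A fixed
    hemodynamic lag delays the state switch by ``lag_s`` seconds.

    ``nuisance_parcels`` (e.g. WM/CSF/FV stand-ins) load on a separate
    shared nuisance factor instead of the neural global factor, so that
    regressing them out does not remove the planted effect.
    """
    _check_param("tr_s", tr_s, 0.0, np.inf)
    if len(effect_spec.delta_z) != n_parcels:
        raise ParameterError("effect_spec length must equal n_parcels")
    seed_parcels = tuple(int(i) for i in seed_parcels)
    m = len(seed_parcels)
    if m == 0:
        raise ParameterError("need at least one seed parcel")

    n_vol = int(math.floor(latent.duration_s / tr_s))
    rng = np.random.default_rng(seed)

    # seed-mean gain against the shared factor (noise variance 1/m)
    kappa = seed_loading / math.sqrt(seed_loading ** 2 + 1.0 / m)
    b0 = base_loading
    r0 = kappa * b0 / math.sqrt(b0 ** 2 + 1.0)
    z0 = math.atanh(r0)

    nuisance_parcels = tuple(int(i) for i in nuisance_parcels)
    load = np.empty((2, n_parcels))
    nload = np.zeros(n_parcels)
    for p in range(n_parcels):
        if p in seed_parcels:
            load[:, p] = seed_loading
            if effect_spec.delta_z[p] != 0.0:
                raise ParameterError("cannot plant an effect on a seed parcel")
            continue
        if p in nuisance_parcels:
            if effect_spec.delta_z[p] != 0.0:
                raise ParameterError("cannot plant an effect on a nuisance parcel")
            load[:, p] = 0.0
            nload[p] = nuisance_loading
            continue
        load[ALERT, p] = b0
        dz = effect_spec.delta_z[p]
        if dz == 0.0:
            load[DROWSY, p] = b0
        else:
            r1 = math.tanh(z0 + dz)
            if not -1.0 < r1 < 1.0:
                raise ParameterError("requested correlation outside (-1, 1)")
            load[DROWSY, p] = _solve_loading(r1, kappa)

    mids = (np.arange(n_vol) + 0.5) * tr_s
    state_idx = np.clip(np.floor(mids - lag_s).astype(int), 0,
                        latent.duration_s - 1)
    vol_states = latent.states[state_idx].astype(int)

    g = rng.normal(size=n_vol)
    g_nuis = rng.normal(size=n_vol)
    noise = rng.normal(size=(n_parcels, n_vol))
    return (load[vol_states, :].T * g[None, :]
            + nload[:, None] * g_nuis[None, :] + noise)


def _dropout_mask(n: int, frac: float, seg_len: int, rng) -> np.ndarray:
    """Boolean mask with contiguous True segments covering ~frac of n."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(frac * n))
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        length = min(seg_len, target - int(mask.sum()) + seg_len // 2)
        start = int(rng.integers(0, max(n - length, 1)))
        mask[start:start + length] = True
    return mask


def generate_physio(latent: LatentVigilanceTrajectory,
                    resp_rate_hz: float = 0.25, mean_ibi_s: float = 1.0,
                    dropout_frac: float = 0.05, seed=None,
                    resp_sfreq: float = 100.0, pulse_sfreq: float = 100.0,
                    pupil_sfreq: float = 60.0, ibi_jitter_s: float = 0.04,
                    outlier_rate: float = 0.01,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Respiratory, pulse, and pupil waveforms tied to the latent state.

    Respiration is a state-amplitude-modulated sinusoid with contiguous
    NaN dropout segments covering ``dropout_frac`` of the samples.  The
    pulse is a train of Gaussian systolic bumps with IBI jitter and a
    small rate of injected long-IBI outlier beats.  The pupil trace is
    zero during blinks and closures; closure episodes are far more
    frequent during drowsy seconds.
    """
    if not np.isfinite(dropout_frac) or not 0 <= dropout_frac < 0.5:
        raise ParameterError("dropout_frac must lie in [0, 0.5)")
    _check_param("mean_ibi_s", mean_ibi_s, 0.0, np.inf)
    _check_param("resp_rate_hz", resp_rate_hz, 0.0, np.inf)
    rng = np.random.default_rng(seed)
    dur = latent.duration_s

    # --- respiration ---
    n_r = int(round(dur * resp_sfreq))
    t_r = np.arange(n_r) / resp_sfreq
    sec = np.minimum(t_r.astype(int), dur - 1)
    amp = np.where(latent.states[sec] == ALERT, 1.0, 1.4)
    resp = amp * np.sin(2 * np.pi * resp_rate_hz * t_r)
    resp = resp + rng.normal(0, 0.05, n_r)
    if dropout_frac > 0:
        seg = int(round(8.0 * resp_sfreq))
        resp[_dropout_mask(n_r, dropout_frac, seg, rng)] = np.nan

    # --- pulse ---
    beats = [0.5 * mean_ibi_s]
    while beats[-1] < dur:
        ibi = mean_ibi_s + (ibi_jitter_s * rng.normal() if ibi_jitter_s > 0 else 0.0)
        ibi = max(ibi, 0.3 * mean_ibi_s)
        if outlier_rate > 0 and rng.random() < outlier_rate:
            ibi *= 2.5
        beats.append(beats[-1] + ibi)
    beat_times = np.array(beats[:-1])
    n_p = int(round(dur * pulse_sfreq))
    t_p = np.arange(n_p) / pulse_sfreq
    pulse = np.zeros(n_p)
    width = 0.05
    for bt in beat_times:
        lo = max(int((bt - 4 * width) * pulse_sfreq), 0)
        hi = min(int((bt + 4 * width) * pulse_sfreq) + 1, n_p)
        pulse[lo:hi] += np.exp(-0.5 * ((t_p[lo:hi] - bt) / width) ** 2)

    # --- pupil ---
    n_e = int(round(dur * pupil_sfreq))
    t_e = np.arange(n_e) / pupil_sfreq
    pupil = 4.0 + 0.2 * rng.normal(size=n_e)
    closed = np.zeros(n_e, dtype=bool)
    for s in range(dur):
        drowsy = latent.states[s] == DROWSY
        # blinks in both states; prolonged closures mostly when drowsy
        if rng.random() < 0.2:
            start = s + rng.uniform(0, 0.7)
            closed[(t_e >= start) & (t_e < start + 0.3)] = True
        p_close = 0.08 if drowsy else 0.002
        if rng.random() < p_close:
            start = s + rng.uniform(0, 0.5)
            length = rng.uniform(2.0, 8.0)
            closed[(t_e >= start) & (t_e < start + length)] = True
    pupil[closed] = 0.0
    return resp, pulse, pupil


def generate_session(cfg: StudyConfig, layout: ParcelLayout,
                     effect_spec: EffectSpec, subject_id: str,
                     session_id: str, seed) -> SessionRecord:
    """One subject-session with all signals tied to a fresh latent chain."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_lat, s_eeg, s_bold, s_phys = ss.spawn(4)
    latent = generate_latent(cfg.duration_s, cfg.transition_rate, s_lat)
    eeg = generate_eeg(latent, DEFAULT_MONTAGE, cfg.eeg_sfreq, cfg.eeg_snr, s_eeg)
    nuisance = layout.wm_ids + layout.csf_ids + layout.fv_ids
    bold = generate_bold(latent, layout.n_parcels, cfg.tr_s, effect_spec,
                         s_bold, seed_parcels=layout.seed_ids,
                         seed_loading=cfg.seed_loading,
                         base_loading=cfg.base_loading,
                         nuisance_parcels=nuisance, lag_s=cfg.bold_lag_s)
    resp, pulse, pupil = generate_physio(
        latent, mean_ibi_s=cfg.mean_ibi_s, dropout_frac=cfg.dropout_frac,
        seed=s_phys, resp_sfreq=cfg.resp_sfreq, pulse_sfreq=cfg.pulse_sfreq,
        pupil_sfreq=cfg.pupil_sfreq)
    return SessionRecord(
        subject_id=subject_id, session_id=session_id, latent=latent,
        eeg=eeg, eeg_sfreq=cfg.eeg_sfreq, montage=DEFAULT_MONTAGE,
        bold=bold, tr_s=cfg.tr_s, resp=resp, resp_sfreq=cfg.resp_sfreq,
        pulse=pulse, pulse_sfreq=cfg.pulse_sfreq,
        pupil=pupil, pupil_sfreq=cfg.pupil_sfreq)


def generate_study(cfg: StudyConfig | None = None, seed: int = 0,
                   layout: ParcelLayout | None = None,
                   effect_spec: EffectSpec | None = None) -> SyntheticStudy:
    """Multi-subject study with the default planted drowsy > alert effect.

    The default effect spec plants ``cfg.delta_z`` on the first
    ``cfg.n_support`` gray-matter targets.
    """
    cfg = cfg or StudyConfig()
    layout = layout or ParcelLayout.default(n_gm=cfg.n_gm)
    if effect_spec is None:
        support = np.asarray(layout.gm_ids[:cfg.n_support])
        effect_spec = EffectSpec.planted(layout.n_parcels, support, cfg.delta_z)
    root = np.random.SeedSequence(seed)
    per_session = root.spawn(cfg.n_subjects * cfg.sessions_per_subject)
    sessions = []
    k = 0
    for i in range(cfg.n_subjects):
        for j in range(cfg.sessions_per_subject):
            sessions.append(generate_session(
                cfg, layout, effect_spec,
                subject_id=f"sub-{i + 1:03d}", session_id=f"ses-{j + 1:02d}",
                seed=per_session[k]))
            k += 1
    return SyntheticStudy(subjects=sessions, effect_spec=effect_spec,
                          layout=layout, rng_seed=seed)
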