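"""Per-second EEG vigilance staging and epoch-level state assignment.

A documented band-power rule assigns each 1-s EEG epoch one of five
ordered stages (5 = most alert ... 1 = most drowsy).  Scan-level
alert/intermediate/drowsy epochs are then derived by testing each
30-volume block of stage integers against a center value of 2.75 with a
one-sample Wilcoxon signed-rank z, thresholding at +/-1.5, concatenating
same-state neighbors, and shifting the result forward to account for
hemodynamic delay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: stage label per integer; 5 is most alert, 1 most drowsy
STAGE_LABELS = {5: "A1", 4: "A2", 3: "A3", 2: "B1", 1: "B2/3"}

BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0)}


class MontageError(ValueError):
    pass


class InsufficientEpochError(ValueError):
    """Raised when too few values exist for the signed-rank z."""


@dataclass
class BandPowerFrames:
    """Per-second, per-channel band powers with channel region tags."""

    delta: np.ndarray   # (n_seconds, n_channels)
    theta: np.ndarray
    alpha: np.ndarray
    regions: tuple[str, ...]

    @property
    def n_seconds(self) -> int:
        return self.delta.shape[0]

    def region_mask(self, region: str) -> np.ndarray:
        return np.array([r == region for r in self.regions])


@dataclass
class StageSeries:
    stages: np.ndarray  # int, one per second, values in 1..5
    sfreq_out: float = 1.0

    def __post_init__(self):
        s = np.asarray(self.stages, dtype=int)
        if s.size and (s.min() < 1 or s.max() > 5):
            raise ValueError("stages must lie in 1..5")
        self.stages = s

    @property
    def labels(self) -> list[str]:
        return [STAGE_LABELS[int(v)] for v in self.stages]


@dataclass
class StateEpoch:
    """Half-open volume range on the BOLD clock with a vigilance state."""

    start_volume: int
    end_volume: int
    state: str          # alert | intermediate | drowsy
    z_stat: float

    @property
    def n_volumes(self) -> int:
        return self.end_volume - self.start_volume


@dataclass(frozen=True)
class StageThresholds:
    """Knobs of the band-power staging rule (documented defaults)."""

    alpha_dominance: float = 1.0   # alpha > dominance * (delta+theta)
    occ_frontal_ratio: float = 2.0  # A1 requires occ/frontal alpha >= this
    anterior_frac: float = 0.5      # frontal alpha share >= this -> A3
    slow_ratio: float = 4.0         # (delta+theta)/alpha >= this -> B2/3


def epoch_band_powers(eeg: np.ndarray, sfreq: float,
                      montage_tags) -> BandPowerFrames:
    """Integrate the periodogram of each 1-s EEG epoch over the
    delta/theta/alpha bands, per channel."""
    if sfreq < 64:
        raise MontageError("sfreq must be >= 64 Hz")
    tags = tuple(montage_tags)
    for tag in tags:
        if tag not in ("occipital", "frontal", "other"):
            raise MontageError(f"channel without valid region tag: {tag!r}")
    if "occipital" not in tags:
        raise MontageError("montage needs at least one occipital channel")
    eeg = np.asarray(eeg, dtype=float)
    n_ch, n_samp = eeg.shape
    if n_ch != len(tags):
        raise MontageError("one region tag required per channel")
    spw = int(round(sfreq))  # samples per 1-s window
    n_sec = n_samp // spw
    x = eeg[:, :n_sec * spw].reshape(n_ch, n_sec, spw)
    freqs, psd = periodogram(x, fs=sfreq, axis=-1)
    df = freqs[1] - freqs[0]
    out = {}
    for band, (f0, f1) in BANDS.items():
        sel = (freqs >= f0) & (freqs < f1)
        out[band] = psd[:, :, sel].sum(axis=-1).T * df  # (n_sec, n_ch)
    return BandPowerFrames(delta=out["delta"], theta=out["theta"],
                           alpha=out["alpha"], regions=tags)


def classify_stage(alpha: np.ndarray, theta: np.ndarray, delta: np.ndarray,
                   regions, thresholds: StageThresholds | None = None) -> int:
    """Stage one 1-s frame of per-channel band powers.

    Rule: alpha-dominant frames are A-stages, split by the
    occipital/frontal alpha ratio (A1 posterior-dominant, A2/A3 by
    anteriorization); non-alpha-dominant frames are B-stages, split by
    the slow-over-alpha power ratio.
    """
    th = thresholds or StageThresholds()
    regions = tuple(regions)
    occ = np.array([r == "occipital" for r in regions])
    fro = np.array([r == "frontal" for r in regions])
    tiny = np.finfo(float).tiny
    alpha_tot = float(np.mean(alpha))
    slow_tot = float(np.mean(theta) + np.mean(delta))
    occ_alpha = float(np.mean(alpha[occ])) if occ.any() else 0.0
    fro_alpha = float(np.mean(alpha[fro])) if fro.any() else 0.0
    if alpha_tot > th.alpha_dominance * slow_tot:
        if occ_alpha / max(fro_alpha, tiny) >= th.occ_frontal_ratio:
            return 5  # A1
        anterior = fro_alpha / max(fro_alpha + occ_alpha, tiny)
        return 3 if anterior >= th.anterior_frac else 4  # A3 / A2
    if slow_tot / max(alpha_tot, tiny) >= th.slow_ratio:
        return 1  # B2/3
    return 2      # B1


def stage_series(frames: BandPowerFrames,
                 thresholds: StageThresholds | None = None) -> StageSeries:
    """Apply :func:`classify_stage` to every 1-s frame."""
    stages = np.array([
        classify_stage(frames.alpha[s], frames.theta[s], frames.delta[s],
                       frames.regions, thresholds)
        for s in range(frames.n_seconds)
    ])
    return StageSeries(stages=stages)


def signed_rank_z(values, center: float = 2.75) -> float:
    """Signed z of the one-sample Wilcoxon signed-rank test vs ``center``.

    Tie-corrected normal approximation without continuity correction:
    with average ranks r_i of |value - center|,
    z = (W+ - sum(r)/2) / sqrt(sum(r^2)/4).  Positive z means the
    median lies above the center (more alert).  Zero differences cannot
    occur for integer stages against a fractional center.
    """
    d = np.asarray(values, dtype=float) - center
    n = d.size
    if n < 10:
        raise InsufficientEpochError(
            f"signed-rank z needs >= 10 values, got {n}")
    if np.any(d == 0):
        raise ValueError("zero differences unsupported (fractional center)")
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    sigma = math.sqrt(np.sum(ranks ** 2) / 4.0)
    return float((w_plus - mu) / sigma)


def assign_epoch_states(stages: StageSeries, tr_s: float,
                        epoch_volumes: int = 30, z_thresh: float = 1.5,
                        shift_s: float = 5.0,
                        n_volumes: int | None = None) -> list[StateEpoch]:
    """Segment the stage series into fixed-length epochs, label each by
    its signed-rank z (alert >= +thresh, drowsy <= -thresh, else
    intermediate), concatenate same-state neighbors, and shift all
    boundaries forward by ``round(shift_s / tr_s)`` volumes.

    The epoch grid is anchored at volume 0; a trailing partial epoch is
    dropped.  A merged epoch's ``z_stat`` is recomputed over its pooled
    stage values.
    """
    sec = stages.stages
    if n_volumes is None:
        n_volumes = int(math.floor(len(sec) / tr_s))
    n_epochs = n_volumes // epoch_volumes
    if n_volumes % epoch_volumes:
        logger.info("dropping trailing partial epoch of %d volumes",
                    n_volumes % epoch_volumes)
    if n_epochs == 0:
        return []

    def epoch_seconds(v0: int, v1: int) -> np.ndarray:
        s0 = int(math.floor(v0 * tr_s))
        s1 = min(int(math.floor(v1 * tr_s)), len(sec))
        return sec[s0:s1]

    raw = []
    for e in range(n_epochs):
        v0, v1 = e * epoch_volumes, (e + 1) * epoch_volumes
        z = signed_rank_z(epoch_seconds(v0, v1))
        if z >= z_thresh:
            state = "alert"
        elif z <= -z_thresh:
            state = "drowsy"
        else:
            state = "intermediate"
        raw.append(StateEpoch(v0, v1, state, z))

    merged: list[StateEpoch] = []
    for ep in raw:
        if merged and merged[-1].state == ep.state:
            prev = merged[-1]
            z = signed_rank_z(epoch_seconds(prev.start_volume, ep.end_volume))
            merged[-1] = StateEpoch(prev.start_volume, ep.end_volume,
                                    prev.state, z)
        else:
            merged.append(ep)

    shift = int(round(shift_s / tr_s))
    shifted = []
    for ep in merged:
        v0 = ep.start_volume + shift
        v1 = min(ep.end_volume + shift, n_volumes)
        if v0 >= n_volumes or v1 <= v0:
            continue
        shifted.append(StateEpoch(v0, v1, ep.state, ep.z_stat))
    return shifted


def alpha_theta_ratio(frames: BandPowerFrames, epochs: list[StateEpoch],
                      tr_s: float) -> list[float]:
    """Per-epoch occipital alpha/theta power ratio (validation metric).

    NaN when the epoch's mean theta power is zero.
    """
    occ = frames.region_mask("occipital")
    out = []
    for ep in epochs:
        s0 = int(math.floor(ep.start_volume * tr_s))
        s1 = min(int(math.floor(ep.end_volume * tr_s)), frames.n_seconds)
        a = float(frames.alpha[s0:s1][:, occ].mean())
        t = float(frames.theta[s0:s1][:, occ].mean())
        out.append(a / t if t > 0 else float("nan"))
    return out
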