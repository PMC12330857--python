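"""TR-locked physiological features: respiratory volume, heart rate,
and per-window percent eye closure.

Respiratory volume (RV) is the standard deviation of the belt waveform
in sliding windows centered at each BOLD volume; windows with too many
missing samples yield missing output.  Heart rate (HR) is the inverse
of the median inter-beat interval (IBI) in the same windows, after
single-pass outlier interpolation of the IBI series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks


class UnusableRecordingError(RuntimeError):
    """Raised when a waveform contains no usable beats/IBIs."""


@dataclass
class PhysioSeries:
    """One value per BOLD volume; NaN marks missing windows."""

    values: np.ndarray
    kind: str           # "RV" or "HR"
    tr_s: float
    units: str

    def __len__(self):
        return len(self.values)


@dataclass
class BeatSequence:
    beat_times_s: np.ndarray     # strictly increasing
    ibi_s: np.ndarray            # len == len(beat_times_s) - 1
    outlier_flags: np.ndarray    # bool per IBI

    def __post_init__(self):
        if len(self.ibi_s) != len(self.beat_times_s) - 1:
            raise ValueError("need exactly one IBI per adjacent beat pair")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")


def _window_bounds(n_volumes: int, tr_s: float, window_s: float):
    mids = (np.arange(n_volumes) + 0.5) * tr_s
    return mids - window_s / 2.0, mids + window_s / 2.0


def compute_rv(resp: np.ndarray, resp_sfreq: float, tr_s: float,
               n_volumes: int, window_s: float = 6.0,
               max_missing_frac: float = 0.2) -> PhysioSeries:
    """Sliding-window respiratory volume matched to the BOLD sampling.

    Per volume: sample standard deviation of the waveform in a
    ``window_s`` window centered at the volume midpoint, using the
    available (non-missing) samples.  The output is missing when the
    in-window missing fraction reaches ``max_missing_frac``.  Edge
    windows are truncated to the recorded span.
    """
    resp = np.asarray(resp, dtype=float)
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if resp.size == 0:
        raise ValueError("empty respiratory waveform")
    t = np.arange(resp.size) / resp_sfreq
    lo, hi = _window_bounds(n_volumes, tr_s, window_s)
    out = np.full(n_volumes, np.nan)
    for k in range(n_volumes):
        i0 = int(np.searchsorted(t, lo[k], side="left"))
        i1 = int(np.searchsorted(t, hi[k], side="left"))
        chunk = resp[i0:i1]
        if chunk.size == 0:
            continue
        missing = np.isnan(chunk)
        if missing.mean() >= max_missing_frac:
            continue
        avail = chunk[~missing]
        out[k] = np.std(avail, ddof=1) if avail.size > 1 else 0.0
    return PhysioSeries(values=out, kind="RV", tr_s=tr_s, units="a.u.")


def detect_beats(pulse: np.ndarray, sfreq: float,
                 min_ibi_s: float = 0.3) -> BeatSequence:
    """Locate heart beats as prominent local maxima of the pulse wave.

    The prominence threshold adapts to the recording: half the spread
    between the 98th percentile and the median.  Peaks closer than
    ``min_ibi_s`` are suppressed (refractory spacing).
    """
    pulse = np.asarray(pulse, dtype=float)
    if not np.all(np.isfinite(pulse)):
        raise ValueError("pulse waveform must be finite")
    if min_ibi_s <= 0:
        raise ValueError("min_ibi_s must be positive")
    prominence = 0.5 * (np.percentile(pulse, 98) - np.median(pulse))
    if prominence <= 0:
        raise UnusableRecordingError("no pulse amplitude above baseline")
    peaks, _ = find_peaks(pulse, prominence=prominence,
                          distance=max(int(round(min_ibi_s * sfreq)), 1))
    if len(peaks) < 2:
        raise UnusableRecordingError("fewer than 2 beats detected")
    beat_times = peaks / sfreq
    ibi = np.diff(beat_times)
    return BeatSequence(beat_times_s=beat_times, ibi_s=ibi,
                        outlier_flags=np.zeros(len(ibi), dtype=bool))


def interpolate_ibi_outliers(beats: BeatSequence,
                             sd_cutoff: float = 2.5) -> BeatSequence:
    """Replace IBI outliers (> ``sd_cutoff`` SDs from the mean) linearly.

    The mean/SD are computed once on the raw IBI series (single pass).
    Outliers are interpolated between the nearest valid neighbors;
    endpoint outliers take the nearest valid value.  A zero-SD series
    has no outliers by definition.
    """
    ibi = np.asarray(beats.ibi_s, dtype=float)
    if len(ibi) < 3:
        raise ValueError("need at least 3 IBIs")
    mu, sd = ibi.mean(), ibi.std(ddof=0)
    flags = np.zeros(len(ibi), dtype=bool) if sd == 0 else \
        np.abs(ibi - mu) > sd_cutoff * sd
    if flags.all():
        raise UnusableRecordingError("all IBIs flagged as outliers")
    if not flags.any():
        return BeatSequence(beats.beat_times_s.copy(), ibi.copy(), flags)
    idx = np.arange(len(ibi))
    fixed = ibi.copy()
    fixed[flags] = np.interp(idx[flags], idx[~flags], ibi[~flags])
    # beat times are kept: corrected IBIs stay located at their original
    # inter-beat intervals for window lookup
    return BeatSequence(beats.beat_times_s.copy(), fixed, flags)


def compute_hr(beats: BeatSequence, tr_s: float, n_volumes: int,
               window_s: float = 6.0) -> PhysioSeries:
    """Heart rate = 1 / median in-window IBI, per BOLD volume (beats/s).

    An IBI is in-window when its interval [t_i, t_{i+1}) overlaps the
    window.  Windows containing no IBI yield missing values.
    """
    lo, hi = _window_bounds(n_volumes, tr_s, window_s)
    starts = beats.beat_times_s[:-1]
    ends = beats.beat_times_s[1:]
    out = np.full(n_volumes, np.nan)
    for k in range(n_volumes):
        sel = (ends > lo[k]) & (starts < hi[k])
        if sel.any():
            out[k] = 1.0 / float(np.median(beats.ibi_s[sel]))
    return PhysioSeries(values=out, kind="HR", tr_s=tr_s, units="beats/s")


@dataclass
class EyeClosureWindow:
    fraction: float
    logit: float
    truncated: bool


def percent_eye_closure(pupil: np.ndarray, pupil_sfreq: float,
                        windows, tr_s: float,
                        shift_s: float = 4.0) -> list[EyeClosureWindow]:
    """Fraction of zero (closed) pupil samples per forward-shifted window.

    ``windows`` are half-open ``(start_volume, end_volume)`` ranges on
    the BOLD clock; each is shifted forward by ``shift_s`` seconds
    before counting.  The logit is computed after clamping the fraction
    to ``[eps, 1 - eps]`` with ``eps = 1 / (2 * n_samples)``.  Windows
    extending past the recording are truncated and flagged.
    """
    pupil = np.asarray(pupil, dtype=float)
    n = pupil.size
    results = []
    for start_vol, end_vol in windows:
        t0 = start_vol * tr_s + shift_s
        t1 = end_vol * tr_s + shift_s
        i0 = max(int(round(t0 * pupil_sfreq)), 0)
        i1 = int(round(t1 * pupil_sfreq))
        truncated = i1 > n
        i1 = min(i1, n)
        chunk = pupil[i0:i1]
        if chunk.size == 0:
            warnings.warn("eye-closure window entirely past recording end")
            results.append(EyeClosureWindow(np.nan, np.nan, True))
            continue
        frac = float(np.mean(chunk == 0.0))
        eps = 1.0 / (2.0 * chunk.size)
        clamped = min(max(frac, eps), 1.0 - eps)
        logit = float(np.log(clamped / (1.0 - clamped)))
        results.append(EyeClosureWindow(frac, logit, truncated))
    return results
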