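"""BOLD signal conditioning: Legendre detrending, band-pass filtering,
confound regression pipelines (mCSF/WM, aCompCor, physio), and tSNR.

Fixed stage order: detrend -> band-pass -> confound regression, with
confound columns band-passed identically before the regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.signal import butter, sosfiltfilt

from .physio import PhysioSeries


class ConfigurationError(ValueError):
    pass


@dataclass
class ConfoundSet:
    regressors: np.ndarray        # volumes x k
    pipeline: str                 # mcsf_wm | acompcor | physio
    provenance: list[str]
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.regressors.shape[1]


def _as_2d(ts: np.ndarray) -> tuple[np.ndarray, bool]:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        return ts[None, :], True
    return ts, False


def detrend_legendre(ts: np.ndarray, order: int = 4) -> np.ndarray:
    """Remove the least-squares projection onto Legendre polynomials of
    degree 0..order (evaluated on [-1, 1]) from each target series."""
    x, squeeze = _as_2d(ts)
    n = x.shape[1]
    if n <= order + 1:
        raise ValueError(f"series of {n} volumes too short for order {order}")
    grid = np.linspace(-1.0, 1.0, n)
    basis = legendre.legvander(grid, order)
    q, _ = np.linalg.qr(basis)
    resid = x - (x @ q) @ q.T
    return resid[0] if squeeze else resid


def bandpass(ts: np.ndarray, tr_s: float, low: float = 0.01,
             high: float = 0.15, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward) per target.

    Edge effects are handled by the filter's reflection padding.
    """
    fs = 1.0 / tr_s
    if high >= fs / 2.0:
        raise ValueError(f"high={high} Hz >= Nyquist {fs / 2.0} Hz")
    x, squeeze = _as_2d(ts)
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sosfiltfilt(sos, x, axis=-1)
    return out[0] if squeeze else out


def bandpass_gain(freq_hz: float, tr_s: float, low: float = 0.01,
                  high: float = 0.15, order: int = 4) -> float:
    """Analytic amplitude gain of the zero-phase filter at ``freq_hz``."""
    from scipy.signal import sosfreqz
    fs = 1.0 / tr_s
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sosfreqz(sos, worN=[2 * np.pi * freq_hz / fs])
    return float(np.abs(h[0]) ** 2)  # squared: filter applied twice


# ---------------------------------------------------------------------------
# physiological response bases (cited canonical forms, pluggable)

def cardiac_response(t: np.ndarray) -> np.ndarray:
    """Canonical cardiac response function."""
    return (0.6 * t ** 2.7 * np.exp(-t / 1.6)
            - 16.0 / math.sqrt(2 * math.pi * 9.0)
            * np.exp(-((t - 12.0) ** 2) / 18.0))


def respiratory_response(t: np.ndarray) -> np.ndarray:
    """Canonical respiratory response function."""
    return (0.6 * t ** 2.1 * np.exp(-t / 1.6)
            - 0.0023 * t ** 3.54 * np.exp(-t / 4.25))


def _response_basis(fn, tr_s: float, span_s: float = 60.0) -> np.ndarray:
    """Five-column basis: canonical, 1st/2nd temporal derivatives, a
    dispersion (time-scaled) variant, and its derivative."""
    t = np.arange(0.0, span_s, tr_s)
    canon = fn(t)
    d1 = np.gradient(canon, tr_s)
    d2 = np.gradient(d1, tr_s)
    disp = fn(t / 1.1) - canon
    disp_d1 = np.gradient(disp, tr_s)
    cols = np.column_stack([canon, d1, d2, disp, disp_d1])
    norms = np.linalg.norm(cols, axis=0)
    norms[norms == 0] = 1.0
    return cols / norms


def _convolve_columns(signal: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Convolve a per-volume signal with each basis column.

    Missing (NaN) input samples are zero-filled for the convolution and
    the corresponding output volumes are reset to 0 afterwards, so that
    missing physiology enters the regression matrix as 0's.
    """
    n = len(signal)
    missing = ~np.isfinite(signal)
    clean = np.where(missing, 0.0, signal)
    out = np.column_stack([
        np.convolve(clean, basis[:, j])[:n] for j in range(basis.shape[1])
    ])
    out[missing, :] = 0.0
    return out


def build_confounds(pipeline: str, *, wm_ts: np.ndarray | None = None,
                    csf_ts: np.ndarray | None = None,
                    fv_ts: np.ndarray | None = None,
                    rv: PhysioSeries | None = None,
                    hr: PhysioSeries | None = None,
                    tr_s: float | None = None,
                    n_components: int = 5) -> ConfoundSet:
    """Assemble the regression matrix for one confound pipeline.

    * ``mcsf_wm``: 3 columns — mean WM, mean deep CSF, mean FV series.
    * ``acompcor``: first ``n_components`` principal components of the
      pooled (centered, variance-normalized) WM + deep-CSF series.
    * ``physio``: RV and HR each convolved with a five-function
      respiratory/cardiac response basis (10 columns); volumes with
      missing physiology contribute 0's.
    """
    if pipeline == "mcsf_wm":
        if wm_ts is None or csf_ts is None or fv_ts is None:
            raise ConfigurationError("mcsf_wm needs wm_ts, csf_ts, fv_ts")
        cols = [_as_2d(x)[0].mean(axis=0) for x in (wm_ts, csf_ts, fv_ts)]
        return ConfoundSet(np.column_stack(cols), pipeline,
                           ["mean_wm", "mean_deep_csf", "mean_fv"])
    if pipeline == "acompcor":
        if wm_ts is None or csf_ts is None:
            raise ConfigurationError("acompcor needs wm_ts and csf_ts")
        pooled = np.vstack([_as_2d(wm_ts)[0], _as_2d(csf_ts)[0]]).T  # T x q
        pooled = pooled - pooled.mean(axis=0)
        sd = pooled.std(axis=0, ddof=0)
        keep = sd > 0
        pooled = pooled[:, keep] / sd[keep]
        u, s, _ = np.linalg.svd(pooled, full_matrices=False)
        k = min(n_components, u.shape[1])
        comps = u[:, :k]
        flags = []
        if k < n_components:
            comps = np.pad(comps, ((0, 0), (0, n_components - k)))
            flags.append(f"only {k} components available")
        var = s ** 2 / max(pooled.shape[0] - 1, 1)
        low = [i for i in range(min(n_components, len(var)))
               if var[i] <= 1e-10]
        if low or k < n_components:
            flags.append("rank-deficient input: components "
                         f"{sorted(set(low) | set(range(k, n_components)))} "
                         "carry ~zero variance")
        return ConfoundSet(comps, pipeline,
                           [f"acompcor_pc{i + 1}" for i in range(n_components)],
                           flags)
    if pipeline == "physio":
        if rv is None or hr is None or tr_s is None:
            raise ConfigurationError("physio needs rv, hr, and tr_s")
        rcols = _convolve_columns(np.asarray(rv.values, dtype=float),
                                  _response_basis(respiratory_response, tr_s))
        ccols = _convolve_columns(np.asarray(hr.values, dtype=float),
                                  _response_basis(cardiac_response, tr_s))
        prov = [f"rv_rrf{i + 1}" for i in range(5)] + \
               [f"hr_crf{i + 1}" for i in range(5)]
        return ConfoundSet(np.column_stack([rcols, ccols]), pipeline, prov)
    raise ConfigurationError(f"unknown pipeline {pipeline!r}")


def regress_confounds(ts: np.ndarray, confounds: ConfoundSet | np.ndarray
                      ) -> np.ndarray:
    """OLS residuals of each target series on the confound columns.

    An intercept is always included.  Collinear columns are dropped
    (with a warning) before solving the normal equations.
    """
    c = confounds.regressors if isinstance(confounds, ConfoundSet) else \
        np.asarray(confounds, dtype=float)
    x, squeeze = _as_2d(ts)
    n = x.shape[1]
    if c.shape[0] != n:
        raise ValueError("confounds and time series differ in volume count")
    design = np.column_stack([np.ones(n), c])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear confound "
                      "column(s)")
        design = design[:, keep]
        q, _ = np.linalg.qr(design)
    resid = x - (x @ q) @ q.T
    return resid[0] if squeeze else resid


def tsnr(ts: np.ndarray) -> np.ndarray:
    """Temporal SNR per target: mean over standard deviation.

    Zero-variance targets yield +/-inf with a warning.
    """
    x, squeeze = _as_2d(ts)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance target(s): tSNR reported as inf")
    with np.errstate(divide="ignore"):
        out = np.where(sd > 0, mu / np.where(sd == 0, 1.0, sd),
                       np.sign(mu) * np.inf)
    return float(out[0]) if squeeze else out


def condition(bold: np.ndarray, tr_s: float, confounds=None, *,
              detrend_order: int = 4, low: float = 0.01,
              high: float = 0.15) -> np.ndarray:
    """Full conditioning chain: detrend, band-pass, regress confounds
    (themselves band-passed identically)."""
    x = detrend_legendre(bold, detrend_order)
    x = bandpass(x, tr_s, low, high)
    if confounds is not None:
        c = confounds.regressors if isinstance(confounds, ConfoundSet) else confounds
        c = bandpass(np.asarray(c, dtype=float).T, tr_s, low, high).T
        x = regress_confounds(x, c)
    return x
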