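"""Random-intercept linear mixed-effects group inference on Fisher-z
correlation samples, plus FDR and dual (top-fraction AND FDR) map
thresholding.

The model is ``y = X b + delta_subject + eps`` fitted by REML.  The
random-intercept structure admits a one-dimensional profiled REML
criterion in the variance ratio ``lambda = var(delta) / var(eps)``,
optimized by bounded search (with the boundary ``lambda = 0`` always
considered).  With one sample per subject the fit degenerates to the
classical one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


class ModelError(ValueError):
    pass


@dataclass
class CorrelationSample:
    """One Fisher-z observation: subject i, session/epoch/window j."""

    r: float
    subject_id: str
    unit_id: str = ""
    state: int | None = None   # alert = 0 (reference), drowsy = 1
    x: float | None = None     # volumes per epoch/window


@dataclass
class LmeFit:
    params: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    df: float
    var_subject: float
    var_resid: float
    lambda_ratio: float
    converged: bool
    n_samples: int
    n_subjects: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class GroupTMap:
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    contrast: str               # group-mean | state-effect
    mask: np.ndarray            # analyzed targets
    n_excluded: int = 0


@dataclass
class SignedMap:
    """Dual-thresholded t-map: sign in {-1, 0, +1} plus surviving t."""

    sign: np.ndarray
    t_surviving: np.ndarray     # t where surviving, 0 elsewhere
    mask: np.ndarray            # GM targets analyzed

    @property
    def positive(self) -> np.ndarray:
        return np.flatnonzero(self.sign > 0)

    @property
    def negative(self) -> np.ndarray:
        return np.flatnonzero(self.sign < 0)


def _group_summaries(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    q = len(uniq)
    p = X.shape[1]
    sx = np.zeros((q, p))
    sy = np.zeros(q)
    ng = np.zeros(q)
    np.add.at(sx, inv, X)
    np.add.at(sy, inv, y)
    np.add.at(ng, inv, 1.0)
    return sx, sy, ng


def _fit_random_intercept(y: np.ndarray, X: np.ndarray, groups,
                          names: list[str],
                          df_method: str = "containment") -> LmeFit:
    """Profiled-REML fit of a random-intercept model (see module doc)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    q = len(np.unique(groups))
    if q < 2:
        raise ModelError("need at least 2 subjects")
    if n <= p:
        raise ModelError("more parameters than samples")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    sx, sy, ng = _group_summaries(X, y, groups)

    def pieces(lam: float):
        w = lam / (1.0 + lam * ng)
        XtVX = XtX - (sx * w[:, None]).T @ sx
        XtVy = Xty - sx.T @ (w * sy)
        ytVy = yty - float(w @ sy ** 2)
        logdet_v = float(np.sum(np.log1p(lam * ng)))
        return XtVX, XtVy, ytVy, logdet_v

    def criterion(lam: float) -> float:
        XtVX, XtVy, ytVy, logdet_v = pieces(lam)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytVy - float(beta @ XtVy)
        if rss <= 0:
            rss = np.finfo(float).tiny
        return (n - p) * np.log(rss) + logdet_v + logdet_x

    # coarse log-grid then bounded refinement; boundary lam=0 kept in play
    grid = np.concatenate([[0.0], np.exp(np.linspace(-8, 8, 33))])
    vals = np.array([criterion(l) for l in grid])
    best = int(np.nanargmin(vals))
    lam_hat = grid[best]
    converged = np.isfinite(vals[best])
    if 0 < best < len(grid) - 1 and converged:
        lo, hi = grid[best - 1], grid[best + 1]
        res = optimize.minimize_scalar(criterion, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if res.success and res.fun <= vals[best]:
            lam_hat = float(res.x)

    XtVX, XtVy, ytVy, _ = pieces(lam_hat)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - float(beta @ XtVy), np.finfo(float).tiny)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))

    if df_method == "containment":
        df = n - p - q + 1
        if df <= 0:
            df = n - p
    elif df_method == "residual":
        df = n - p
    else:
        raise ModelError(f"unknown df_method {df_method!r}")

    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return LmeFit(
        params=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        t=dict(zip(names, map(float, tvals))),
        p=dict(zip(names, map(float, pvals))),
        df=float(df), var_subject=float(lam_hat * sigma2),
        var_resid=float(sigma2), lambda_ratio=float(lam_hat),
        converged=bool(converged and np.all(np.isfinite(beta))),
        n_samples=n, n_subjects=q)


def _unpack(samples):
    y = np.array([s.r for s in samples], dtype=float)
    g = np.array([s.subject_id for s in samples])
    c = np.array([np.nan if s.state is None else s.state for s in samples])
    x = np.array([np.nan if s.x is None else s.x for s in samples])
    return y, g, c, x


def fit_lme_intercept(samples, df_method: str = "containment") -> LmeFit:
    """Group-mean model ``r_ij = mu + delta_i + eps_ij``."""
    y, g, _, _ = _unpack(samples)
    return _fit_random_intercept(y, np.ones((len(y), 1)), g, ["mu"],
                                 df_method)


def fit_lme_two_state(samples, df_method: str = "containment") -> LmeFit:
    """State-contrast model ``r_ij = a0 + a1*c_ij + b*x_ij + d_i + e_ij``.

    ``c_ij`` is 1 for drowsy (state 2), 0 for the alert reference.  The
    epoch-length covariate enters untransformed; a constant covariate is
    dropped with a warning.
    """
    y, g, c, x = _unpack(samples)
    if np.any(np.isnan(c)):
        raise ModelError("every sample needs a state indicator")
    states = np.unique(c)
    if len(states) < 2:
        raise ModelError("both states must be represented")
    cols = [np.ones(len(y)), c]
    names = ["alpha0", "alpha1"]
    dropped = []
    if not np.any(np.isnan(x)):
        if np.std(x) < 1e-12:
            warnings.warn("constant epoch-length covariate dropped")
            dropped.append("beta")
        else:
            cols.append(x)
            names.append("beta")
    fit = _fit_random_intercept(y, np.column_stack(cols), g, names, df_method)
    fit.dropped = dropped
    return fit


def fit_lme_single_state(samples, df_method: str = "containment") -> LmeFit:
    """Single-state model ``r_ij = mu + b*(x_ij - mean(x)) + d_i + e_ij``.

    Centering makes ``mu`` the group-average correlation at the mean
    epoch length.
    """
    y, g, c, x = _unpack(samples)
    known = c[~np.isnan(c)]
    if known.size and len(np.unique(known)) > 1:
        raise ModelError("single-state model got samples from both states")
    cols = [np.ones(len(y))]
    names = ["mu"]
    if not np.any(np.isnan(x)) and np.std(x) >= 1e-12:
        cols.append(x - x.mean())
        names.append("beta")
    return _fit_random_intercept(y, np.column_stack(cols), g, names,
                                 df_method)


def fdr_bh(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def group_tmap(z_samples: np.ndarray, subject_ids, contrast: str,
               states=None, x=None, mask: np.ndarray | None = None,
               df_method: str = "containment") -> GroupTMap:
    """Per-target LME t/p map over a samples-by-targets matrix.

    ``contrast='group-mean'`` fits the intercept model and maps mu's t;
    ``contrast='state-effect'`` fits the two-state model and maps
    alpha1's t; ``contrast='single-state'`` fits the centered-covariate
    single-state model and maps mu's t.  Non-converged targets are
    excluded from the mask.
    """
    z = np.asarray(z_samples, dtype=float)
    n_samp, n_targ = z.shape
    mask = np.ones(n_targ, dtype=bool) if mask is None else np.asarray(mask, bool)
    t = np.full(n_targ, np.nan)
    p = np.full(n_targ, np.nan)
    excluded = 0
    for j in range(n_targ):
        if not mask[j]:
            continue
        samples = [
            CorrelationSample(
                r=z[i, j], subject_id=str(subject_ids[i]),
                state=None if states is None else int(states[i]),
                x=None if x is None else float(x[i]))
            for i in range(n_samp)
        ]
        try:
            if contrast == "group-mean":
                fit = fit_lme_intercept(samples, df_method)
                key = "mu"
            elif contrast == "state-effect":
                fit = fit_lme_two_state(samples, df_method)
                key = "alpha1"
            elif contrast == "single-state":
                fit = fit_lme_single_state(samples, df_method)
                key = "mu"
            else:
                raise ModelError(f"unknown contrast {contrast!r}")
        except ModelError:
            raise
        if not fit.converged:
            mask = mask.copy()
            mask[j] = False
            excluded += 1
            continue
        t[j] = fit.t[key]
        p[j] = fit.p[key]
    p_fdr = np.full(n_targ, np.nan)
    if mask.any():
        p_fdr[mask], _ = fdr_bh(p[mask])
    return GroupTMap(t=t, p=p, p_fdr=p_fdr, contrast=contrast, mask=mask,
                     n_excluded=excluded)


def threshold_tmap(tmap: GroupTMap, gm_mask: np.ndarray,
                   top_frac: float = 0.4, q: float = 0.05) -> SignedMap:
    """Survivors = top ``top_frac`` of |t| among GM targets AND
    FDR-significant (adjusted p < q); sign of t retained.  Ties at the
    |t| cutoff are all included.
    """
    gm = np.asarray(gm_mask, dtype=bool) & tmap.mask
    if not gm.any():
        raise ValueError("empty GM mask")
    n = len(tmap.t)
    abs_t = np.abs(tmap.t)
    m = int(gm.sum())
    k = max(int(np.ceil(top_frac * m)), 1)
    gm_abs = np.sort(abs_t[gm])[::-1]
    cutoff = gm_abs[k - 1]
    p_fdr_gm, _ = fdr_bh(tmap.p[gm], q)
    p_fdr = np.full(n, np.nan)
    p_fdr[gm] = p_fdr_gm
    survive = gm & (abs_t >= cutoff) & (p_fdr < q)
    sign = np.zeros(n, dtype=np.int8)
    sign[survive] = np.sign(tmap.t[survive]).astype(np.int8)
    t_surv = np.where(survive, tmap.t, 0.0)
    return SignedMap(sign=sign, t_surviving=t_surv, mask=gm)
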