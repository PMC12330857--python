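"""In-memory orchestration of the analysis stages over a study.

The CLI wraps these functions with on-disk I/O; tests and the
acceptance script call them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import conditioning, connectivity, physio, staging
from .clustering import (
    ClusterAssignment,
    StateVigilanceSummary,
    canonicalize_states,
    kmedians_cluster,
    state_vigilance_test,
)
from .inference import GroupTMap, SignedMap, group_tmap, threshold_tmap
from .synthetic import ALERT, DROWSY, SessionRecord, SyntheticStudy


def session_confounds(sess: SessionRecord, layout, pipeline: str):
    """Build the chosen confound set from one session's own signals."""
    if pipeline == "none":
        return None
    if pipeline == "mcsf_wm":
        return conditioning.build_confounds(
            "mcsf_wm", wm_ts=sess.bold[list(layout.wm_ids)],
            csf_ts=sess.bold[list(layout.csf_ids)],
            fv_ts=sess.bold[list(layout.fv_ids)])
    if pipeline == "acompcor":
        return conditioning.build_confounds(
            "acompcor", wm_ts=sess.bold[list(layout.wm_ids)],
            csf_ts=sess.bold[list(layout.csf_ids)])
    if pipeline == "physio":
        rv = physio.compute_rv(sess.resp, sess.resp_sfreq, sess.tr_s,
                               sess.n_volumes)
        beats = physio.interpolate_ibi_outliers(
            physio.detect_beats(sess.pulse, sess.pulse_sfreq))
        hr = physio.compute_hr(beats, sess.tr_s, sess.n_volumes)
        return conditioning.build_confounds("physio", rv=rv, hr=hr,
                                            tr_s=sess.tr_s)
    raise conditioning.ConfigurationError(f"unknown pipeline {pipeline!r}")


def condition_session(sess: SessionRecord, layout,
                      pipeline: str = "mcsf_wm") -> np.ndarray:
    """Detrend, band-pass, and confound-regress all parcels."""
    conf = session_confounds(sess, layout, pipeline)
    return conditioning.condition(sess.bold, sess.tr_s, conf)


def stage_session(sess: SessionRecord, thresholds=None, epoch_volumes=30,
                  z_thresh=1.5, shift_s=5.0):
    """EEG band powers -> per-second stages -> shifted state epochs."""
    tags = [region for _, region in sess.montage]
    frames = staging.epoch_band_powers(sess.eeg, sess.eeg_sfreq, tags)
    stages = staging.stage_series(frames, thresholds)
    epochs = staging.assign_epoch_states(
        stages, sess.tr_s, epoch_volumes=epoch_volumes, z_thresh=z_thresh,
        shift_s=shift_s, n_volumes=sess.n_volumes)
    return frames, stages, epochs


@dataclass
class StaticResult:
    tmap: GroupTMap
    signed: SignedMap
    n_sessions: int


def run_static(study: SyntheticStudy, pipeline: str = "mcsf_wm",
               top_frac: float = 0.4, q: float = 0.05) -> StaticResult:
    """Whole-scan seed maps per session -> group-mean LME -> threshold."""
    layout = study.layout
    gm = list(layout.gm_ids)
    rows, subjects = [], []
    for sess in study.sessions:
        cond = condition_session(sess, layout, pipeline)
        seed = connectivity.extract_seed(cond, list(layout.seed_ids))
        cmap = connectivity.correlation_map(seed, cond[gm])
        rows.append(cmap.z_values)
        subjects.append(sess.subject_id)
    z = np.vstack(rows)
    tmap = group_tmap(z, subjects, contrast="group-mean")
    signed = threshold_tmap(tmap, np.ones(z.shape[1], bool), top_frac, q)
    return StaticResult(tmap=tmap, signed=signed, n_sessions=len(rows))


@dataclass
class StateResult:
    contrast_tmap: GroupTMap
    contrast_signed: SignedMap
    single_state: dict[str, GroupTMap]
    single_signed: dict[str, SignedMap]
    epochs: dict[str, list]              # per session-id
    staging_frames: dict[str, object] = field(default_factory=dict)
    n_epoch_maps: int = 0


def run_state(study: SyntheticStudy, pipeline: str = "mcsf_wm",
              epoch_volumes: int = 30, z_thresh: float = 1.5,
              shift_s: float = 5.0, min_volumes: int = 30,
              top_frac: float = 0.4, q: float = 0.05) -> StateResult:
    """Epoch-restricted seed maps -> two-state and single-state LMEs."""
    layout = study.layout
    gm = list(layout.gm_ids)
    z_rows, subjects, states, x, epoch_log = [], [], [], [], {}
    frames_log = {}
    for sess in study.sessions:
        frames, _, epochs = stage_session(
            sess, epoch_volumes=epoch_volumes, z_thresh=z_thresh,
            shift_s=shift_s)
        key = f"{sess.subject_id}/{sess.session_id}"
        epoch_log[key] = epochs
        frames_log[key] = frames
        cond = condition_session(sess, layout, pipeline)
        seed = connectivity.extract_seed(cond, list(layout.seed_ids))
        for m in connectivity.epoch_fc(seed, cond[gm], epochs,
                                       min_volumes=min_volumes):
            z_rows.append(m.z_values)
            subjects.append(sess.subject_id)
            states.append(1 if m.state == "drowsy" else 0)
            x.append(m.n_volumes)
    if not z_rows:
        raise RuntimeError("no usable alert/drowsy epochs in the study")
    z = np.vstack(z_rows)
    subjects = np.array(subjects)
    states = np.array(states)
    x = np.array(x, dtype=float)
    gm_mask = np.ones(z.shape[1], bool)

    contrast = group_tmap(z, subjects, contrast="state-effect",
                          states=states, x=x)
    contrast_signed = threshold_tmap(contrast, gm_mask, top_frac, q)
    single, single_signed = {}, {}
    for name, code in (("alert", 0), ("drowsy", 1)):
        sel = states == code
        if sel.sum() >= 2 and len(np.unique(subjects[sel])) >= 2:
            tm = group_tmap(z[sel], subjects[sel], contrast="single-state",
                            x=x[sel])
            single[name] = tm
            single_signed[name] = threshold_tmap(tm, gm_mask, top_frac, q)
    return StateResult(contrast_tmap=contrast, contrast_signed=contrast_signed,
                       single_state=single, single_signed=single_signed,
                       epochs=epoch_log, staging_frames=frames_log,
                       n_epoch_maps=len(z_rows))


@dataclass
class ClusterResult:
    assignment: ClusterAssignment
    metric: np.ndarray          # per-window vigilance z
    subjects: np.ndarray
    starts: np.ndarray          # per-window start volume
    session_ids: np.ndarray
    summary: StateVigilanceSummary
    contrast_tmap: GroupTMap
    contrast_signed: SignedMap
    window_volumes: int


def window_vigilance_z(stages: staging.StageSeries, start_vol: int,
                       window_volumes: int, tr_s: float,
                       shift_s: float = 5.0) -> float:
    """Signed-rank vigilance z of the stage seconds underlying a BOLD
    window (window shifted back by the hemodynamic delay)."""
    s0 = max(int(math.floor(start_vol * tr_s - shift_s)), 0)
    s1 = min(int(math.floor((start_vol + window_volumes) * tr_s - shift_s)),
             len(stages.stages))
    return staging.signed_rank_z(stages.stages[s0:s1])


def run_cluster(study: SyntheticStudy, pipeline: str = "mcsf_wm",
                window_s: float = 240.0, overlap: float = 0.5,
                k: int = 2, restarts: int = 20, seed: int = 0,
                shift_s: float = 5.0, top_frac: float = 0.4,
                q: float = 0.05) -> ClusterResult:
    """Sliding-window FC pooled across sessions, k-medians states,
    vigilance association, and the state-contrast map."""
    layout = study.layout
    gm = list(layout.gm_ids)
    tr = study.sessions[0].tr_s
    window_volumes = int(round(window_s / tr))
    maps, metric, subjects, starts, sess_ids = [], [], [], [], []
    for sess in study.sessions:
        _, stages, _ = stage_session(sess, shift_s=shift_s)
        cond = condition_session(sess, layout, pipeline)
        seedc = connectivity.extract_seed(cond, list(layout.seed_ids))
        wset = connectivity.windowed_fc(seedc, cond[gm], window_volumes,
                                        overlap)
        for m, s0 in zip(wset.maps, wset.starts):
            maps.append(m.z_values)
            metric.append(window_vigilance_z(stages, int(s0), window_volumes,
                                             tr, shift_s))
            subjects.append(sess.subject_id)
            starts.append(int(s0))
            sess_ids.append(f"{sess.subject_id}/{sess.session_id}")
    X = np.vstack(maps)
    metric = np.array(metric)
    subjects = np.array(subjects)
    assignment = canonicalize_states(
        kmedians_cluster(X, k=k, restarts=restarts, seed=seed), metric)
    summary = state_vigilance_test(assignment, metric, subjects)
    c = (assignment.labels == 2).astype(int)  # state 2 vs state 1
    tmap = group_tmap(X, subjects, contrast="state-effect", states=c)
    signed = threshold_tmap(tmap, np.ones(X.shape[1], bool), top_frac, q)
    return ClusterResult(assignment=assignment, metric=metric,
                         subjects=subjects, starts=np.array(starts),
                         session_ids=np.array(sess_ids), summary=summary,
                         contrast_tmap=tmap, contrast_signed=signed,
                         window_volumes=window_volumes)


# ---------------------------------------------------------------------------
# ground-truth helpers for synthetic studies

def epoch_majority_state(latent, epoch, tr_s: float, lag_s: float = 5.0):
    """Majority latent state over an epoch's volumes; None if mixed
    (no state reaches 75% occupancy -> 'ambiguous')."""
    mids = (np.arange(epoch.start_volume, epoch.end_volume) + 0.5) * tr_s
    idx = np.clip(np.floor(mids - lag_s).astype(int), 0, latent.duration_s - 1)
    frac_drowsy = float(np.mean(latent.states[idx] == DROWSY))
    if frac_drowsy >= 0.75:
        return "drowsy"
    if frac_drowsy <= 0.25:
        return "alert"
    return None


def window_majority_state(latent, start_vol: int, window_volumes: int,
                          tr_s: float, lag_s: float = 5.0) -> int:
    """Majority latent state (ALERT/DROWSY) over a window's volumes."""
    mids = (np.arange(start_vol, start_vol + window_volumes) + 0.5) * tr_s
    idx = np.clip(np.floor(mids - lag_s).astype(int), 0, latent.duration_s - 1)
    return DROWSY if np.mean(latent.states[idx] == DROWSY) > 0.5 else ALERT
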