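"""Seed extraction and static / epoch-restricted / sliding-window
seed-to-target correlation maps with Fisher r-to-z transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .staging import StateEpoch

logger = logging.getLogger(__name__)

#: correlations are clipped to |r| <= 1 - R_CLIP before atanh
R_CLIP = 1e-7


@dataclass
class CorrelationMap:
    z_values: np.ndarray        # one Fisher-z per target
    seed_id: str
    scope: str                  # static | epoch | window
    n_volumes: int
    subject_id: str = ""
    session_id: str = ""
    state: str | None = None    # for epoch maps
    index: int | None = None    # epoch/window index
    flagged_targets: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))


@dataclass
class WindowedFCSet:
    maps: list[CorrelationMap]
    window_volumes: int
    overlap_frac: float
    starts: np.ndarray
    metric: np.ndarray | None = None   # per-window vigilance z / closure logit

    def __len__(self):
        return len(self.maps)

    def as_matrix(self) -> np.ndarray:
        """Windows x targets matrix of Fisher-z values."""
        return np.vstack([m.z_values for m in self.maps])


def extract_seed(ts_matrix: np.ndarray, seed_ids) -> np.ndarray:
    """Unweighted mean series over the selected targets."""
    ts = np.asarray(ts_matrix, dtype=float)
    idx = np.asarray(seed_ids)
    if idx.dtype == bool:
        idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty seed")
    return ts[idx.astype(int), :].mean(axis=0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to 1 - R_CLIP."""
    return np.arctanh(np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP))


def correlation_map(seed: np.ndarray, targets: np.ndarray,
                    seed_id: str = "seed", scope: str = "static",
                    **meta) -> CorrelationMap:
    """Pearson r of the seed against every target, Fisher z-transformed.

    Zero-variance targets are flagged and reported as z = 0.
    """
    seed = np.asarray(seed, dtype=float)
    t = np.asarray(targets, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    n = seed.size
    if n < 3:
        raise ValueError("need at least 3 paired volumes")
    if t.shape[1] != n:
        raise ValueError("seed and targets differ in volume count")
    s = seed - seed.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("zero-variance seed")
    tc = t - t.mean(axis=1, keepdims=True)
    t_norm = np.linalg.norm(tc, axis=1)
    flagged = np.flatnonzero(t_norm == 0)
    safe = np.where(t_norm == 0, 1.0, t_norm)
    r = (tc @ s) / (safe * s_norm)
    r[flagged] = 0.0
    return CorrelationMap(z_values=fisher_z(r), seed_id=seed_id, scope=scope,
                          n_volumes=n, flagged_targets=flagged, **meta)


def epoch_fc(seed: np.ndarray, targets: np.ndarray,
             epochs: list[StateEpoch], min_volumes: int = 30,
             seed_id: str = "seed", **meta) -> list[CorrelationMap]:
    """One correlation map per surviving alert/drowsy epoch.

    Intermediate epochs are excluded; epochs shorter than
    ``min_volumes`` are skipped (logged).
    """
    maps = []
    for i, ep in enumerate(epochs):
        if ep.state == "intermediate":
            continue
        if ep.n_volumes < min_volumes:
            logger.info("skipping %s epoch of %d volumes (< %d)",
                        ep.state, ep.n_volumes, min_volumes)
            continue
        m = correlation_map(seed[ep.start_volume:ep.end_volume],
                            targets[:, ep.start_volume:ep.end_volume],
                            seed_id=seed_id, scope="epoch", **meta)
        m.state = ep.state
        m.index = i
        maps.append(m)
    return maps


def windowed_fc(seed: np.ndarray, targets: np.ndarray,
                window_volumes: int, overlap: float = 0.5,
                seed_id: str = "seed", **meta) -> WindowedFCSet:
    """Sliding-window maps at starts 0, step, 2*step, ... where
    ``step = round(window_volumes * (1 - overlap))``; a trailing partial
    window is dropped."""
    n = np.asarray(seed).size
    if window_volumes > n:
        raise ValueError("window longer than session")
    step = int(round(window_volumes * (1.0 - overlap)))
    if step <= 0:
        raise ValueError("overlap too large: empty step")
    starts = np.arange(0, n - window_volumes + 1, step)
    maps = []
    for wi, s0 in enumerate(starts):
        m = correlation_map(seed[s0:s0 + window_volumes],
                            targets[:, s0:s0 + window_volumes],
                            seed_id=seed_id, scope="window", **meta)
        m.index = wi
        maps.append(m)
    return WindowedFCSet(maps=maps, window_volumes=window_volumes,
                         overlap_frac=overlap, starts=starts)
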