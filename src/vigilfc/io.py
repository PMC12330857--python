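"""Plain-text I/O for sessions, studies, maps, and tables.

Sessions are written as TSV files (EEG/BOLD with one column per
channel/parcel, physio as ``time_s<TAB>value`` with missing values
encoded as "NaN") plus a JSON ground-truth sidecar.  Signed maps and
epoch/state tables are TSV.  An optional raster writer tiles parcel
series into a small NIfTI-1 4D volume for the volumetric path.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import SignedMap
from .synthetic import (
    EffectSpec,
    LatentVigilanceTrajectory,
    ParcelLayout,
    SessionRecord,
    SyntheticStudy,
)


def _write_wave(path: Path, values: np.ndarray, sfreq: float) -> None:
    t = np.arange(len(values)) / sfreq
    df = pd.DataFrame({"time_s": t, "value": values})
    df.to_csv(path, sep="\t", index=False, na_rep="NaN", float_format="%.6f")


def _read_wave(path: Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    sfreq = 1.0 / (t[1] - t[0])
    return df["value"].to_numpy(), float(round(sfreq, 6))


def write_session(outdir: Path, sess: SessionRecord) -> Path:
    """Write one session's signals and ground-truth sidecar; returns the
    session directory."""
    d = Path(outdir) / sess.subject_id / sess.session_id
    d.mkdir(parents=True, exist_ok=True)

    eeg_cols = {f"{name}:{region}": sess.eeg[i]
                for i, (name, region) in enumerate(sess.montage)}
    pd.DataFrame(eeg_cols).to_csv(d / "eeg.tsv", sep="\t", index=False,
                                  float_format="%.5f")
    bold_cols = {f"p{j:04d}": sess.bold[j] for j in range(sess.bold.shape[0])}
    pd.DataFrame(bold_cols).to_csv(d / "bold.tsv", sep="\t", index=False,
                                   float_format="%.6f")
    _write_wave(d / "resp.tsv", sess.resp, sess.resp_sfreq)
    _write_wave(d / "pulse.tsv", sess.pulse, sess.pulse_sfreq)
    _write_wave(d / "pupil.tsv", sess.pupil, sess.pupil_sfreq)

    sidecar = {
        "subject_id": sess.subject_id,
        "session_id": sess.session_id,
        "tr_s": sess.tr_s,
        "eeg_sfreq": sess.eeg_sfreq,
        "resp_sfreq": sess.resp_sfreq,
        "pulse_sfreq": sess.pulse_sfreq,
        "pupil_sfreq": sess.pupil_sfreq,
        "montage": [list(ch) for ch in sess.montage],
        "latent_states": [int(s) for s in sess.latent.states],
        "transition_rate": sess.latent.transition_rate,
        "duration_s": sess.latent.duration_s,
    }
    (d / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return d


def read_session(session_dir: Path) -> SessionRecord:
    d = Path(session_dir)
    meta = json.loads((d / "ground_truth.json").read_text())
    eeg_df = pd.read_csv(d / "eeg.tsv", sep="\t")
    montage = tuple(tuple(c.split(":", 1)) for c in eeg_df.columns)
    eeg = eeg_df.to_numpy().T
    bold = pd.read_csv(d / "bold.tsv", sep="\t").to_numpy().T
    resp, resp_sf = _read_wave(d / "resp.tsv")
    pulse, pulse_sf = _read_wave(d / "pulse.tsv")
    pupil, pupil_sf = _read_wave(d / "pupil.tsv")
    latent = LatentVigilanceTrajectory(
        states=np.array(meta["latent_states"], dtype=np.int8),
        transition_rate=meta["transition_rate"],
        duration_s=meta["duration_s"])
    return SessionRecord(
        subject_id=meta["subject_id"], session_id=meta["session_id"],
        latent=latent, eeg=eeg, eeg_sfreq=meta["eeg_sfreq"], montage=montage,
        bold=bold, tr_s=meta["tr_s"], resp=resp, resp_sfreq=resp_sf,
        pulse=pulse, pulse_sfreq=pulse_sf, pupil=pupil, pupil_sfreq=pupil_sf)


def write_study(outdir: Path, study: SyntheticStudy) -> Path:
    """Write all sessions plus a manifest and the study-level truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sess in study.sessions:
        d = write_session(out, sess)
        manifest.append(str(d.relative_to(out)))
    truth = {
        "rng_seed": study.rng_seed,
        "effect_delta_z": [float(v) for v in study.effect_spec.delta_z],
        "layout": {
            "seed_ids": list(study.layout.seed_ids),
            "gm_ids": list(study.layout.gm_ids),
            "wm_ids": list(study.layout.wm_ids),
            "csf_ids": list(study.layout.csf_ids),
            "fv_ids": list(study.layout.fv_ids),
        },
        "sessions": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(truth, indent=1))
    return out


def read_study(indir: Path) -> SyntheticStudy:
    out = Path(indir)
    truth = json.loads((out / "manifest.json").read_text())
    sessions = [read_session(out / rel) for rel in truth["sessions"]]
    layout = ParcelLayout(
        seed_ids=tuple(truth["layout"]["seed_ids"]),
        gm_ids=tuple(truth["layout"]["gm_ids"]),
        wm_ids=tuple(truth["layout"]["wm_ids"]),
        csf_ids=tuple(truth["layout"]["csf_ids"]),
        fv_ids=tuple(truth["layout"]["fv_ids"]))
    return SyntheticStudy(subjects=sessions,
                          effect_spec=EffectSpec(
                              np.array(truth["effect_delta_z"])),
                          layout=layout, rng_seed=truth["rng_seed"])


def write_signed_map(path: Path, signed: SignedMap, tmap=None) -> None:
    """TSV with columns target_id, t, p, p_fdr, sign (0-based targets)."""
    n = len(signed.sign)
    t = tmap.t if tmap is not None else signed.t_surviving
    p = tmap.p if tmap is not None else np.full(n, np.nan)
    p_fdr = tmap.p_fdr if tmap is not None else np.full(n, np.nan)
    df = pd.DataFrame({
        "target_id": np.arange(n),
        "t": t, "p": p, "p_fdr": p_fdr,
        "sign": signed.sign.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, na_rep="NaN")


def read_signed_map(path: Path) -> SignedMap:
    df = pd.read_csv(path, sep="\t")
    sign = df["sign"].to_numpy().astype(np.int8)
    t = df["t"].to_numpy()
    return SignedMap(sign=sign, t_surviving=np.where(sign != 0, t, 0.0),
                     mask=np.ones(len(sign), dtype=bool))


def write_epoch_table(path: Path, epochs_by_session: dict) -> None:
    rows = []
    for key, epochs in epochs_by_session.items():
        for ep in epochs:
            rows.append({"session": key, "start_volume": ep.start_volume,
                         "end_volume": ep.end_volume, "state": ep.state,
                         "z_stat": ep.z_stat, "n_volumes": ep.n_volumes})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parcels_to_nifti(bold: np.ndarray, path: Path, tr_s: float = 1.0):
    """Tile parcel series into a small 4D NIfTI-1 volume (one voxel per
    parcel on a near-square grid) plus a parcel-label volume."""
    import nibabel as nib
    n_parcels, n_vol = bold.shape
    side = int(math.ceil(math.sqrt(n_parcels)))
    vol = np.zeros((side, side, 1, n_vol), dtype=np.float32)
    labels = np.full((side, side, 1), -1, dtype=np.int16)
    for p in range(n_parcels):
        i, j = divmod(p, side)
        vol[i, j, 0, :] = bold[p]
        labels[i, j, 0] = p
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
    nib.save(img, str(path))
    lab_path = str(path).replace(".nii", "_labels.nii")
    nib.save(nib.Nifti1Image(labels, affine), lab_path)
    return path


def nifti_to_parcels(path: Path, labels_path: Path) -> np.ndarray:
    """Invert :func:`parcels_to_nifti`: mean series per nonnegative label."""
    import nibabel as nib
    vol = np.asarray(nib.load(str(path)).dataobj)
    labels = np.asarray(nib.load(str(labels_path)).dataobj)
    ids = np.unique(labels[labels >= 0])
    out = np.empty((len(ids), vol.shape[-1]))
    flat_v = vol.reshape(-1, vol.shape[-1])
    flat_l = labels.reshape(-1)
    for k, p in enumerate(ids):
        out[k] = flat_v[flat_l == p].mean(axis=0)
    return out
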