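"""On-disk study layout.

Recordings travel as compressed ``.npz`` arrays (channels x samples plus
sampling rate, channel names, positions), ground truth as JSON sidecars,
and the design table as TSV with columns subject_id, group, lsas_total,
lsas_fear, lsas_avoidance. BrainVision/EDF raw files are read through MNE
when real data is used.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GroundTruth, Recording
from .synthetic import StudyBundle

__all__ = ["save_recording", "load_recording", "save_study", "load_study", "read_raw"]


def save_recording(rec: Recording, path: str | Path) -> None:
    np.savez_compressed(
        path,
        data=rec.data.astype(np.float32),
        srate=rec.srate,
        ch_names=np.array(rec.ch_names),
        ch_pos=rec.ch_pos if rec.ch_pos is not None else np.empty((0, 3)),
        epochs=np.array(rec.epochs, dtype=np.int64).reshape(-1, 2),
        reference=rec.reference,
    )


def load_recording(path: str | Path) -> Recording:
    z = np.load(path, allow_pickle=False)
    pos = z["ch_pos"]
    return Recording(
        data=z["data"].astype(np.float64),
        srate=float(z["srate"]),
        ch_names=[str(c) for c in z["ch_names"]],
        ch_pos=None if pos.size == 0 else pos,
        epochs=[tuple(e) for e in z["epochs"]],
        reference=str(z["reference"]),
    )


def save_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.design.to_csv(out / "design.tsv", sep="\t", index=False)
    for sid, rec, truth in zip(
        bundle.design["subject_id"], bundle.recordings, bundle.truths
    ):
        if rec is not None:
            save_recording(rec, out / f"{sid}.npz")
        (out / f"{sid}.truth.json").write_text(truth.to_json())
    return out


def load_study(in_dir: str | Path) -> StudyBundle:
    src = Path(in_dir)
    design = pd.read_csv(src / "design.tsv", sep="\t")
    recs, truths = [], []
    srate, duration = 0.0, 0.0
    for sid in design["subject_id"]:
        p = src / f"{sid}.npz"
        rec = load_recording(p) if p.exists() else None
        recs.append(rec)
        tp = src / f"{sid}.truth.json"
        truths.append(GroundTruth.from_json(tp.read_text()) if tp.exists() else None)
        if rec is not None:
            srate, duration = rec.srate, rec.duration_s
    return StudyBundle(
        design=design, truths=truths, recordings=recs,
        srate=srate, duration_s=duration,
    )


def read_raw(path: str | Path) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into a Recording."""
    import mne

    mne.set_log_level("ERROR")
    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="ERROR")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix}")
    raw.pick("eeg")
    pos = None
    montage = raw.get_montage()
    if montage is not None:
        ch_pos = montage.get_positions()["ch_pos"]
        if all(c in ch_pos for c in raw.ch_names):
            pos = np.asarray([ch_pos[c] for c in raw.ch_names])
            pos = pos - pos.mean(axis=0)
            pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Recording(
        data=raw.get_data() * 1e6,
        srate=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        ch_pos=pos,
    )
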