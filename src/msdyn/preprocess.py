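"""Continuous-EEG cleaning chain.

Order of operations mirrors standard resting-state practice: broadband
filter + notch on the continuous signal, segmentation into fixed 2 s
epochs, spherical-spline interpolation of bad channels, amplitude-based
epoch rejection, average reference, and finally the narrower 2-20 Hz band
used for microstate segmentation. Ocular/EMG component removal is left to
an external ICA hook (synthetic data is generated artifact-free).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .containers import QCReport, Recording

__all__ = [
    "bandpass_and_notch",
    "epoch",
    "reject_bad_epochs",
    "interpolate_channels",
    "average_reference",
    "microstate_band",
    "clean",
]

MAX_INTERPOLATED_CHANNELS = 6  # subjects needing this many or more are excluded


def _design_fir(
    srate: float, low: float | None, high: float | None, n_samples: int,
    stop: bool = False, trans_bandwidth: float | None = None,
) -> np.ndarray:
    """Odd-length Hamming windowed-sinc kernel (zero-phase when centered).

    Transition widths follow the usual adaptive rule (a quarter of the
    edge frequency, at least 2 Hz, never more than the edge itself); the
    length is 3.3 / narrowest transition, capped so reflection padding
    stays shorter than the signal.
    """
    from scipy.signal import firwin

    nyq = srate / 2.0
    trans = []
    if low is not None and low > 0:
        trans.append(min(max(low * 0.25, 2.0), low))
    if high is not None:
        trans.append(min(max(high * 0.25, 2.0), nyq - high))
    width = trans_bandwidth if trans_bandwidth else (min(trans) if trans else 2.0)
    numtaps = int(round(3.3 / width * srate)) | 1
    numtaps = min(numtaps, (2 * n_samples - 1) | 1)
    if stop:
        return firwin(numtaps, [low, high], fs=srate, pass_zero="bandstop")
    if low and high:
        return firwin(numtaps, [low, high], fs=srate, pass_zero="bandpass")
    if high:
        return firwin(numtaps, high, fs=srate, pass_zero="lowpass")
    return firwin(numtaps, low, fs=srate, pass_zero="highpass")


def _apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with reflection padding; net zero phase."""
    from scipy.signal import fftconvolve

    pad = len(taps) // 2
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = fftconvolve(xp, taps[None, :], mode="same", axes=-1)
    return y[:, pad:-pad] if pad else y


def _filter_data(x: np.ndarray, srate: float, low, high) -> np.ndarray:
    return _apply_fir(x, _design_fir(srate, low, high, x.shape[-1]))


def bandpass_and_notch(
    rec: Recording,
    low: float = 0.5,
    high: float = 80.0,
    notch: float | None = 50.0,
) -> Recording:
    """Zero-phase FIR band-pass plus power-line notch on continuous data."""
    if not (0 < low < high < rec.srate / 2):
        raise ValueError("need 0 < low < high < Nyquist")
    out = rec.copy()
    out.data = _filter_data(out.data, rec.srate, low, high)
    if notch is not None:
        taps = _design_fir(
            rec.srate, notch - 2.0, notch + 2.0, out.n_samples, stop=True,
            trans_bandwidth=1.0,
        )
        out.data = _apply_fir(out.data, taps)
    return out


def epoch(rec: Recording, length_s: float = 2.0) -> Recording:
    """Cut a continuous recording into consecutive fixed-length epochs.

    The trailing remainder shorter than one epoch is dropped.
    """
    if rec.epochs:
        raise ValueError("recording is already epoched")
    n_per = int(round(length_s * rec.srate))
    n_ep = rec.n_samples // n_per
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    out = rec.copy()
    out.data = out.data[:, : n_ep * n_per]
    out.epochs = [(i * n_per, (i + 1) * n_per) for i in range(n_ep)]
    return out


def reject_bad_epochs(
    rec: Recording,
    amp_uv: float = 80.0,
    max_bad_channels: int = 10,
    criterion: str = "absolute",
    qc: QCReport | None = None,
) -> tuple[Recording, QCReport]:
    """Drop epochs where too many channels exceed the amplitude bound.

    An epoch is removed iff *strictly more than* ``max_bad_channels``
    channels violate the criterion anywhere within it. ``criterion`` is
    ``"absolute"`` (any |sample| > amp_uv, the default) or
    ``"peak_to_peak"`` (max - min > amp_uv).
    """
    if not rec.epochs:
        raise ValueError("reject_bad_epochs requires an epoched recording")
    if criterion not in ("absolute", "peak_to_peak"):
        raise ValueError(f"unknown criterion {criterion!r}")
    keep: list[tuple[int, int]] = []
    kept_blocks: list[np.ndarray] = []
    cursor = 0
    n_rej = 0
    for e0, e1 in rec.epochs:
        seg = rec.data[:, e0:e1]
        if criterion == "absolute":
            bad = np.any(np.abs(seg) > amp_uv, axis=1)
        else:
            bad = (seg.max(axis=1) - seg.min(axis=1)) > amp_uv
        if int(bad.sum()) > max_bad_channels:
            n_rej += 1
            continue
        kept_blocks.append(seg)
        keep.append((cursor, cursor + seg.shape[1]))
        cursor += seg.shape[1]
    out = rec.copy()
    out.data = (
        np.concatenate(kept_blocks, axis=1)
        if kept_blocks
        else np.empty((rec.n_channels, 0))
    )
    out.epochs = keep
    ep_len = (rec.epochs[0][1] - rec.epochs[0][0]) / rec.srate
    if qc is None:
        qc = QCReport(epoch_length_s=ep_len)
    qc.epoch_length_s = ep_len
    qc.total_epochs = len(rec.epochs)
    qc.rejected_epochs = n_rej
    qc.retained_epochs = len(keep)
    return out, qc


def interpolate_channels(rec: Recording, bad: Sequence[str]) -> Recording:
    """Replace bad channels with spherical-spline estimates from the rest."""
    bad = list(bad)
    if not bad:
        return rec.copy()
    if len(bad) >= MAX_INTERPOLATED_CHANNELS:
        raise ValueError(
            f"{len(bad)} bad channels >= {MAX_INTERPOLATED_CHANNELS}: "
            "subject should be excluded, not repaired"
        )
    unknown = [b for b in bad if b not in rec.ch_names]
    if unknown:
        raise ValueError(f"bad channels not in recording: {unknown}")
    if rec.ch_pos is None:
        raise ValueError("channel positions required for interpolation")
    import mne

    mne.set_log_level("ERROR")
    info = mne.create_info(rec.ch_names, rec.srate, "eeg", verbose="ERROR")
    montage = mne.channels.make_dig_montage(
        ch_pos={n: p * 0.095 for n, p in zip(rec.ch_names, rec.ch_pos)},
        coord_frame="head",
    )
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="ERROR")
    raw.set_montage(montage)
    raw.info["bads"] = bad
    raw.interpolate_bads(reset_bads=True, verbose="ERROR")
    out = rec.copy()
    out.data = raw.get_data() * 1e6
    return out


def average_reference(rec: Recording) -> Recording:
    """Re-reference every sample's map to zero channel mean (idempotent)."""
    out = rec.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    out.reference = "average"
    return out


def microstate_band(rec: Recording, low: float = 2.0, high: float = 20.0) -> Recording:
    """2-20 Hz zero-phase band-pass applied per epoch (structure preserved)."""
    out = rec.copy()
    if rec.epochs:
        lengths = {e1 - e0 for e0, e1 in rec.epochs}
        if len(lengths) == 1:
            # equal-length epochs: filter all at once as stacked signals
            n_per = lengths.pop()
            stacked = np.concatenate(
                [rec.data[:, e0:e1] for e0, e1 in rec.epochs], axis=0
            )
            filt = _filter_data(stacked, rec.srate, low, high)
            for i, (e0, e1) in enumerate(rec.epochs):
                out.data[:, e0:e1] = filt[i * rec.n_channels : (i + 1) * rec.n_channels]
        else:
            for e0, e1 in rec.epochs:
                out.data[:, e0:e1] = _filter_data(
                    rec.data[:, e0:e1], rec.srate, low, high
                )
    else:
        out.data = _filter_data(rec.data, rec.srate, low, high)
    return out


def clean(
    rec: Recording,
    band: tuple[float, float] = (0.5, 80.0),
    notch: float | None = 50.0,
    epoch_s: float = 2.0,
    amp_uv: float = 80.0,
    max_bad_channels: int = 10,
    bad_channels: Sequence[str] = (),
    ms_band: tuple[float, float] = (2.0, 20.0),
    ica_hook: Callable[[Recording], Recording] | None = None,
) -> tuple[Recording, QCReport]:
    """Full cleaning chain from continuous raw EEG to analysis-ready epochs.

    filter -> epoch -> interpolate -> reject -> (external ICA hook) ->
    average reference -> microstate band. Returns the cleaned recording and
    its QC report.
    """
    qc = QCReport(epoch_length_s=epoch_s)
    r = bandpass_and_notch(rec, band[0], band[1], notch)
    r = epoch(r, epoch_s)
    if bad_channels:
        r = interpolate_channels(r, bad_channels)
        qc.interpolated_channels = list(bad_channels)
    r, qc = reject_bad_epochs(r, amp_uv, max_bad_channels, qc=qc)
    if ica_hook is not None:
        r = ica_hook(r)
    r = average_reference(r)
    r = microstate_band(r, ms_band[0], ms_band[1])
    return r, qc
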