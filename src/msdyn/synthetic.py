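"""Ground-truth synthetic resting-state EEG.

The generator emulates eyes-closed alpha-band EEG whose instantaneous
topography is always one of K quasi-stable template maps (microstates):
a semi-Markov state path (gamma dwell times, explicit jump chain) selects
the active template, an ~10 Hz carrier with a fresh random phase per
segment modulates its amplitude (so polarity flips across segments), and
spatially white sensor noise is added at a controlled SNR. Every recording
carries a :class:`~msdyn.containers.GroundTruth` sidecar so downstream
stages can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GroundTruth, Recording
from .montage import CAP64, channel_positions, flat_positions

__all__ = [
    "ARCHETYPES",
    "make_templates",
    "sample_state_sequence",
    "make_ground_truth",
    "synthesize_recording",
    "make_group_study",
    "StudyBundle",
]

# Canonical four resting-state classes: A and B are mirrored oblique
# dipoles (left-anterior/right-posterior and right-anterior/left-posterior),
# C peaks over anterior-central sensors, D is a straight anterior-posterior
# gradient. E-G are extra smooth patterns so k up to 7 is supported.
_TILT = np.deg2rad(55.0)  # obliquity of the A/B dipole axes from the midline


def _archetype_values(name: str, xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    if name == "A":  # left-anterior positive, right-posterior negative
        return -np.sin(_TILT) * x + np.cos(_TILT) * y
    if name == "B":  # right-anterior positive, left-posterior negative
        return np.sin(_TILT) * x + np.cos(_TILT) * y
    if name == "C":  # anterior-central maximum
        c = np.array([0.0, 0.75])
        return np.exp(-np.sum((xy - c) ** 2, axis=1) / (2 * 0.55**2))
    if name == "D":  # anterior-posterior dipole
        return y
    if name == "E":  # occipital maximum
        c = np.array([0.0, -0.85])
        return np.exp(-np.sum((xy - c) ** 2, axis=1) / (2 * 0.55**2))
    if name == "F":  # pure left-right dipole
        return x
    if name == "G":  # vertex maximum
        return np.exp(-np.sum(xy**2, axis=1) / (2 * 0.5**2))
    raise KeyError(name)


ARCHETYPES = ["A", "B", "C", "D", "E", "F", "G"]


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate (constant) map cannot be normalized")
    return maps / norms


def make_templates(
    n_channels: int = 64,
    k: int = 4,
    geometry: str = "standard-10-20",
    seed: int = 0,
    ch_names: list[str] | None = None,
):
    """Build k smooth, zero-mean, unit-norm archetype topographies.

    The maps are deterministic functions of the sensor geometry (the seed
    is accepted for interface symmetry with the stochastic generators but
    does not enter the construction). For k = 4 the archetypes follow the
    canonical A-D orientations. Pairwise absolute spatial correlation stays
    below 0.7 by construction of the archetype set.

    Returns a :class:`~msdyn.containers.TemplateSet`.
    """
    from .containers import TemplateSet

    if n_channels < 8:
        raise ValueError("need at least 8 channels for smooth topographies")
    if not 1 <= k <= len(ARCHETYPES):
        raise ValueError(
            f"k={k} outside the implemented archetype range 1..{len(ARCHETYPES)}; "
            "supply explicit maps for more classes"
        )
    if ch_names is None:
        if n_channels == 64:
            ch_names = list(CAP64)
        else:
            import mne

            mne.set_log_level("ERROR")
            full = mne.channels.make_standard_montage("standard_1005").ch_names
            ch_names = full[:n_channels]
    names, pos = channel_positions(ch_names, montage=geometry)
    xy = flat_positions(pos)
    maps = np.stack([_archetype_values(a, xy) for a in ARCHETYPES[:k]])
    maps = _normalize_maps(maps)
    return TemplateSet(maps=maps, labels=ARCHETYPES[:k], ch_names=names)


def sample_state_sequence(
    duration_s: float,
    srate: float,
    dwell_ms_mean: np.ndarray,
    jump_matrix: np.ndarray,
    seed: int,
    gamma_shape: float = 2.0,
) -> np.ndarray:
    """Semi-Markov state path: gamma dwell times, explicit jump chain.

    Dwell times are gamma(shape=``gamma_shape``) with the requested
    per-state means; on each jump the next state is drawn from the
    zero-diagonal row-stochastic ``jump_matrix``. Returns one int state per
    sample covering the full duration.
    """
    dwell = np.asarray(dwell_ms_mean, dtype=float)
    J = np.asarray(jump_matrix, dtype=float)
    k = dwell.size
    if J.shape != (k, k):
        raise ValueError("jump_matrix shape does not match number of states")
    if np.any(np.abs(np.diag(J)) > 1e-12):
        raise ValueError("jump_matrix must have a zero diagonal")
    if not np.allclose(J.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("jump_matrix rows must sum to 1")
    if np.any(dwell < 2000.0 / srate):
        raise ValueError("dwell means must be at least 2 samples")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * srate))
    out = np.empty(n, dtype=np.int64)
    state = int(rng.integers(k))
    t = 0
    while t < n:
        d_ms = rng.gamma(gamma_shape, dwell[state] / gamma_shape)
        length = max(1, int(round(d_ms * srate / 1000.0)))
        out[t : t + length] = state
        t += length
        state = int(rng.choice(k, p=J[state]))
    return out


def empirical_jump_matrix(label_seq: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized frequency of state changes in a label path."""
    a, b = label_seq[:-1], label_seq[1:]
    mask = a != b
    M = np.zeros((k, k))
    np.add.at(M, (a[mask], b[mask]), 1.0)
    rows = M.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return M / rows


def uniform_jump_matrix(k: int) -> np.ndarray:
    J = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(J, 0.0)
    return J


def make_ground_truth(
    duration_s: float,
    srate: float = 1000.0,
    n_channels: int = 64,
    k: int = 4,
    dwell_ms_mean: np.ndarray | None = None,
    jump_matrix: np.ndarray | None = None,
    carrier_hz: float = 10.0,
    snr: float = 4.0,
    seed: int = 0,
    gamma_shape: float = 2.0,
    templates: np.ndarray | None = None,
) -> GroundTruth:
    """Assemble templates, a state path, and generative parameters."""
    if templates is None:
        templates = make_templates(n_channels=n_channels, k=k).maps
    if dwell_ms_mean is None:
        dwell_ms_mean = np.full(k, 80.0)
    if jump_matrix is None:
        jump_matrix = uniform_jump_matrix(k)
    label_seq = sample_state_sequence(
        duration_s, srate, dwell_ms_mean, jump_matrix, seed, gamma_shape
    )
    return GroundTruth(
        templates=np.asarray(templates, dtype=float),
        label_seq=label_seq,
        transition_matrix=np.asarray(jump_matrix, dtype=float),
        dwell_ms_mean=np.asarray(dwell_ms_mean, dtype=float),
        carrier_hz=carrier_hz,
        snr=snr,
        seed=seed,
    )


def synthesize_recording(
    truth: GroundTruth,
    srate: float = 1000.0,
    duration_s: float | None = None,
    amplitude_uv: float = 50.0,
    ch_names: list[str] | None = None,
) -> Recording:
    """Render a GroundTruth state path into a multichannel recording.

    At sample t the clean signal is ``templates[state_t] * A *
    sin(2*pi*f*t/srate + phi_seg)`` with a fresh uniform phase per dwell
    segment, so successive segments of the same state flip polarity at
    random. Sensor noise is Gaussian, zero-mean across channels (white in
    the average-reference subspace), scaled so that the ratio of clean-signal
    RMS to noise RMS equals ``truth.snr``.
    """
    if duration_s is None:
        duration_s = len(truth.label_seq) / srate
    n = int(round(duration_s * srate))
    if n < int(10 * srate):
        raise ValueError("need at least 10 s of signal")
    if n > len(truth.label_seq):
        raise ValueError("ground-truth label sequence shorter than duration")
    labels = truth.label_seq[:n]
    k, n_ch = truth.templates.shape

    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0x5EC]))
    t = np.arange(n) / srate
    phase = np.empty(n)
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [n]])
    for s0, s1 in zip(starts, stops):
        phase[s0:s1] = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * truth.carrier_hz * t + phase)

    clean = truth.templates[labels].T * (amplitude_uv * carrier)  # n_ch x n
    sig_rms = np.sqrt(np.mean(clean**2))
    if np.isfinite(truth.snr):
        noise = rng.standard_normal((n_ch, n))
        noise -= noise.mean(axis=0, keepdims=True)
        noise *= (sig_rms / truth.snr) / np.sqrt(np.mean(noise**2))
        data = clean + noise
    else:
        data = clean

    if ch_names is None:
        ch_names = list(CAP64) if n_ch == 64 else [f"E{i+1}" for i in range(n_ch)]
    names, pos = (
        channel_positions(ch_names)
        if set(ch_names) <= set(CAP64) or n_ch == 64
        else (ch_names, None)
    )
    return Recording(data=data, srate=srate, ch_names=names, ch_pos=pos)


# ---------------------------------------------------------------------------
# Two-group study design


@dataclass
class StudyBundle:
    """A simulated two-group cohort: per-subject truth, scores, recordings."""

    design: pd.DataFrame  # subject_id, group, lsas_total, lsas_fear, lsas_avoidance
    truths: list[GroundTruth]
    recordings: list[Recording | None]
    srate: float
    duration_s: float
    state_labels: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])

    def truth_dwell_frame(self) -> pd.DataFrame:
        """Per-subject generative dwell means (ms), one column per state."""
        rows = []
        for sid, tr in zip(self.design["subject_id"], self.truths):
            row = {"subject_id": sid}
            row.update(
                {s: tr.dwell_ms_mean[i] for i, s in enumerate(self.state_labels)}
            )
            rows.append(row)
        return pd.DataFrame(rows)


# Baseline per-state mean dwell times (ms) for the comparison group; the
# contrasted group shifts state C up and state D down (effect_spec).
DEFAULT_DWELL_MS = {"A": 71.0, "B": 70.0, "C": 62.0, "D": 110.0}
DEFAULT_EFFECT_MS = {"C": +20.0, "D": -25.0}


def make_group_study(
    n_per_group: tuple[int, int] = (23, 18),
    effect_spec: dict[str, float] | None = None,
    seed: int = 0,
    srate: float = 250.0,
    duration_s: float = 300.0,
    snr: float = 4.0,
    dwell_ms_base: dict[str, float] | None = None,
    between_subject_sd_ms: float = 10.0,
    score_dwell_correlation: float = 0.5,
    synthesize: bool = True,
    carrier_hz: float = 10.0,
) -> StudyBundle:
    """Simulate a two-group resting-state cohort with dwell-time contrasts.

    Group ``high`` receives the per-state dwell offsets in ``effect_spec``
    (default: state C +20 ms, state D -25 ms); per-subject dwell means are
    jittered by a between-subject SD so group comparisons face realistic
    subject-level variance. Anxiety-scale scores are generated with group
    separation mirroring a high/low split and, within group, correlate with
    the subject's true state-C dwell deviation at the requested strength.

    With ``synthesize=False`` only ground-truth parameters and scores are
    produced (no EEG is rendered) — enough to exercise the statistical
    layer in large replicate counts.
    """
    if effect_spec is None:
        effect_spec = dict(DEFAULT_EFFECT_MS)
    if dwell_ms_base is None:
        dwell_ms_base = dict(DEFAULT_DWELL_MS)
    states = list(dwell_ms_base)
    unknown = set(effect_spec) - set(states)
    if unknown:
        raise ValueError(f"effect_spec names unknown state(s): {sorted(unknown)}")
    if min(n_per_group) < 2:
        raise ValueError("need at least 2 subjects per group")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57D]))
    k = len(states)
    J = uniform_jump_matrix(k)
    shared_templates = make_templates(k=k).maps
    base = np.array([dwell_ms_base[s] for s in states])
    offsets = {
        "high": np.array([effect_spec.get(s, 0.0) for s in states]),
        "low": np.zeros(k),
    }
    score_mu = {"high": 82.0, "low": 28.0}
    score_sd = 12.5

    rows, truths, recs = [], [], []
    idx = 0
    for group, n in zip(("high", "low"), n_per_group):
        for _ in range(n):
            idx += 1
            sid = f"sub-{idx:03d}"
            jitter = rng.normal(0.0, between_subject_sd_ms, size=k)
            dwell = np.maximum(base + offsets[group] + jitter, 30.0)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if synthesize:
                truth = make_ground_truth(
                    duration_s=duration_s,
                    srate=srate,
                    k=k,
                    dwell_ms_mean=dwell,
                    jump_matrix=J,
                    carrier_hz=carrier_hz,
                    snr=snr,
                    seed=sub_seed,
                    templates=shared_templates,
                )
            else:  # truth parameters only; no state path is needed
                truth = GroundTruth(
                    templates=shared_templates,
                    label_seq=np.empty(0, dtype=np.int64),
                    transition_matrix=J,
                    dwell_ms_mean=dwell,
                    carrier_hz=carrier_hz,
                    snr=snr,
                    seed=sub_seed,
                )
            truths.append(truth)
            recs.append(
                synthesize_recording(truth, srate=srate, duration_s=duration_s)
                if synthesize
                else None
            )
            # score: group mean + a component tracking the subject's true
            # C-dwell deviation, at the requested within-group correlation
            z_c = jitter[states.index("C")] / between_subject_sd_ms
            rho = score_dwell_correlation
            z = rho * z_c + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
            total = float(np.clip(score_mu[group] + score_sd * z, 0, 144))
            fear = float(np.clip(total * 0.5 + rng.normal(0, 2.0), 0, 72))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "lsas_total": round(total, 1),
                    "lsas_fear": round(fear, 1),
                    "lsas_avoidance": round(max(total - fear, 0.0), 1),
                }
            )
    design = pd.DataFrame(rows)
    return StudyBundle(
        design=design,
        truths=truths,
        recordings=recs,
        srate=srate,
        duration_s=duration_s,
        state_labels=states,
    )
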