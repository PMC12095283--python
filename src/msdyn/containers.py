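"""Core data containers for the microstate pipeline.

All containers are plain dataclasses holding numpy arrays; heavy lifting
(filtering, interpolation, clustering) lives in the functional modules.
Voltages are in microvolts throughout, time in samples unless a name says
otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

UNASSIGNED = -1  # label value for samples with no defined topography (zero GFP)


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts.

    ``epochs`` is a list of ``[start, stop)`` sample intervals; an empty list
    means the recording is continuous. ``reference`` is ``"original"`` or
    ``"average"``.
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    ch_pos: np.ndarray | None = None  # (n_channels, 3) unit-sphere coords
    epochs: list[tuple[int, int]] = field(default_factory=list)
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            srate=self.srate,
            ch_names=list(self.ch_names),
            ch_pos=None if self.ch_pos is None else self.ch_pos.copy(),
            epochs=list(self.epochs),
            reference=self.reference,
        )

    def epoch_slices(self) -> list[tuple[int, int]]:
        """Epoch bounds, falling back to the whole recording if continuous."""
        if self.epochs:
            return list(self.epochs)
        return [(0, self.n_samples)]


@dataclass
class QCReport:
    """Per-subject preprocessing bookkeeping."""

    interpolated_channels: list[str] = field(default_factory=list)
    total_epochs: int = 0
    rejected_epochs: int = 0
    retained_epochs: int = 0
    epoch_length_s: float = 2.0
    min_retained_s: float = 180.0

    @property
    def retained_seconds(self) -> float:
        return self.retained_epochs * self.epoch_length_s

    @property
    def passes_inclusion(self) -> bool:
        return self.retained_seconds >= self.min_retained_s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["retained_seconds"] = self.retained_seconds
        d["passes_inclusion"] = self.passes_inclusion
        return d


@dataclass
class TemplateSet:
    """K microstate template topographies (K x C, zero-mean, unit-norm rows)."""

    maps: np.ndarray
    labels: list[str]
    ch_names: list[str] | None = None
    gev_total: float | None = None
    k_criteria: pd.DataFrame | None = None
    label_provenance: dict | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2:
            raise ValueError("maps must be K x C")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("labels length does not match number of maps")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def reordered(self, order: Sequence[int], labels: Sequence[str]) -> "TemplateSet":
        return TemplateSet(
            maps=self.maps[list(order)],
            labels=list(labels),
            ch_names=self.ch_names,
            gev_total=self.gev_total,
            k_criteria=self.k_criteria,
            label_provenance=self.label_provenance,
        )


@dataclass
class LabelSequence:
    """Per-sample microstate assignments aligned to a recording's epochs.

    ``states[t]`` is the template index or :data:`UNASSIGNED`.
    """

    states: np.ndarray
    srate: float
    epochs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    def segment_table(self) -> pd.DataFrame:
        """Runs of constant label within each epoch.

        Columns: state, start, stop (exclusive), duration_ms, epoch,
        is_edge (touches an epoch boundary, i.e. possibly truncated).
        """
        rows = []
        for ei, (e0, e1) in enumerate(self.epochs or [(0, len(self.states))]):
            seg = self.states[e0:e1]
            if seg.size == 0:
                continue
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate([[0], change])
            stops = np.concatenate([change, [seg.size]])
            for s0, s1 in zip(starts, stops):
                rows.append(
                    {
                        "state": int(seg[s0]),
                        "start": int(e0 + s0),
                        "stop": int(e0 + s1),
                        "duration_ms": (s1 - s0) * 1000.0 / self.srate,
                        "epoch": ei,
                        "is_edge": bool(s0 == 0 or s1 == seg.size),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["state", "start", "stop", "duration_ms", "epoch", "is_edge"],
        )

    def n_switches(self) -> int:
        """Label changes summed within epochs (epoch joins not counted)."""
        total = 0
        for e0, e1 in self.epochs or [(0, len(self.states))]:
            seg = self.states[e0:e1]
            if seg.size > 1:
                total += int(np.count_nonzero(np.diff(seg)))
        return total

    def copy(self) -> "LabelSequence":
        return LabelSequence(self.states.copy(), self.srate, list(self.epochs))


@dataclass
class MicrostateParams:
    """Per-state temporal parameters plus GEV and the transition matrix.

    ``transition[i, j]`` is the probability of an ordered segment adjacency
    i -> j among all adjacencies (off-diagonal cells sum to 1); the diagonal
    is structurally zero.
    """

    labels: list[str]
    duration_ms: np.ndarray  # NaN where the state never occurs interior
    occurrence_hz: np.ndarray
    coverage_pct: np.ndarray
    gev: float
    transition: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.labels,
                "duration_ms": self.duration_ms,
                "occurrence_hz": self.occurrence_hz,
                "coverage_pct": self.coverage_pct,
                "gev": self.gev,
            }
        )

    def transition_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.labels)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "from": self.labels[i],
                        "to": self.labels[j],
                        "probability": float(self.transition[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Generative parameters and realized state path for one synthetic subject."""

    templates: np.ndarray  # K x C, zero-mean unit-norm rows
    label_seq: np.ndarray  # per-sample int in 0..K-1
    transition_matrix: np.ndarray  # K x K jump chain, zero diagonal, rows sum 1
    dwell_ms_mean: np.ndarray  # per-state mean dwell (ms)
    carrier_hz: float
    snr: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "templates": self.templates.tolist(),
                "label_seq": self.label_seq.tolist(),
                "transition_matrix": self.transition_matrix.tolist(),
                "dwell_ms_mean": np.asarray(self.dwell_ms_mean).tolist(),
                "carrier_hz": self.carrier_hz,
                "snr": None if np.isinf(self.snr) else self.snr,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            templates=np.asarray(d["templates"], dtype=float),
            label_seq=np.asarray(d["label_seq"], dtype=np.int64),
            transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
            dwell_ms_mean=np.asarray(d["dwell_ms_mean"], dtype=float),
            carrier_hz=float(d["carrier_hz"]),
            snr=np.inf if d["snr"] is None else float(d["snr"]),
            seed=int(d["seed"]),
        )
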