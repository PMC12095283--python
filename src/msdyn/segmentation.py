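"""Sample-level microstate segmentation and temporal parameters.

Given a cleaned, average-referenced recording and a template set, every
sample is assigned to the template of minimal global map dissimilarity
(equivalently maximal absolute spatial correlation), the label path is
smoothed with a windowed nonsmoothness penalty, segments shorter than a
minimum duration are dissolved, and the canonical temporal parameters
(mean duration, occurrence rate, time coverage, GEV, transition
probabilities) are computed from the resulting segment table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .containers import UNASSIGNED, LabelSequence, MicrostateParams, Recording, TemplateSet

__all__ = [
    "GFPSeries",
    "gfp",
    "find_gfp_peaks",
    "extract_peak_maps",
    "backfit",
    "smooth_labels",
    "drop_short_segments",
    "parameters",
    "segment",
]


@dataclass
class GFPSeries:
    """Global field power per sample, with detected peak indices."""

    values: np.ndarray
    srate: float
    epochs: list[tuple[int, int]]
    peak_indices: np.ndarray | None = None


def _check_avg_ref(rec: Recording) -> None:
    mean_abs = np.abs(rec.data.mean(axis=0))
    scale = max(float(np.abs(rec.data).max()), 1e-30)
    if mean_abs.max() > 1e-6 * scale:
        raise ValueError("recording must be average-referenced (zero channel mean)")


def gfp(rec: Recording) -> GFPSeries:
    """Global field power: spatial standard deviation of each sample's map.

    With average reference this equals the RMS of the instantaneous map.
    """
    _check_avg_ref(rec)
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, srate=rec.srate, epochs=rec.epoch_slices())


def find_gfp_peaks(g: GFPSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Strict local maxima of the GFP curve, per epoch, boundaries excluded.

    Peaks closer than ``min_separation_ms`` are thinned keeping the larger;
    on an exact two-sample plateau the earlier sample is kept.
    """
    dist = max(1, int(round(min_separation_ms * g.srate / 1000.0)))
    found = []
    for e0, e1 in g.epochs:
        seg = g.values[e0:e1]
        if seg.size < 3:
            continue
        idx, _ = find_peaks(seg, distance=dist)
        found.append(idx + e0)
    peaks = (
        np.concatenate(found) if found else np.empty(0, dtype=np.int64)
    ).astype(np.int64)
    g.peak_indices = peaks
    return peaks


def extract_peak_maps(
    rec: Recording, peaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-sample topographies and their GFP weights (for clustering)."""
    maps = rec.data[:, peaks].T
    weights = maps.std(axis=1, ddof=0)
    return maps, weights


def _fit_matrix(rec: Recording, ts: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """(K x n) spatial correlations template-vs-sample, plus GFP per sample.

    Zero-GFP samples get correlation 0 to every template.
    """
    x = rec.data - rec.data.mean(axis=0, keepdims=True)
    g = np.linalg.norm(x, axis=0)
    safe = np.where(g > 0, g, 1.0)
    xn = x / safe
    tmaps = ts.maps - ts.maps.mean(axis=1, keepdims=True)
    tmaps = tmaps / np.linalg.norm(tmaps, axis=1, keepdims=True)
    r = tmaps @ xn
    r[:, g == 0] = 0.0
    return r, g / np.sqrt(rec.n_channels)  # GFP = RMS for avg-ref maps


def backfit(rec: Recording, ts: TemplateSet) -> LabelSequence:
    """Label every sample with its best-matching template (minimal GMD).

    Polarity- and gain-invariant; zero-GFP samples become unassigned.
    """
    _check_avg_ref(rec)
    r, _ = _fit_matrix(rec, ts)
    states = np.argmax(np.abs(r), axis=0).astype(np.int64)
    zero_gfp = np.all(r == 0.0, axis=0)
    states[zero_gfp] = UNASSIGNED
    return LabelSequence(states=states, srate=rec.srate, epochs=rec.epoch_slices())


def smooth_labels(
    ls: LabelSequence,
    rec: Recording,
    ts: TemplateSet,
    window_ms: float = 30.0,
    besag: float = 10.0,
    max_iter: int = 50,
) -> LabelSequence:
    """Windowed nonsmoothness-penalized relabeling.

    Each sample's cost for template k is its misfit (1 - r_k**2) minus a
    bonus proportional to the number of same-labeled neighbours within a
    half-window on each side; labels are re-chosen by minimum cost and the
    update is iterated to a fixed point. The penalty weight is
    ``besag / (2 * (C - 1))`` so the conventional factor of 10 produces
    strong smoothing relative to the [0, 1] misfit scale. The result never
    has more label switches than the input (iteration stops otherwise).
    Unassigned samples stay unassigned and do not count as neighbours.
    """
    if besag == 0:
        return ls.copy()
    r, _ = _fit_matrix(rec, ts)
    k, n = r.shape
    misfit = 1.0 - r**2
    lam = besag / (2.0 * (rec.n_channels - 1))
    half = max(1, int(round(window_ms * rec.srate / 2000.0)))
    kernel = np.ones(2 * half + 1)
    kernel[half] = 0.0  # a sample is not its own neighbour

    cur = ls.states.copy()
    unassigned = cur == UNASSIGNED
    best = ls.copy()
    best_switch = ls.n_switches()
    for _ in range(max_iter):
        cost = misfit.copy()
        for e0, e1 in ls.epochs:
            seg = cur[e0:e1]
            onehot = np.zeros((k, e1 - e0))
            valid = seg != UNASSIGNED
            onehot[seg[valid], np.flatnonzero(valid)] = 1.0
            for s in range(k):
                counts = np.convolve(onehot[s], kernel, mode="same")
                cost[s, e0:e1] -= lam * counts
        new = np.argmin(cost, axis=0).astype(np.int64)
        new[unassigned] = UNASSIGNED
        if np.array_equal(new, cur):
            break
        cand = LabelSequence(new, ls.srate, list(ls.epochs))
        sw = cand.n_switches()
        if sw > best_switch:
            break
        cur = new
        best, best_switch = cand, sw
    return best


def drop_short_segments(
    ls: LabelSequence,
    rec: Recording,
    ts: TemplateSet,
    min_ms: float = 30.0,
    max_iter: int = 100_000,
) -> LabelSequence:
    """Dissolve interior segments shorter than ``min_ms``.

    Each sample of a short segment is reassigned to whichever adjacent
    segment's state fits it better (higher absolute spatial correlation);
    the scan repeats until no interior segment is below the minimum.
    Epoch-edge segments are exempt (their true duration is unknown). If an
    epoch degenerates to nothing but short segments, all its samples join
    the single best-fitting state.
    """
    r, _ = _fit_matrix(rec, ts)
    absr = np.abs(r)
    out = ls.copy()
    min_len = min_ms * ls.srate / 1000.0

    def _runs(seg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        change = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [seg.size]])
        return seg[starts], starts, stops

    for e0, e1 in out.epochs or [(0, len(out.states))]:
        for _ in range(max_iter):
            seg = out.states[e0:e1]
            st, starts, stops = _runs(seg)
            short = (
                (stops - starts < min_len)
                & (st != UNASSIGNED)
                & (starts > 0)
                & (stops < seg.size)  # edge runs exempt
            )
            idx = np.flatnonzero(short)
            if idx.size:
                # runs isolated between unassigned gaps cannot be dissolved
                fixable = (st[idx - 1] != UNASSIGNED) | (st[idx + 1] != UNASSIGNED)
                idx = idx[fixable]
            if idx.size == 0:
                break
            # dissolve the shortest run, then rebuild: samples go to the
            # better-fitting neighbour under a single left/right cut, so
            # each dissolution strictly reduces the run count
            i = idx[np.argmin(stops[idx] - starts[idx])]
            left, right = int(st[i - 1]), int(st[i + 1])
            sl = slice(e0 + starts[i], e0 + stops[i])
            if left == UNASSIGNED or right == UNASSIGNED or left == right:
                out.states[sl] = right if left == UNASSIGNED else left
            else:
                fl, fr = absr[left, sl], absr[right, sl]
                gain = np.concatenate([[0.0], np.cumsum(fl - fr)])
                cut = int(np.argmax(gain))  # samples < cut join the left
                out.states[sl][:cut] = left
                out.states[sl][cut:] = right
        # degenerate epoch: nothing but short runs -> best single state
        seg = out.states[e0:e1]
        st, starts, stops = _runs(seg)
        ok = ((stops - starts) >= min_len) | (st == UNASSIGNED)
        if seg.size and not ok.any():
            out.states[e0:e1] = int(np.argmax(absr[:, e0:e1].sum(axis=1)))
    return out


def parameters(
    ls: LabelSequence,
    rec: Recording,
    ts: TemplateSet,
    include_edge_in_duration: bool = False,
) -> MicrostateParams:
    """Temporal microstate parameters from a cleaned label sequence.

    duration: per-state mean of interior segment durations (ms); edge
    segments (truncated by epoch boundaries) are excluded by default since
    their true dwell is censored. occurrence: interior segments per
    analyzed second. coverage: per-state percentage of assigned samples
    (edge segments included; unassigned samples excluded from the
    denominator). GEV: GFP-squared-weighted mean of the squared spatial
    correlation with the assigned template. transition: ordered
    segment-adjacency frequencies, all K*(K-1) cells pooled in one
    denominator (cells sum to 1); no adjacency is counted across epochs.
    """
    k = ts.k
    table = ls.segment_table()
    seg = table[table["state"] != UNASSIGNED]
    analyzed_s = sum(e1 - e0 for e0, e1 in ls.epochs) / ls.srate

    use = seg if include_edge_in_duration else seg[~seg["is_edge"]]
    duration = np.full(k, np.nan)
    occurrence = np.zeros(k)
    for s in range(k):
        d = use[use["state"] == s]["duration_ms"]
        if len(d):
            duration[s] = float(d.mean())
        occurrence[s] = len(d) / analyzed_s

    assigned = ls.states != UNASSIGNED
    n_assigned = int(assigned.sum())
    coverage = np.zeros(k)
    if n_assigned:
        for s in range(k):
            coverage[s] = 100.0 * np.count_nonzero(ls.states == s) / n_assigned

    r, g = _fit_matrix(rec, ts)
    gev = 0.0
    denom = float(np.sum(g[assigned] ** 2))
    if denom > 0:
        rt = r[ls.states[assigned], np.flatnonzero(assigned)]
        gev = float(np.sum((g[assigned] * rt) ** 2) / denom)

    trans = np.zeros((k, k))
    for ei in sorted(seg["epoch"].unique()):
        sub = table[table["epoch"] == ei]
        st = sub["state"].to_numpy()
        for a, b in zip(st[:-1], st[1:]):
            if a != UNASSIGNED and b != UNASSIGNED and a != b:
                trans[a, b] += 1
    total = trans.sum()
    if total > 0:
        trans /= total

    return MicrostateParams(
        labels=list(ts.labels),
        duration_ms=duration,
        occurrence_hz=occurrence,
        coverage_pct=coverage,
        gev=gev,
        transition=trans,
    )


def segment(
    rec: Recording,
    ts: TemplateSet,
    smooth_ms: float = 30.0,
    besag: float = 10.0,
    min_duration_ms: float = 30.0,
) -> tuple[LabelSequence, MicrostateParams]:
    """Backfit -> smooth -> drop short segments -> parameters."""
    ls = backfit(rec, ts)
    ls = smooth_labels(ls, rec, ts, window_ms=smooth_ms, besag=besag)
    ls = drop_short_segments(ls, rec, ts, min_ms=min_duration_ms)
    return ls, parameters(ls, rec, ts)
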