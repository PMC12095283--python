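"""GFP, peak picking, backfitting, smoothing, cleanup, parameters."""

import numpy as np
import pytest

from msdyn import (
    LabelSequence,
    Recording,
    TemplateSet,
    UNASSIGNED,
    backfit,
    drop_short_segments,
    find_gfp_peaks,
    gfp,
    make_templates,
    parameters,
    smooth_labels,
)
from msdyn.montage import channel_positions
from msdyn.segmentation import GFPSeries


def _rec(data, srate=1000.0, epochs=None):
    data = np.asarray(data, float)
    names = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data, srate, names, epochs=epochs or [])


def _template_recording(states, srate=1000.0, amp=10.0):
    """Recording whose map at t is amp * template[states[t]], avg-referenced."""
    ts = make_templates(64, 4)
    data = amp * ts.maps[np.asarray(states)].T
    names, pos = channel_positions()
    rec = Recording(data, srate, names, pos, reference="average")
    return rec, ts


class TestGFP:
    def test_two_channel_map(self):
        g = gfp(_rec([[1.0], [-1.0]]))
        assert g.values[0] == pytest.approx(1.0)

    def test_zero_map(self):
        assert gfp(_rec([[0.0], [0.0]])).values[0] == 0.0

    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 20))
        x -= x.mean(axis=0)
        a, b = gfp(_rec(x)), gfp(_rec(-2.5 * x))
        assert np.allclose(b.values, 2.5 * a.values)

    def test_rejects_unreferenced_input(self):
        with pytest.raises(ValueError, match="average-referenced"):
            gfp(_rec([[5.0], [1.0]]))


class TestPeakPicking:
    def test_amplitude_modulated_carrier_spacing(self):
        t = np.arange(2000) / 1000.0
        env = np.abs(np.sin(2 * np.pi * 10.0 * t))
        x = np.vstack([env, -env])
        g = GFPSeries(values=env, srate=1000.0, epochs=[(0, 2000)])
        peaks = find_gfp_peaks(g)
        assert np.allclose(np.diff(peaks), 50, atol=2)

    def test_monotone_ramp_has_no_peaks(self):
        g = GFPSeries(np.linspace(0, 1, 500), 1000.0, [(0, 500)])
        assert find_gfp_peaks(g).size == 0

    def test_two_equal_adjacent_maxima_keep_earlier(self):
        v = np.array([0.0, 1.0, 5.0, 5.0, 1.0, 0.0, 0.0])
        g = GFPSeries(v, 1000.0, [(0, 7)])
        assert list(find_gfp_peaks(g, min_separation_ms=1.0)) == [2]

    def test_min_separation_keeps_larger(self):
        v = np.array([0.0, 3.0, 0.5, 4.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        g = GFPSeries(v, 1000.0, [(0, 10)])
        assert list(find_gfp_peaks(g, min_separation_ms=5.0)) == [3]


class TestBackfit:
    def test_noiseless_identifiability(self):
        states = np.repeat([0, 1, 2, 3], 50)
        rec, ts = _template_recording(states)
        ls = backfit(rec, ts)
        assert np.array_equal(ls.states, states)

    def test_matches_naive_gmd_argmin(self):
        from msdyn.clustering import gmd

        rng = np.random.default_rng(1)
        ts = make_templates(64, 4)
        data = rng.normal(size=(64, 1000))
        data -= data.mean(axis=0)
        names, _ = channel_positions()
        rec = Recording(data, 1000.0, names, reference="average")
        ls = backfit(rec, ts)
        naive = np.array(
            [
                np.argmin([gmd(data[:, t], m) for m in ts.maps])
                for t in range(1000)
            ]
        )
        assert np.array_equal(ls.states, naive)

    def test_invariant_to_gain_and_polarity(self):
        states = np.repeat([0, 1, 2, 3], 50)
        rec, ts = _template_recording(states)
        for factor in (-1.0, 0.003, 1e4):
            scaled = rec.copy()
            scaled.data = scaled.data * factor
            assert np.array_equal(backfit(scaled, ts).states, states)

    def test_zero_gfp_unassigned(self):
        states = np.repeat([0, 1], 30)
        rec, ts = _template_recording(states)
        rec.data[:, 10:14] = 0.0
        ls = backfit(rec, ts)
        assert np.all(ls.states[10:14] == UNASSIGNED)


class TestSmoothing:
    def _noisy_alternation(self, seed=0):
        rng = np.random.default_rng(seed)
        states = np.repeat(rng.integers(0, 4, 20), 60)  # 60 ms segments
        rec, ts = _template_recording(states)
        rec.data += 8.0 * rng.standard_normal(rec.data.shape)
        rec = Recording(rec.data - rec.data.mean(0), rec.srate, rec.ch_names,
                        rec.ch_pos, reference="average")
        return rec, ts, states

    def test_switch_count_never_increases(self):
        rec, ts, _ = self._noisy_alternation()
        ls = backfit(rec, ts)
        sm = smooth_labels(ls, rec, ts)
        assert sm.n_switches() <= ls.n_switches()

    def test_noise_flicker_removed(self):
        rec, ts, states = self._noisy_alternation()
        ls = backfit(rec, ts)
        sm = smooth_labels(ls, rec, ts)
        # long segments dominate after smoothing
        tab = sm.segment_table()
        frac_long = tab[tab.duration_ms >= 30]["duration_ms"].sum() / (
            tab["duration_ms"].sum()
        )
        assert frac_long > 0.9
        assert np.mean(sm.states == states) > np.mean(ls.states == states)

    def test_zero_penalty_is_identity(self):
        rec, ts, _ = self._noisy_alternation(1)
        ls = backfit(rec, ts)
        sm = smooth_labels(ls, rec, ts, besag=0.0)
        assert np.array_equal(sm.states, ls.states)

    def test_already_smooth_fixed_point(self):
        states = np.repeat([0, 1, 2, 3], 100)
        rec, ts = _template_recording(states)
        ls = backfit(rec, ts)
        sm = smooth_labels(ls, rec, ts)
        assert np.array_equal(sm.states, states)


class TestDropShortSegments:
    def test_short_between_identical_neighbors_absorbed(self):
        states = np.concatenate(
            [np.full(50, 0), np.full(10, 1), np.full(60, 0)]
        )
        rec, ts = _template_recording(states)
        ls = LabelSequence(states.copy(), 1000.0, [(0, 120)])
        out = drop_short_segments(ls, rec, ts, 30.0)
        assert np.all(out.states == 0)

    def test_all_long_segments_unchanged(self):
        states = np.concatenate(
            [np.full(50, 0), np.full(40, 1), np.full(50, 2)]
        )
        rec, ts = _template_recording(states)
        ls = LabelSequence(states.copy(), 1000.0, [(0, 140)])
        out = drop_short_segments(ls, rec, ts, 30.0)
        assert np.array_equal(out.states, states)

    def test_random_labels_leave_no_interior_shorts(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 4, 1000)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states.copy(), 1000.0, [(0, 500), (500, 1000)])
        out = drop_short_segments(ls, rec, ts, 30.0)
        tab = out.segment_table()
        interior = tab[~tab.is_edge & (tab.state != UNASSIGNED)]
        assert (interior.duration_ms >= 30.0).all()


class TestParameters:
    def test_single_adjacency_transition(self):
        states = np.array([0, 0, 1, 1])
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 4)])
        par = parameters(ls, rec, ts)
        expected = np.zeros((4, 4))
        expected[0, 1] = 1.0
        assert np.allclose(par.transition, expected)

    def test_coverage_partitions_assigned_time(self):
        rng = np.random.default_rng(4)
        states = np.repeat(rng.integers(0, 4, 12), 50)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 300), (300, 600)])
        par = parameters(ls, rec, ts)
        assert par.coverage_pct.sum() == pytest.approx(100.0)

    def test_occurrence_duration_coverage_identity(self):
        rng = np.random.default_rng(5)
        states = np.repeat(rng.integers(0, 4, 40), 60)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 1200), (1200, 2400)])
        par = parameters(ls, rec, ts, include_edge_in_duration=True)
        ms_per_s = np.nansum(par.duration_ms * par.occurrence_hz)
        assert ms_per_s == pytest.approx(10.0 * par.coverage_pct.sum(), rel=0.01)

    def test_noiseless_gev_is_one(self):
        states = np.repeat([0, 1, 2, 3], 50)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 200)])
        par = parameters(ls, rec, ts)
        assert par.gev == pytest.approx(1.0, abs=1e-12)

    def test_absent_state_reported_missing(self):
        states = np.repeat([0, 1], 100)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 200)])
        par = parameters(ls, rec, ts)
        assert np.isnan(par.duration_ms[3])
        assert par.occurrence_hz[3] == 0.0
        assert par.coverage_pct[3] == 0.0

    def test_gev_drops_with_random_templates(self):
        rng = np.random.default_rng(6)
        states = np.repeat([0, 1, 2, 3], 50)
        rec, ts = _template_recording(states)
        ls = LabelSequence(states, 1000.0, [(0, 200)])
        good = parameters(ls, rec, ts).gev
        bad_ts = TemplateSet(
            maps=rng.normal(size=(4, 64)), labels=list("ABCD")
        )
        bad = parameters(ls, rec, bad_ts).gev
        assert bad < good
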