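"""Ground-truth generator: templates, state paths, recordings, cohorts."""

import numpy as np
import pytest

from msdyn import TemplateSet, average_reference, backfit, find_gfp_peaks, gfp
from msdyn.synthetic import (
    empirical_jump_matrix,
    make_ground_truth,
    make_group_study,
    make_templates,
    sample_state_sequence,
    synthesize_recording,
    uniform_jump_matrix,
)


class TestTemplates:
    def test_normalization_and_separation(self):
        ts = make_templates(64, 4)
        assert np.allclose(ts.maps.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(ts.maps, axis=1), 1.0)
        R = np.abs(ts.maps @ ts.maps.T)
        np.fill_diagonal(R, 0.0)
        assert R.max() <= 0.7

    def test_orientations_for_canonical_four(self):
        # A tilts left-anterior, D is a pure anterior-posterior gradient
        from msdyn.montage import channel_positions, flat_positions

        ts = make_templates(64, 4)
        _, pos = channel_positions()
        xy = flat_positions(pos)
        a, d = ts.maps[0], ts.maps[3]
        # left-anterior sensors positive on A, right-posterior negative
        assert a[np.argmax(-xy[:, 0] + xy[:, 1])] > 0
        assert a[np.argmax(xy[:, 0] - xy[:, 1])] < 0
        # D increases monotonically with anterior coordinate (strong corr)
        assert np.corrcoef(d, xy[:, 1])[0, 1] > 0.95

    def test_deterministic_across_seeds(self):
        assert np.array_equal(
            make_templates(64, 4, seed=1).maps, make_templates(64, 4, seed=2).maps
        )

    def test_degenerate_single_map(self):
        ts = make_templates(64, 1)
        assert ts.maps.shape == (1, 64)
        assert abs(np.linalg.norm(ts.maps[0]) - 1) < 1e-12

    @pytest.mark.parametrize(
        "kwargs", [dict(k=0), dict(k=8), dict(n_channels=4), dict(geometry="nope")]
    )
    def test_invalid_requests_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_templates(**{"n_channels": 64, "k": 4, **kwargs})


class TestStateSequence:
    def test_dwell_mean_law_of_large_numbers(self):
        seq = sample_state_sequence(
            300.0, 1000.0, np.full(4, 80.0), uniform_jump_matrix(4), seed=1
        )
        change = np.flatnonzero(np.diff(seq)) + 1
        durations = np.diff(np.concatenate([[0], change, [len(seq)]]))
        assert len(durations) > 3000
        assert abs(durations.mean() - 80.0) / 80.0 < 0.05

    def test_forced_alternation(self):
        J = np.array([[0.0, 1.0], [1.0, 0.0]])
        seq = sample_state_sequence(60.0, 250.0, np.array([40.0, 40.0]), J, seed=2)
        change = np.flatnonzero(np.diff(seq)) + 1
        runs = seq[np.concatenate([[0], change])]
        assert np.all(runs[:-1] != runs[1:])

    def test_jump_matrix_convergence(self):
        # entrywise agreement within 5 binomial standard errors
        J = uniform_jump_matrix(4)
        seq = sample_state_sequence(300.0, 1000.0, np.full(4, 80.0), J, seed=3)
        emp = empirical_jump_matrix(seq, 4)
        n_jumps = np.count_nonzero(np.diff(seq)) / 4  # per origin state
        se = np.sqrt(J[0, 1] * (1 - J[0, 1]) / n_jumps)
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(emp - J)[off]) < 5 * se

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.5, 0.5], [1.0, 0.0]]),  # nonzero diagonal
            np.array([[0.0, 0.9], [1.0, 0.0]]),  # rows don't sum to 1
        ],
    )
    def test_invalid_jump_matrix(self, bad):
        with pytest.raises(ValueError):
            sample_state_sequence(10.0, 250.0, np.array([40.0, 40.0]), bad, 0)

    def test_dwell_below_two_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_state_sequence(
                10.0, 100.0, np.array([10.0, 40.0]), uniform_jump_matrix(2), 0
            )


class TestRecording:
    def test_noiseless_backfit_recovers_labels(self, truth_noiseless):
        truth = truth_noiseless
        rec = average_reference(synthesize_recording(truth, srate=250.0))
        ts = TemplateSet(maps=truth.templates, labels=list("ABCD"))
        ls = backfit(rec, ts)
        assigned = ls.states >= 0
        assert assigned.mean() > 0.99
        assert np.array_equal(
            ls.states[assigned], truth.label_seq[: rec.n_samples][assigned]
        )

    def test_snr4_peak_labels_match_truth(self, truth_snr4):
        truth = truth_snr4
        rec = average_reference(synthesize_recording(truth, srate=250.0))
        g = gfp(rec)
        peaks = find_gfp_peaks(g)
        ts = TemplateSet(maps=truth.templates, labels=list("ABCD"))
        ls = backfit(rec, ts)
        assert np.mean(ls.states[peaks] == truth.label_seq[peaks]) >= 0.95

    def test_gfp_peak_spacing_near_half_carrier_period(self, truth_noiseless):
        rec = average_reference(synthesize_recording(truth_noiseless, srate=250.0))
        peaks = find_gfp_peaks(gfp(rec))
        spacing_ms = np.diff(peaks) / 250.0 * 1000.0
        # 10 Hz carrier -> amplitude maxima every half period (50 ms);
        # segment-boundary phase resets add some shorter intervals
        assert 35.0 <= np.median(spacing_ms) <= 55.0

    def test_seeded_bit_reproducibility(self):
        a = synthesize_recording(make_ground_truth(12.0, srate=250.0, seed=5), 250.0)
        b = synthesize_recording(make_ground_truth(12.0, srate=250.0, seed=5), 250.0)
        assert np.array_equal(a.data, b.data)

    def test_short_duration_rejected(self):
        truth = make_ground_truth(12.0, srate=250.0, seed=5)
        with pytest.raises(ValueError):
            synthesize_recording(truth, srate=250.0, duration_s=5.0)


class TestGroupStudy:
    def test_truth_effects_and_design(self):
        b = make_group_study(
            n_per_group=(20, 20), seed=4, duration_s=20.0, synthesize=False
        )
        assert list(b.design.columns) == [
            "subject_id", "group", "lsas_total", "lsas_fear", "lsas_avoidance",
        ]
        dw = b.truth_dwell_frame().merge(
            b.design[["subject_id", "group"]], on="subject_id"
        )
        diff_c = dw[dw.group == "high"].C.mean() - dw[dw.group == "low"].C.mean()
        diff_d = dw[dw.group == "high"].D.mean() - dw[dw.group == "low"].D.mean()
        assert 10.0 < diff_c < 30.0  # generated +20 ms C contrast
        assert -35.0 < diff_d < -15.0  # generated -25 ms D contrast
        # scores separate the groups like a median split
        hi = b.design[b.design.group == "high"].lsas_total
        lo = b.design[b.design.group == "low"].lsas_total
        assert hi.mean() > lo.mean() + 30

    def test_scores_track_c_dwell_within_group(self):
        b = make_group_study(
            n_per_group=(40, 40), seed=9, synthesize=False,
            score_dwell_correlation=0.8,
        )
        dw = b.truth_dwell_frame().merge(b.design, on="subject_id")
        lo = dw[dw.group == "low"]
        r = np.corrcoef(lo.C, lo.lsas_total)[0, 1]
        assert r > 0.4

    def test_unknown_state_in_effect_spec(self):
        with pytest.raises(ValueError):
            make_group_study(effect_spec={"Q": 5.0}, synthesize=False)

    def test_minimal_design_runs(self):
        b = make_group_study(
            n_per_group=(2, 2), seed=1, duration_s=12.0, srate=250.0
        )
        assert len(b.recordings) == 4
        assert b.recordings[0].data.shape == (64, 3000)
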