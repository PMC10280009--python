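import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan.caller import (
    HIGH,
    LOW,
    NONE,
    CallerParams,
    call_introgressions,
    compute_call_track,
    denoise_seeds,
    extract_calls,
    fill_gaps,
    initial_call_gbs,
    initial_call_wgs,
    prune_short,
    read_track_table,
    write_track_table,
)
from introscan.coverage import CoverageProfile
from introscan.genome_windows import GenomeSpec, build_grid

from .conftest import grid_for, track_from_arrays
from .oracles import oracle_denoise, oracle_fill, oracle_prune

PARAMS = CallerParams()


def wgs_profile(values, window_size=10_000, sample="s"):
    grid = grid_for({"c1": len(values)}, window_size)
    return CoverageProfile(sample, grid, np.asarray(values, dtype=float))


class TestInitialCallWgs:
    def test_constant_profile_all_none(self):
        track = initial_call_wgs(wgs_profile([0.4] * 100))
        assert np.all(track.labels == NONE)

    def test_zero_mad_still_calls_outliers_low(self):
        # median 0.10, MAD 0: the ten depressed windows deviate by 0.08 > 0
        track = initial_call_wgs(wgs_profile([0.10] * 90 + [0.02] * 10))
        assert np.all(track.labels[:90] == NONE)
        assert np.all(track.labels[90:] == LOW)
        np.testing.assert_allclose(track.deviation[90:], -0.08)

    def test_zero_mad_calls_elevated_windows_high(self):
        track = initial_call_wgs(wgs_profile([0.10] * 90 + [0.30] * 10))
        assert np.all(track.labels[90:] == HIGH)

    def test_donor_windows_masked_and_excluded_from_median(self):
        grid = build_grid(
            [GenomeSpec("1A", 500_000, subgenome="A"),
             GenomeSpec("1R", 500_000, subgenome="R", is_donor=True)],
            10_000,
        )
        values = np.concatenate([np.full(50, 0.4), np.zeros(50)])
        track = initial_call_wgs(CoverageProfile("s", grid, values))
        assert np.all(track.labels == NONE)  # donor zeros never labeled LOW
        assert np.all(track.masked[50:])
        assert np.all(np.isnan(track.deviation[50:]))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="2 windows"):
            initial_call_wgs(wgs_profile([0.5]))


class TestInitialCallGbs:
    def _pair(self, sample_vals, ref_vals):
        grid = grid_for({"c1": len(sample_vals)})
        return (
            CoverageProfile("s", grid, np.asarray(sample_vals, dtype=float)),
            CoverageProfile("ref", grid, np.asarray(ref_vals, dtype=float)),
        )

    def test_identical_profiles_all_none(self):
        s, r = self._pair([0.5] * 50, [0.5] * 50)
        assert np.all(initial_call_gbs(s, r).labels == NONE)

    def test_median_normalization_cancels_scale(self):
        rng = np.random.default_rng(0)
        base = 0.2 + 0.1 * rng.random(60)
        s, r = self._pair(np.clip(base * 0.5, 0, 1), base)
        assert np.all(initial_call_gbs(s, r).labels == NONE)

    def test_thirty_percent_deficit_called_low(self):
        sample = [0.5] * 100
        sample[40] = 0.35
        s, r = self._pair(sample, [0.5] * 100)
        track = initial_call_gbs(s, r)
        assert track.labels[40] == LOW
        assert track.deviation[40] == pytest.approx(-0.30)
        assert np.sum(track.labels != NONE) == 1

    def test_reference_zero_windows_masked(self):
        ref = [0.5] * 100
        ref[7] = 0.0
        sample = [0.5] * 100
        sample[7] = 0.4
        s, r = self._pair(sample, ref)
        track = initial_call_gbs(s, r)
        assert track.masked[7] and track.labels[7] == NONE

    def test_zero_median_profile_rejected(self):
        s, r = self._pair([0.0] * 100, [0.5] * 100)
        with pytest.raises(ValueError, match="unusable"):
            initial_call_gbs(s, r)

    def test_grid_mismatch_rejected(self):
        s = CoverageProfile("s", grid_for({"c1": 10}), np.full(10, 0.5))
        r = CoverageProfile("r", grid_for({"c2": 10}), np.full(10, 0.5))
        with pytest.raises(ValueError, match="grid"):
            initial_call_gbs(s, r)


class TestRunSteps:
    def test_denoise_threshold_boundary(self):
        track = track_from_arrays({"c1": [LOW] * 4 + [NONE] * 10 + [LOW] * 5})
        out = denoise_seeds(track, PARAMS)
        assert np.all(out.labels[:4] == NONE)
        assert np.all(out.labels[14:] == LOW)

    def test_runs_do_not_span_chromosomes(self):
        # 3 LOW at end of c1 adjoining 3 LOW at start of c2: both erased
        track = track_from_arrays(
            {"c1": [NONE] * 7 + [LOW] * 3, "c2": [LOW] * 3 + [NONE] * 7}
        )
        out = denoise_seeds(track, PARAMS)
        assert np.all(out.labels == NONE)

    def test_denoise_all_none_unchanged(self):
        track = track_from_arrays({"c1": [NONE] * 20})
        assert np.all(denoise_seeds(track, PARAMS).labels == NONE)

    def test_gap_filled_when_signs_agree(self):
        labels = [LOW] * 5 + [NONE] * 3 + [LOW] * 5
        devs = [-0.1] * 5 + [-0.01, -0.02, -0.005] + [-0.1] * 5
        out = fill_gaps(track_from_arrays({"c1": labels}, {"c1": devs}), PARAMS)
        assert np.all(out.labels == LOW)

    def test_positive_deviation_blocks_filling(self):
        labels = [LOW] * 5 + [NONE] * 3 + [LOW] * 5
        devs = [-0.1] * 5 + [-0.01, +0.02, -0.005] + [-0.1] * 5
        out = fill_gaps(track_from_arrays({"c1": labels}, {"c1": devs}), PARAMS)
        assert np.all(out.labels[5:8] == NONE)

    def test_zero_deviation_blocks_filling(self):
        labels = [LOW] * 5 + [NONE] + [LOW] * 5
        devs = [-0.1] * 5 + [0.0] + [-0.1] * 5
        out = fill_gaps(track_from_arrays({"c1": labels}, {"c1": devs}), PARAMS)
        assert out.labels[5] == NONE

    def test_opposite_labels_never_bridged(self):
        labels = [LOW] * 5 + [NONE] * 3 + [HIGH] * 5
        devs = [-0.1] * 5 + [-0.1] * 3 + [0.1] * 5
        out = fill_gaps(track_from_arrays({"c1": labels}, {"c1": devs}), PARAMS)
        assert np.all(out.labels[5:8] == NONE)

    def test_prune_threshold_boundary(self):
        track = track_from_arrays({"c1": [HIGH] * 24 + [NONE] * 2 + [HIGH] * 25})
        out = prune_short(track, PARAMS)
        assert np.all(out.labels[:24] == NONE)
        assert np.all(out.labels[26:] == HIGH)

    def test_filled_run_still_below_call_size_is_pruned(self):
        # 5 + 3 + 5 = 13 windows < 25: survives fill, dies at prune
        labels = [LOW] * 5 + [NONE] * 3 + [LOW] * 5 + [NONE] * 20
        devs = [-0.1] * 13 + [0.01] * 20
        track = track_from_arrays({"c1": labels}, {"c1": devs})
        out = prune_short(fill_gaps(track, PARAMS), PARAMS)
        assert np.all(out.labels == NONE)

    @pytest.mark.parametrize("step", [denoise_seeds, prune_short])
    def test_run_erasure_is_idempotent(self, step):
        rng = np.random.default_rng(42)
        for _ in range(20):
            labels = rng.choice([LOW, NONE, HIGH], size=120)
            track = track_from_arrays({"c1": labels})
            once = step(track, PARAMS)
            twice = step(once, PARAMS)
            np.testing.assert_array_equal(once.labels, twice.labels)


label_vectors = st.lists(st.sampled_from([LOW, NONE, HIGH]), min_size=1, max_size=60)


class TestOracleAgreement:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(labels=label_vectors, data=st.data())
    def test_steps_match_brute_force_enumeration(self, labels, data):
        devs = [
            data.draw(st.sampled_from([-0.3, -0.01, 0.0, 0.01, 0.3, float("nan")]))
            for _ in labels
        ]
        track = track_from_arrays(
            {"c1": labels}, {"c1": devs}
        )
        p = CallerParams(min_seed_run=3, min_call_windows=6)
        step2 = denoise_seeds(track, p)
        assert step2.labels.tolist() == oracle_denoise(labels, 3)
        step3 = fill_gaps(step2, p)
        assert step3.labels.tolist() == oracle_fill(step2.labels.tolist(), devs)
        step4 = prune_short(step3, p)
        assert step4.labels.tolist() == oracle_prune(step3.labels.tolist(), 6)


class TestFullPipeline:
    def test_implanted_thirty_window_deficit_recovered_exactly(self):
        values = np.full(1000, 0.10)
        values[300:330] = 0.03
        calls = call_introgressions(wgs_profile(values.tolist()), "wgs")
        assert len(calls) == 1
        call = calls[0]
        assert (call.label, call.n_windows) == ("LOW", 30)
        assert (call.start, call.end) == (300 * 10_000, 330 * 10_000)
        assert call.size == 300_000

    def test_twenty_window_deficit_pruned(self):
        values = np.full(1000, 0.10)
        values[300:320] = 0.03
        assert call_introgressions(wgs_profile(values.tolist()), "wgs") == []

    def test_flat_profile_yields_no_calls(self):
        assert call_introgressions(wgs_profile([0.1] * 200), "wgs") == []

    def test_gbs_mode_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            call_introgressions(wgs_profile([0.1] * 50), "gbs")

    def test_calls_are_maximal_runs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = np.clip(0.1 + rng.normal(0, 0.03, 400), 0, 1)
            track = compute_call_track(wgs_profile(values.tolist()), "wgs")
            calls = extract_calls(track)
            calls.sort(key=lambda c: c.start)
            for a, b in zip(calls, calls[1:]):
                if a.label == b.label:
                    assert b.start > a.end  # same-label calls never adjacent

    def test_scale_invariance_wgs(self):
        rng = np.random.default_rng(7)
        values = np.clip(0.1 + rng.normal(0, 0.02, 500), 0, 1)
        values[100:140] = 0.02
        profile = wgs_profile(values.tolist())
        base = call_introgressions(profile, "wgs")
        scaled = call_introgressions(profile.scaled(3.7), "wgs")
        assert [(c.start, c.end, c.label) for c in base] == [
            (c.start, c.end, c.label) for c in scaled
        ]


class TestTrackTable:
    def test_round_trip(self, tmp_path):
        values = np.full(100, 0.10)
        values[10:50] = 0.03
        track = compute_call_track(wgs_profile(values.tolist()), "wgs")
        path = tmp_path / "track.tsv"
        write_track_table(track, path)
        back = read_track_table(path, track.grid)
        np.testing.assert_array_equal(back.labels, track.labels)
        np.testing.assert_allclose(back.values, track.values)
        np.testing.assert_allclose(back.deviation, track.deviation)
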