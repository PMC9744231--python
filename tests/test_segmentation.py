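"""HMM segmentation, peak calling and chromatin classification."""
import numpy as np
import pytest

from ubiquifold import (
    ChromatinDomain,
    CoverageTrack,
    PointPeak,
    call_point_peaks,
    classify_chromatin,
    segment_accessibility,
    segment_three_state,
    simulate_coverage,
)
from ubiquifold.segmentation import merge_short_segments

from conftest import base_level_agreement


def make_track(values, bin_size=200, mark="H3K27me3"):
    values = np.asarray(values, dtype=float)
    genome = {"chr2L": values.size * bin_size}
    return CoverageTrack(
        genome=genome, bin_size=bin_size, values={"chr2L": values}, mark=mark
    )


class TestSegmentThreeState:
    def test_planted_levels_recovered_within_two_bins(self):
        rng = np.random.default_rng(21)
        mult = np.ones(2000)
        mult[400:600] = 8.0  # high domain
        mult[1000:1150] = 3.0  # intermediate domain
        track = make_track(rng.poisson(10.0 * mult))
        domains = segment_three_state(track)
        high = [d for d in domains if d.label == "high"]
        inter = [d for d in domains if d.label == "intermediate"]
        assert len(high) == 1 and len(inter) == 1
        assert abs(high[0].start // 200 - 400) <= 2
        assert abs(high[0].end // 200 - 600) <= 2
        assert abs(inter[0].start // 200 - 1000) <= 2
        assert abs(inter[0].end // 200 - 1150) <= 2

    def test_constant_track_single_background_domain(self):
        track = make_track(np.full(500, 7.0))
        with pytest.warns(UserWarning, match="constant"):
            domains = segment_three_state(track)
        assert len(domains) == 1
        assert domains[0].label == "none"
        assert (domains[0].start, domains[0].end) == (0, 500 * 200)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        mult = np.ones(1000)
        mult[200:300] = 8.0
        vals = rng.poisson(10.0 * mult)
        d1 = segment_three_state(make_track(vals))
        d2 = segment_three_state(make_track(vals))
        assert [(d.start, d.end, d.label) for d in d1] == [
            (d.start, d.end, d.label) for d in d2
        ]

    def test_domains_tile_genome(self):
        rng = np.random.default_rng(4)
        mult = np.ones(1500)
        mult[100:400] = 8.0
        track = make_track(rng.poisson(10.0 * mult))
        domains = segment_three_state(track)
        pos = 0
        for d in domains:
            assert d.start == pos
            pos = d.end
        assert pos == track.genome["chr2L"]


class TestMergeShortSegments:
    def test_gap_between_high_domains_absorbed(self):
        """Two high runs separated by one background bin merge into one
        high domain when the minimum length is 3 bins."""
        states = np.array([2] * 10 + [0] + [2] * 10)
        logs = np.array([4.4] * 10 + [2.3] + [4.4] * 10)
        merged = merge_short_segments(states, logs, np.array([2.3, 3.4, 4.4]), 3)
        assert np.all(merged == 2)

    def test_exhaustive_oracle_on_tiny_instance(self):
        """The merge rule must send each short run to the flanking level
        whose emission mean is closer to the run's observed mean."""
        state_means = np.array([0.0, 1.0, 2.0])
        states = np.array([0] * 5 + [1] * 2 + [2] * 5)
        # observed mean of the short middle run sits close to the right flank
        logs = np.array([0.0] * 5 + [1.8] * 2 + [2.0] * 5)
        merged = merge_short_segments(states, logs, state_means, 3)
        assert list(merged) == [0] * 5 + [2] * 7
        # and close to the left flank when the data say so
        logs2 = np.array([0.0] * 5 + [0.2] * 2 + [2.0] * 5)
        merged2 = merge_short_segments(states, logs2, state_means, 3)
        assert list(merged2) == [0] * 7 + [2] * 5

    def test_long_runs_untouched(self):
        states = np.array([0] * 10 + [2] * 10)
        logs = np.array([0.0] * 10 + [2.0] * 10)
        out = merge_short_segments(states, logs, np.array([0.0, 1.0, 2.0]), 3)
        assert np.array_equal(out, states)


class TestSegmentAccessibility:
    def test_planted_high_accessibility_recovered(self):
        rng = np.random.default_rng(31)
        mult = np.ones(1500)
        mult[300:400] = 10.0
        track = make_track(rng.poisson(10.0 * mult), mark="ATAC")
        domains = segment_accessibility(track)
        high = [d for d in domains if d.label == "high"]
        assert len(high) == 1
        assert high[0].overlap(300 * 200, 400 * 200) >= 0.9 * 100 * 200

    def test_three_levels_strictly_ordered(self):
        rng = np.random.default_rng(32)
        mult = np.ones(2000)
        mult[400:600] = 10.0
        mult[1200:1400] = 3.5
        track = make_track(rng.poisson(10.0 * mult), mark="ATAC")
        domains = segment_accessibility(track)
        mean_of = {
            lbl: np.mean([d.mean_level for d in domains if d.label == lbl])
            for lbl in ("low", "intermediate", "high")
        }
        assert mean_of["high"] > mean_of["intermediate"] > mean_of["low"]

    def test_constant_track_single_low_domain(self):
        with pytest.warns(UserWarning):
            domains = segment_accessibility(make_track(np.full(300, 5.0)))
        assert [d.label for d in domains] == ["low"]


class TestCallPointPeaks:
    def test_single_hot_bin(self):
        vals = np.full(1000, 10.0)
        vals[500] = 500.0
        peaks = call_point_peaks(make_track(vals, mark="Pho"))
        assert len(peaks) == 1
        assert peaks[0].summit // 200 == 500
        assert peaks[0].q_value < 0.01

    def test_uniform_track_no_peaks(self):
        assert call_point_peaks(make_track(np.full(2000, 10.0), mark="Pho")) == []

    def test_poisson_background_controls_fdr(self):
        rng = np.random.default_rng(41)
        peaks = call_point_peaks(make_track(rng.poisson(10.0, 5000), mark="Pho"))
        assert len(peaks) == 0

    def test_two_close_pres_stay_separate(self, planted_genome):
        params, annotation, _, truth = planted_genome
        track, _ = simulate_coverage(
            annotation, params, "Pho", "wt", pre_positions=truth.pre_positions
        )
        peaks = call_point_peaks(track, merge_distance=1000)
        called = sorted(p.summit for p in peaks)
        expected = sorted(p for _, p in truth.pre_positions)
        assert len(called) == len(expected)
        for got, want in zip(called, expected):
            assert abs(got - want) <= params.bin_size

    def test_merge_distance_joins_adjacent_bins(self):
        vals = np.full(1000, 10.0)
        vals[500] = 400.0
        vals[502] = 350.0
        peaks = call_point_peaks(make_track(vals, mark="Pho"), merge_distance=1000)
        assert len(peaks) == 1
        assert peaks[0].summit // 200 == 500  # summit at the higher bin


class TestClassifyChromatin:
    def domains(self, spec):
        return [ChromatinDomain("chr2L", s, e, lbl) for s, e, lbl in spec]

    def test_high_with_pho_is_canonical(self):
        k27 = self.domains([(0, 10_000, "none"), (10_000, 30_000, "high"),
                            (30_000, 50_000, "none")])
        pho = [PointPeak("chr2L", 20_000, 30.0, 1e-6)]
        ann = classify_chromatin(k27, pho, [])
        assert ann.label_at("chr2L", 20_000) == "canonical"

    def test_intermediate_without_pho_is_noncanonical(self):
        k27 = self.domains([(0, 10_000, "none"), (10_000, 30_000, "intermediate"),
                            (30_000, 50_000, "none")])
        ann = classify_chromatin(k27, [], [])
        assert ann.label_at("chr2L", 20_000) == "noncanonical"

    def test_high_without_pho_flagged_noncanonical(self):
        k27 = self.domains([(0, 10_000, "none"), (10_000, 30_000, "high"),
                            (30_000, 50_000, "none")])
        ann = classify_chromatin(k27, [], [])
        dom = [d for d in ann if d.start == 10_000][0]
        assert dom.label == "noncanonical" and dom.flagged

    def test_no_marks_is_neutral(self):
        ann = classify_chromatin(self.domains([(0, 50_000, "none")]), [], [])
        assert ann.class_lengths() == {"neutral": 50_000}

    def test_k36_subinterval_becomes_active(self):
        k27 = self.domains([(0, 100_000, "none")])
        k36 = self.domains(
            [(0, 40_000, "none"), (40_000, 60_000, "high"), (60_000, 100_000, "none")]
        )
        ann = classify_chromatin(k27, [], k36)
        assert ann.label_at("chr2L", 50_000) == "active"
        assert ann.label_at("chr2L", 20_000) == "neutral"
        assert ann.is_partition()

    def test_output_is_partition(self, planted_genome):
        params, annotation, _, truth = planted_genome
        k27, _ = simulate_coverage(annotation, params, "H3K27me3", "wt")
        k36, _ = simulate_coverage(annotation, params, "H3K36me2", "wt")
        pho, _ = simulate_coverage(
            annotation, params, "Pho", "wt", pre_positions=truth.pre_positions
        )
        called = classify_chromatin(
            segment_three_state(k27),
            call_point_peaks(pho),
            segment_three_state(k36),
        )
        assert called.is_partition()
        assert base_level_agreement(annotation, called) >= 0.95
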