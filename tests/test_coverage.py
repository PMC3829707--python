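"""Coverage quantification: normalization, CV, DP segmentation, filtering."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycleseq import coverage
from cycleseq.coverage import (
    CoverageExperiment,
    compute_cv,
    filter_segments,
    normalize_split,
    quantify_experiment,
    quantify_genes,
    segment_signal,
)


def brute_force_rss(values: np.ndarray, k: int) -> float:
    """Minimal piecewise-constant RSS with exactly k segments, by
    enumerating every changepoint placement."""

    def seg_rss(chunk):
        return float(np.sum((chunk - chunk.mean()) ** 2))

    n = len(values)
    best = np.inf
    for cps in combinations(range(1, n), k - 1):
        bounds = [0, *cps, n]
        rss = sum(
            seg_rss(values[bounds[i] : bounds[i + 1]]) for i in range(k)
        )
        best = min(best, rss)
    return best


def two_track_experiment(plus, minus=None, n_reps=3, n_tp=1):
    """Experiment with given per-replicate plus-strand tracks."""
    plus = [np.asarray(p, dtype=float) for p in plus]
    n = len(plus[0])
    if minus is None:
        minus = [np.zeros(n) for _ in plus]
    tracks = {}
    for t in range(n_tp):
        for r in range(n_reps):
            tracks[(t, r, "+")] = plus[r].copy()
            tracks[(t, r, "-")] = np.asarray(minus[r], dtype=float).copy()
    ann = pd.DataFrame(
        [{"gene_id": "g0", "start": 0, "end": n, "strand": "+", "dup_group": -1}]
    )
    return CoverageExperiment(tracks, ann, n)


class TestNormalizeSplit:
    def test_equalizes_replicate_sums(self):
        exp = two_track_experiment([np.full(10, 10.0), np.full(10, 30.0),
                                    np.full(10, 20.0)])
        out = normalize_split(exp)
        sums = [out.tracks[(0, r, "+")].sum() for r in range(3)]
        assert np.allclose(sums, 200.0)

    def test_identical_replicates_unchanged(self):
        exp = two_track_experiment([np.full(10, 7.0)] * 3)
        out = normalize_split(exp)
        for r in range(3):
            assert np.allclose(out.tracks[(0, r, "+")], 7.0)

    def test_high_gene_does_not_distort_bulk_scaling(self):
        # 5 bulk genes equal in all replicates; one high gene huge in rep 0
        n = 600
        tracks = {}
        for r in range(3):
            plus = np.full(n, 10.0)
            plus[500:600] = 5000.0 if r == 0 else 2000.0
            tracks[(0, r, "+")] = plus
            tracks[(0, r, "-")] = np.zeros(n)
        ann = pd.DataFrame(
            [
                {"gene_id": f"g{i}", "start": i * 100, "end": (i + 1) * 100,
                 "strand": "+", "dup_group": -1}
                for i in range(6)
            ]
        )
        exp = CoverageExperiment(tracks, ann, n)
        out = normalize_split(exp, split_threshold=1000.0)
        # bulk footprint was identical across replicates -> stays identical
        for r in range(3):
            assert np.allclose(out.tracks[(0, r, "+")][:500], 10.0)

    def test_zero_replicate_raises_with_name(self):
        exp = two_track_experiment(
            [np.full(10, 5.0), np.zeros(10), np.full(10, 5.0)]
        )
        with pytest.raises(ValueError, match="replicate"):
            normalize_split(exp)


class TestComputeCv:
    @pytest.mark.parametrize(
        "reps,expected",
        [((10, 10, 10), 0.0), ((1, 2, 3), 0.5), ((0, 0, 0), 0.0)],
    )
    def test_hand_computed(self, reps, expected):
        exp = two_track_experiment([np.full(5, float(v)) for v in reps])
        cv = compute_cv(exp, 0)
        assert np.allclose(cv["+"], expected)

    def test_single_replicate_rejected(self):
        exp = two_track_experiment([np.full(5, 1.0)], n_reps=1)
        with pytest.raises(ValueError, match="replicates"):
            compute_cv(exp, 0)


class TestSegmentation:
    def test_clean_step(self):
        seg = segment_signal(np.array([1, 1, 1, 5, 5, 5.0]), 2)
        assert seg.changepoints.tolist() == [0, 3, 6]
        assert seg.segment_means.tolist() == [1.0, 5.0]

    def test_constant_sequence_one_segment(self):
        seg = segment_signal(np.full(20, 3.3), 4)
        assert seg.n_segments == 1

    def test_max_segments_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            seg = segment_signal(np.array([1.0, 2.0]), 5)
        assert seg.n_segments <= 2

    def test_dp_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            values = rng.normal(size=n)
            k = int(rng.integers(1, min(4, n) + 1))
            rss, _ = coverage._dp_segment(values, k)
            assert rss[k - 1] == pytest.approx(
                brute_force_rss(values, k), abs=1e-9
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10),
        st.integers(1, 3),
    )
    def test_dp_optimal_on_arbitrary_inputs(self, values, k):
        values = np.asarray(values)
        k = min(k, len(values))
        rss, _ = coverage._dp_segment(values, k)
        assert rss[k - 1] <= brute_force_rss(values, k) + 1e-6


class TestFilterSegments:
    def test_low_cv_everything_retained(self):
        seg = segment_signal(np.full(30, 0.2), 3)
        assert filter_segments(seg, 1.0).all()

    def test_high_cv_segment_discarded(self):
        values = np.concatenate([np.full(10, 0.2), np.full(10, 1.5),
                                 np.full(10, 0.2)])
        seg = segment_signal(values, 4)
        keep = filter_segments(seg, 1.0)
        assert not keep[10:20].any()
        assert keep[:10].all() and keep[20:].all()

    def test_zero_threshold_keeps_only_zero_cv(self):
        values = np.concatenate([np.zeros(10), np.full(10, 0.3)])
        seg = segment_signal(values, 2)
        keep = filter_segments(seg, 0.0)
        assert keep[:10].all() and not keep[10:].any()


class TestQuantify:
    def test_mean_over_retained(self):
        exp = two_track_experiment([np.full(100, 10.0)] * 3)
        keep = np.zeros(100, dtype=bool)
        keep[:50] = True
        m = quantify_genes(exp, {0: {"+": keep, "-": np.ones(100, bool)}})
        assert np.allclose(m.values.loc["g0"], 10.0)
        assert m.retained_fraction["g0"] == pytest.approx(0.5)

    def test_discarded_high_coverage_excluded(self):
        track = np.concatenate([np.full(50, 10.0), np.full(50, 1000.0)])
        exp = two_track_experiment([track] * 3)
        keep = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        m = quantify_genes(exp, {0: {"+": keep, "-": np.ones(100, bool)}})
        assert np.allclose(m.values.loc["g0"], 10.0)

    def test_no_retained_falls_back_flagged(self):
        exp = two_track_experiment([np.full(10, 4.0)] * 3)
        m = quantify_genes(
            exp, {0: {"+": np.zeros(10, bool), "-": np.zeros(10, bool)}}
        )
        assert np.allclose(m.values.loc["g0"], 4.0)
        assert bool(m.fallback_flag["g0"])

    def test_gene_outside_bounds_rejected(self):
        exp = two_track_experiment([np.full(10, 1.0)] * 3)
        exp.annotation.loc[0, "end"] = 99
        with pytest.raises(ValueError, match="outside"):
            quantify_genes(
                exp, {0: {"+": np.ones(10, bool), "-": np.ones(10, bool)}}
            )

    def test_quantification_linear_in_coverage(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(20, size=100).astype(float)
        exp1 = two_track_experiment([base, base * 1.1, base * 0.9])
        exp3 = two_track_experiment(
            [3 * base, 3 * base * 1.1, 3 * base * 0.9]
        )
        m1 = quantify_experiment(exp1, normalize=False)
        m3 = quantify_experiment(exp3, normalize=False)
        assert np.allclose(m3.values.values, 3 * m1.values.values)


class TestZeroNoise:
    def test_everything_retained_and_exact(self, noiseless_sim):
        exp = noiseless_sim.experiment
        m = quantify_experiment(exp, normalize=False)
        assert m.retained_fraction.min() == pytest.approx(1.0)
        truth = noiseless_sim.truth_expression
        got = m.timepoint_means.loc[truth.index]
        got.columns = truth.columns
        pd.testing.assert_frame_equal(got, truth, rtol=1e-9)

    def test_replicates_identical(self, noiseless_sim):
        exp = noiseless_sim.experiment
        for t in exp.timepoints:
            cv = compute_cv(exp, t)
            assert np.allclose(cv["+"], 0.0) and np.allclose(cv["-"], 0.0)


class TestIo:
    def test_gff3_roundtrip(self, tmp_path, small_sim):
        path = tmp_path / "genes.gff3"
        coverage.write_gff3(small_sim.experiment.annotation, path)
        back = coverage.read_gff3(path)
        pd.testing.assert_frame_equal(
            back, small_sim.experiment.annotation.reset_index(drop=True)
        )

    def test_bedgraph_roundtrip(self, tmp_path):
        track = np.array([0, 0, 1.5, 1.5, 3, 0, 0, 2.25])
        path = tmp_path / "t.bedgraph"
        coverage.write_bedgraph(track, path)
        assert np.allclose(coverage.read_bedgraph(path, len(track)), track)
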