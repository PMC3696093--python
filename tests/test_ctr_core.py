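"""Transition statistic, bootstrap null, candidate scan and refinement."""

import math

import numpy as np
import pytest

from ctrics import (GenomeTable, Interval, IntervalSet, ScoreParams,
                    background_correct, bootstrap_threshold, call_ctrs,
                    filter_unmappable, find_candidates, refine_ctr, t_score,
                    t_statistic)
from ctrics.ctr_core import ORIENT_EH, ORIENT_HE, CtrCall, EdgeError, scan_t

from conftest import make_track


def naive_t(vec, i, N):
    """Direct-slicing oracle for the transition statistic."""
    L = float(np.mean(vec[i - N:i]))
    R = float(np.mean(vec[i + 1:i + N + 1]))
    d = min(L, R) if min(L, R) > 0 else 1.0 / N
    return (math.sqrt(L) - math.sqrt(R)) / math.sqrt(d)


class TestTStatistic:
    def test_symmetric_flanks_give_zero(self):
        assert t_statistic(5.0, 5.0, 20) == 0.0

    def test_four_vs_one(self):
        # (sqrt(4) - sqrt(1)) / sqrt(1) = 1
        assert t_statistic(4.0, 1.0, 20) == pytest.approx(1.0)

    def test_zero_min_uses_one_over_N(self):
        # (1 - 0) / sqrt(1/20) = sqrt(20)
        assert t_statistic(1.0, 0.0, 20) == pytest.approx(math.sqrt(20))

    def test_t_score_requires_full_flanks(self):
        track = make_track({"chr1": np.ones(50, dtype=np.int64)})
        with pytest.raises(EdgeError):
            t_score(track, "chr1", 5, N=20)

    def test_scan_matches_naive_recomputation(self, rng):
        # streaming cumulative-sum scan vs direct flank means, exact
        for _ in range(20):
            M = int(rng.integers(41, 400))
            vec = rng.poisson(rng.uniform(0.5, 6.0), M)
            idx, L, R, T = scan_t(vec, 20)
            assert idx[0] == 20 and idx[-1] == M - 21
            for k in rng.choice(idx.size, size=min(25, idx.size), replace=False):
                i = idx[k]
                assert T[k] == pytest.approx(naive_t(vec, i, 20), abs=1e-12)

    def test_antisymmetry_under_mirroring(self, rng):
        for _ in range(20):
            vec = rng.poisson(2.0, int(rng.integers(50, 300)))
            _, _, _, T = scan_t(vec, 20)
            _, _, _, Tm = scan_t(vec[::-1], 20)
            np.testing.assert_allclose(T, -Tm[::-1], atol=1e-12)


class TestBackgroundCorrect:
    def test_self_normalization(self):
        chip = make_track({"chr1": np.array([2, 3, 0, 5])})
        out = background_correct(chip, chip)
        np.testing.assert_array_equal(out.values["chr1"], [1.0, 1.0, 0.0, 1.0])
        assert out.value_kind == "normalized"

    def test_zero_control_guard(self):
        chip = make_track({"chr1": np.array([6, 0])})
        ctrl = make_track({"chr1": np.array([0, 6])})
        out = background_correct(chip, ctrl)
        assert out.values["chr1"][0] == pytest.approx(6.0)

    def test_matches_scalar_formula_oracle(self, rng):
        n_t = rng.poisson(3.0, 200)
        n_c = rng.poisson(2.0, 200)
        n_c[0] = 0
        chip = make_track({"chr1": n_t})
        ctrl = make_track({"chr1": n_c})
        out = background_correct(chip, ctrl)
        depth = n_t.sum() / n_c.sum()
        for i in rng.choice(200, 50, replace=False):
            expected = n_t[i] / (max(n_c[i], 1) * depth)
            assert out.values["chr1"][i] == pytest.approx(expected)

    def test_mismatched_grids_rejected(self):
        chip = make_track({"chr1": np.ones(10, dtype=np.int64)})
        ctrl = make_track({"chr1": np.ones(12, dtype=np.int64)})
        with pytest.raises(ValueError, match="grid"):
            background_correct(chip, ctrl)

    def test_proportional_control_gives_constant_track(self, rng):
        v = rng.poisson(5.0, 300) + 1  # strictly positive
        chip = make_track({"chr1": v})
        ctrl = make_track({"chr1": 3 * v})
        out = background_correct(chip, ctrl)
        vals = out.values["chr1"]
        np.testing.assert_allclose(vals, vals[0])


class TestBootstrap:
    def test_pvalue_one_gives_minimum(self, rng):
        track = make_track({"chr1": rng.poisson(2.0, 500)})
        params = ScoreParams(n_boot=10_000, p_value=0.999999, seed=3)
        null = bootstrap_threshold(track, params)
        assert null.threshold <= np.quantile(null.abs_t, 0.01)

    def test_constant_track_gives_zero_threshold(self):
        track = make_track({"chr1": np.full(200, 4, dtype=np.int64)})
        null = bootstrap_threshold(track, ScoreParams(n_boot=10_000, seed=1))
        assert null.threshold == 0.0

    def test_matches_independent_resampler(self, rng):
        """Chunked vectorized bootstrap vs a plain python re-implementation
        of the same resampling scheme, compared on the tail quantile."""
        vec = rng.poisson(2.0, 100)
        track = make_track({"chr1": vec})
        params = ScoreParams(n_boot=100_000, p_value=0.01, seed=5)
        null = bootstrap_threshold(track, params)
        oracle_rng = np.random.default_rng(999)
        ts = []
        for _ in range(100_000):
            L = vec[oracle_rng.integers(0, 100, 20)].mean()
            R = vec[oracle_rng.integers(0, 100, 20)].mean()
            d = min(L, R) if min(L, R) > 0 else 1 / 20
            ts.append(abs((math.sqrt(L) - math.sqrt(R)) / math.sqrt(d)))
        oracle_thr = np.quantile(ts, 0.99)
        assert null.threshold == pytest.approx(oracle_thr, rel=0.05)

    def test_threshold_monotone_in_pvalue(self, rng):
        track = make_track({"chr1": rng.poisson(2.0, 1000)})
        null = bootstrap_threshold(track, ScoreParams(n_boot=50_000, seed=2))
        t1 = null.threshold_at(0.0001)
        t2 = null.threshold_at(0.001)
        t3 = null.threshold_at(0.01)
        assert t1 >= t2 >= t3


def step_track(n_before=200, n_after=200, low=0.0, high=10.0):
    vec = np.concatenate([np.full(n_before, low), np.full(n_after, high)])
    return make_track({"chr1": vec.astype(float)}, value_kind="normalized")


class TestCandidatesAndRefinement:
    def test_flat_track_yields_no_candidates(self, quick_params):
        track = make_track({"chr1": np.full(300, 3, dtype=np.int64)})
        null = bootstrap_threshold(track, quick_params)
        assert find_candidates(track, null, quick_params) == []

    def test_ideal_step_gives_one_candidate_near_step(self, quick_params):
        track = step_track()
        null = bootstrap_threshold(track, quick_params)
        cands = find_candidates(track, null, quick_params)
        assert len(cands) == 1
        assert abs(cands[0].anchor - 200) <= quick_params.N

    def test_enrichment_gate_blocks_weak_transition(self, quick_params):
        # a 0 -> 0.5 step on a genome whose average is 1.0: |T| is huge but
        # neither flank reaches 1.5x the genome average, so no candidate
        vec = np.concatenate([np.zeros(100), np.full(100, 0.5), np.full(800, 1.125)])
        track = make_track({"chr1": vec}, value_kind="normalized")
        null = bootstrap_threshold(track, quick_params)
        gate = quick_params.enrich_fold * track.genome_mean()
        idx, L, R, T = scan_t(vec, quick_params.N)
        step = (idx > 80) & (idx < 120)
        assert np.abs(T[step]).max() >= null.threshold  # transition is strong
        assert not np.any(np.maximum(L[step], R[step]) >= gate)
        cands = find_candidates(track, null, quick_params)
        assert all(not (80 < c.anchor < 120) for c in cands)

    def test_refined_ctr_abuts_ideal_step(self, quick_params):
        track = step_track()
        null = bootstrap_threshold(track, quick_params)
        cands = find_candidates(track, null, quick_params)
        call = refine_ctr(track, cands[0], quick_params, null)
        # step at bp 40000 (window 200); either abutting window is exact
        assert call.start in (199 * 200, 200 * 200)
        assert call.orientation == ORIENT_EH
        assert call.T < 0

    def test_mirrored_step_swaps_orientation(self, quick_params):
        track = step_track()
        mirrored = make_track({"chr1": track.values["chr1"][::-1].copy()},
                              value_kind="normalized")
        null = bootstrap_threshold(mirrored, quick_params)
        cands = find_candidates(mirrored, null, quick_params)
        call = refine_ctr(mirrored, cands[0], quick_params, null)
        assert call.orientation == ORIENT_HE
        assert call.T > 0

    def test_candidate_at_chromosome_edge_dropped(self, quick_params):
        from ctrics.ctr_core import Candidate
        track = make_track({"chr1": np.ones(45, dtype=np.int64)})
        cand = Candidate(chrom="chr1", anchor=1, first=1, last=1,
                         T_anchor=2.0, abs_t_max=2.0)
        # span [anchor-N, anchor+N] clipped to eligible range is empty
        assert refine_ctr(track, cand, ScoreParams(N=30, n=3, n_boot=10_000)) is None


class TestFilterUnmappable:
    def _call(self, chrom, start):
        return CtrCall(chrom, start, start + 200, ORIENT_EH, 1.0, 1.0, 0.001)

    def test_empty_set_is_identity(self):
        calls = [self._call("chr1", 1000)]
        assert filter_unmappable(calls, IntervalSet("um", [])) == calls

    def test_exactly_4kb_retained(self):
        # interval [10000, 10500); call midpoint at 10500+? choose midpoint
        # exactly 4000 bp left of the interval start
        call = self._call("chr1", 5900)  # midpoint 6000; 10000 - 6000 = 4000
        um = IntervalSet("um", [Interval("chr1", 10_000, 10_500)])
        assert filter_unmappable([call], um) == [call]
        closer = self._call("chr1", 6000)  # midpoint 6100, distance 3900
        assert filter_unmappable([closer], um) == []

    def test_matches_quadratic_oracle(self, rng):
        calls = [self._call("chr1", int(s)) for s in rng.integers(0, 200_000, 60)]
        ivs = IntervalSet("um", [Interval("chr1", int(s), int(s) + int(l))
                                 for s, l in zip(rng.integers(0, 200_000, 25),
                                                 rng.integers(100, 5000, 25))])
        kept = filter_unmappable(calls, ivs, min_dist=4000)
        expected = []
        for c in calls:
            m = c.midpoint
            ok = True
            for iv in ivs:
                d = max(iv.start - m, m - (iv.end - 1), 0)
                if d < 4000:
                    ok = False
            if ok:
                expected.append(c)
        assert kept == expected


class TestFullPipeline:
    def test_two_runs_same_seed_identical(self, tmp_path):
        from ctrics import SynthConfig, generate
        from ctrics.synth import write_bed
        cfg = SynthConfig(chrom_lengths=(("chrS1", 1_000_000),), n_domains=2, seed=9)
        treat, _, _ = generate(cfg)
        bed = write_bed(treat, tmp_path / "t.bed")
        params = ScoreParams(n_boot=20_000, seed=4)
        calls1, null1 = call_ctrs(bed, cfg.genome(), params)
        calls2, null2 = call_ctrs(bed, cfg.genome(), params)
        assert calls1 == calls2
        assert null1.threshold == null2.threshold
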