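import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episcan import (
    BetaMatrix,
    EpimutationRegion,
    ScanParams,
    SimulationConfig,
    adjust_fdr,
    annotate_islands,
    call_regions,
    classify_region,
    scan_cohort,
    simulate_cohort,
    single_case_test,
)
from episcan.scan import OutlierResult
from episcan.simulate import evaluate_calls


def bh_oracle(p: list[float]) -> list[float]:
    """Brute-force Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j)·m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def make_beta(columns: dict[str, list[float]]) -> BetaMatrix:
    n = len(next(iter(columns.values())))
    return BetaMatrix(
        pd.DataFrame(columns, index=[f"S{i:02d}" for i in range(n)])
    )


class TestSingleCaseTest:
    def test_value_at_rest_mean_gives_null(self):
        rng = np.random.default_rng(0)
        rest = rng.beta(10, 10, size=20)
        col = np.concatenate([[rest.mean()], rest])
        bm = make_beta({"cg1": np.clip(col, 0, 1).tolist()})
        res = single_case_test(bm, "S00", "cg1")
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_rest_hits_sd_floor(self):
        bm = make_beta({"cg1": [0.9] + [0.1] * 15})
        res = single_case_test(bm, "S00", "cg1")
        assert res.rest_sd == 1e-6
        assert res.direction == "hyper"
        assert res.p < 1e-30

    def test_printed_monoallelic_case_statistic(self):
        # carrier β 0.34 against 45 rest values with mean 0.05, sd 0.02:
        # t = 0.29 / (0.02·sqrt(46/45)) ≈ 14.34, df = 44
        rng = np.random.default_rng(42)
        rest = rng.uniform(size=45)  # bounded support keeps β in [0, 1]
        rest = (rest - rest.mean()) / rest.std(ddof=1) * 0.02 + 0.05
        bm = make_beta({"cg1": [0.34] + rest.tolist()})
        res = single_case_test(bm, "S00", "cg1")
        expected_t = 0.29 / (0.02 * np.sqrt(46 / 45))
        assert res.t_stat == pytest.approx(expected_t, rel=1e-10)
        assert res.t_stat == pytest.approx(14.34, abs=0.01)
        # p against numerical integration of the t density
        from scipy.integrate import quad
        tail, _ = quad(lambda u: stats.t.pdf(u, 44), res.t_stat, np.inf)
        assert res.p == pytest.approx(2 * tail, rel=1e-6)

    def test_untestable_when_rest_too_small(self):
        bm = make_beta({"cg1": [0.5] * 8})
        assert single_case_test(bm, "S00", "cg1", min_rest_n=10) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(12, 40))
    def test_equals_pooled_two_sample_t(self, seed, n):
        """Single-case t is a pooled two-sample t with group sizes 1 and n."""
        rng = np.random.default_rng(seed)
        col = rng.random(n + 1)
        bm = make_beta({"cg1": col.tolist()})
        res = single_case_test(bm, "S00", "cg1")
        t2, p2 = stats.ttest_ind([col[0]], col[1:], equal_var=True)
        assert res.t_stat == pytest.approx(float(t2), abs=1e-10)
        assert res.p == pytest.approx(float(p2), abs=1e-10)


class TestAdjustFdr:
    def test_single_and_tied_p_pass_through(self):
        np.testing.assert_allclose(adjust_fdr([0.03]), [0.03])
        np.testing.assert_allclose(adjust_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_nan_propagates_and_empty_ok(self):
        q = adjust_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert adjust_fdr([]).size == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([0.001, 0.01, 0.05, 0.2, 0.5, 0.8, 1.0]),
                 min_size=1, max_size=8)
    )
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(adjust_fdr(p), bh_oracle(p), atol=1e-12)


def _result(sample, probe, beta_self, rest_mean, q):
    return OutlierResult(
        sample=sample, probe=probe, beta_self=beta_self, rest_mean=rest_mean,
        rest_sd=0.02, n_rest=45, t_stat=10.0, df=44, p=q / 10, q=q,
    )


class TestCallRegions:
    def test_two_probes_below_min_run(self, small_manifest):
        results = [_result("S1", f"cg{i}", 0.4, 0.05, 0.001) for i in (0, 1)]
        results += [_result("S1", f"cg{i}", 0.05, 0.05, 0.9) for i in (2, 3, 4)]
        assert call_regions(results, small_manifest) == []

    def test_five_probe_run_called_once(self, small_manifest):
        results = [_result("S1", f"cg{i}", 0.4, 0.05, 0.001) for i in range(5)]
        regions = call_regions(results, small_manifest)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_probes == 5
        assert (r.chrom, r.start, r.end) == ("chr1", 99, 500)
        assert r.direction == "hyper"

    def test_direction_flip_breaks_run(self, small_manifest):
        results = [
            _result("S1", "cg0", 0.4, 0.05, 0.001),
            _result("S1", "cg1", 0.01, 0.5, 0.001),  # hypo in the middle
            _result("S1", "cg2", 0.4, 0.05, 0.001),
        ]
        assert call_regions(results, small_manifest) == []

    def test_chromosome_boundary_breaks_run(self, small_manifest):
        results = [_result("S1", f"cg{i}", 0.4, 0.05, 0.001) for i in (3, 4, 5, 6)]
        # cg3/cg4 on chr1, cg5/cg6 on chr2: neither side reaches 3 probes
        assert call_regions(results, small_manifest) == []

    def test_max_gap_splits_runs(self):
        manifest_df = pd.DataFrame(
            {"probe_id": [f"cg{i}" for i in range(6)],
             "chrom": ["chr1"] * 6,
             "pos": [100, 200, 300, 5_000, 5_100, 5_200]}
        )
        from episcan import ProbeManifest
        manifest = ProbeManifest(manifest_df)
        results = [_result("S1", f"cg{i}", 0.4, 0.05, 0.001) for i in range(6)]
        assert len(call_regions(results, manifest, max_gap=None)) == 1
        assert len(call_regions(results, manifest, max_gap=1_000)) == 2

    def test_unknown_probe_is_hard_error(self, small_manifest):
        with pytest.raises(KeyError, match="cgZZ"):
            call_regions([_result("S1", "cgZZ", 0.4, 0.05, 0.001)], small_manifest)

    def test_untestable_probe_does_not_break_adjacency(self, small_manifest):
        # cg1 untestable (absent): cg0, cg2, cg3 are adjacent testable probes
        results = [_result("S1", f"cg{i}", 0.4, 0.05, 0.001) for i in (0, 2, 3)]
        regions = call_regions(results, small_manifest)
        assert len(regions) == 1
        assert regions[0].probe_ids == ["cg0", "cg2", "cg3"]


def region(carrier, rest, direction="hyper"):
    return EpimutationRegion(
        sample="S1", chrom="chr1", start=0, end=100, probe_ids=["a", "b", "c"],
        mean_beta_carrier=carrier, mean_beta_rest=rest, min_q=1e-5, max_q=1e-3,
        direction=direction,
    )


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "carrier,rest,expected",
        [
            (0.34, 0.05, "monoallelic"),  # the printed monoallelic case
            (0.18, 0.03, "mosaic"),  # the printed mosaic case
            (0.26, 0.05, "monoallelic"),
            (0.2499, 0.05, "mosaic"),
            (0.09, 0.05, "low_level"),
        ],
    )
    def test_bands_on_carrier_mean(self, carrier, rest, expected):
        assert classify_region(region(carrier, rest)) == expected

    def test_hypo_and_high_background_pass_through(self):
        assert classify_region(region(0.1, 0.5, "hypo")) == "hypomethylated"
        assert classify_region(region(0.5, 0.3)) == "low_level"


class TestAnnotateIslands:
    def test_overlap_and_half_open_touching(self, small_islands):
        inside = region(0.3, 0.05)
        inside.chrom, inside.start, inside.end = "chr1", 120, 250
        touching = region(0.3, 0.05)
        # ends exactly where the island starts: half-open -> no overlap
        touching.chrom, touching.start, touching.end = "chr1", 50, 99
        annotate_islands([inside, touching], small_islands)
        assert inside.islands == ["CGI_A"]
        assert touching.islands == []

    def test_region_spanning_two_islands(self):
        from episcan import IslandSet
        islands = IslandSet(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 200], "end": [100, 300],
                 "name": ["I1", "I2"]}
            )
        )
        r = region(0.3, 0.05)
        r.chrom, r.start, r.end = "chr1", 50, 250
        annotate_islands([r], islands)
        assert r.islands == ["I1", "I2"]


class TestScanCohort:
    def test_null_cohort_yields_no_regions(self):
        cfg = SimulationConfig(seed=9, n_probes=3_000, spikes=[])
        beta, manifest, islands, _ = simulate_cohort(cfg)
        assert scan_cohort(beta, manifest, islands) == []

    def test_single_spike_recovered_exactly(self, default_cohort):
        beta, manifest, islands, truth = default_cohort
        regions = scan_cohort(beta, manifest, islands)
        rec, fp = evaluate_calls(regions, truth)
        assert rec == 1 and fp == 0
        r = regions[0]
        assert r.sample == truth.records[0].carrier
        assert set(r.probe_ids) == set(truth.records[0].probe_ids)
        assert r.classification == "monoallelic"
        assert truth.records[0].island_name in r.islands

    def test_sample_permutation_invariance(self):
        cfg = SimulationConfig(seed=4, n_probes=1_500, n_samples=20)
        beta, manifest, islands, _ = simulate_cohort(cfg)
        regions = scan_cohort(beta, manifest, islands)
        rng = np.random.default_rng(0)
        perm = rng.permutation(beta.n_samples)
        shuffled = BetaMatrix(beta.values.iloc[perm])
        regions2 = scan_cohort(shuffled, manifest, islands)
        key = lambda r: (r.sample, r.chrom, r.start, tuple(r.probe_ids))
        assert [key(r) for r in regions] == [key(r) for r in regions2]

    def test_monotonic_in_min_run_and_q_threshold(self, default_cohort):
        beta, manifest, islands, _ = default_cohort
        counts_run = [
            len(scan_cohort(beta, manifest, islands, ScanParams(min_run=k)))
            for k in (3, 4, 5, 6)
        ]
        assert counts_run == sorted(counts_run, reverse=True)
        counts_q = [
            len(scan_cohort(beta, manifest, islands, ScanParams(q_threshold=q)))
            for q in (0.05, 0.005, 0.0005)
        ]
        assert counts_q == sorted(counts_q, reverse=True)

    def test_small_cohort_rejected(self):
        cfg = SimulationConfig(seed=1, n_probes=300, n_samples=12)
        beta, manifest, islands, _ = simulate_cohort(cfg)
        small = BetaMatrix(beta.values.iloc[:8])
        with pytest.raises(ValueError, match="12 samples"):
            scan_cohort(small, manifest, islands)

    def test_missing_values_excluded_from_rest(self):
        # one missing rest value at the tested probe changes nothing else
        rng = np.random.default_rng(2)
        col = rng.beta(10, 190, size=20).tolist()
        bm = make_beta({"cg1": [0.4] + col[1:]})
        res_full = single_case_test(bm, "S00", "cg1")
        vals = bm.values.copy()
        vals.loc["S05", "cg1"] = np.nan
        res_drop = single_case_test(BetaMatrix(vals), "S00", "cg1")
        assert res_drop.n_rest == res_full.n_rest - 1
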