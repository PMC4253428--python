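"""Caller filter cascade: quality/strand thresholds, germline removal,
recurrence flagging, coverage and mutation-rate arithmetic."""
import numpy as np
import pytest

from surfscan.calling import (call_variants, coverage_summary, filter_germline,
                              flag_recurrent, mutation_rate, normalize_variant)
from surfscan.config import CallerThresholds
from surfscan.errors import SurfscanError
from surfscan.pileup import Observation, PileupSite

from oracles import random_sites, scan_calls


def make_site(ref="A", alt="T", n_fwd=3, n_rev=3, bq=30, mq=30, n_ref=10,
              pos=100, indel=None):
    obs = []
    for _ in range(n_ref):
        obs.append(Observation(ref, 40, 60, "+"))
    for strand, n in (("+", n_fwd), ("-", n_rev)):
        for _ in range(n):
            base = ref if indel else alt
            obs.append(Observation(base, bq, mq, strand, indel))
    return PileupSite("chr1", pos, ref, tuple(obs))


class TestThresholds:
    @pytest.mark.parametrize("kwargs,expect_call", [
        (dict(n_fwd=3, n_rev=3, bq=30, mq=30), True),   # meets the 3+3 HQ rule
        (dict(n_fwd=5, n_rev=0), False),                # one-strand support only
        (dict(n_fwd=3, n_rev=3, bq=24), False),         # base quality below 25
        (dict(n_fwd=3, n_rev=3, mq=19), False),         # map quality below 20
        (dict(n_fwd=2, n_rev=3), False),                # 2 < 3 on one strand
        (dict(n_fwd=3, n_rev=3, bq=25, mq=20), True),   # inclusive boundaries
    ])
    def test_per_strand_rule(self, kwargs, expect_call):
        calls = call_variants([make_site(**kwargs)], CallerThresholds(), "CL")
        assert bool(calls) is expect_call

    @pytest.mark.parametrize("n_fwd,n_rev,expect_call", [
        (2, 1, True), (1, 2, True), (3, 0, False), (0, 3, False), (1, 1, False),
    ])
    def test_total_with_both_strands_rule(self, n_fwd, n_rev, expect_call):
        thr = CallerThresholds(strand_mode="total_with_both_strands")
        calls = call_variants([make_site(n_fwd=n_fwd, n_rev=n_rev)], thr, "CL")
        assert bool(calls) is expect_call

    def test_indel_alleles_vcf_style(self):
        ins = call_variants([make_site(indel="+AT")], CallerThresholds(), "CL")[0]
        assert (ins.ref, ins.alt, ins.var_type) == ("A", "AAT", "INS")
        dele = call_variants([make_site(indel="-GG")], CallerThresholds(), "CL")[0]
        assert (dele.ref, dele.alt, dele.var_type) == ("AGG", "A", "DEL")

    def test_support_and_depth_recorded(self):
        c = call_variants([make_site(n_fwd=4, n_rev=3)], CallerThresholds(), "CL")[0]
        assert (c.fwd_hq_support, c.rev_hq_support, c.depth) == (4, 3, 17)

    def test_matches_bruteforce_scanner_on_random_pileups(self):
        rng = np.random.default_rng(2024)
        for mode in ("per_strand", "total_with_both_strands"):
            thr = CallerThresholds(strand_mode=mode)
            for _ in range(20):
                sites = random_sites(rng, 10)
                got = {(c.contig, c.position, c.ref, c.alt, c.var_type)
                       for c in call_variants(sites, thr, "CL")}
                want = scan_calls(sites, thr.min_base_quality, thr.min_map_quality,
                                  thr.min_support_per_strand, mode)
                assert got == want

    def test_raising_thresholds_never_adds_calls(self):
        rng = np.random.default_rng(7)
        sites = random_sites(rng, 40)
        base = CallerThresholds(min_base_quality=10, min_map_quality=10,
                                min_support_per_strand=1)
        n0 = len(call_variants(sites, base, "CL"))
        for tweak in (dict(min_base_quality=20), dict(min_map_quality=20),
                      dict(min_support_per_strand=2)):
            thr = CallerThresholds(**{**dict(min_base_quality=10, min_map_quality=10,
                                             min_support_per_strand=1), **tweak})
            assert len(call_variants(sites, thr, "CL")) <= n0


class TestGermlineFilter:
    def test_exact_match_flagged_and_removed(self):
        calls = call_variants([make_site()], CallerThresholds(), "CL")
        somatic = filter_germline(calls, {("chr1", 100, "A", "T")})
        assert somatic == [] and "germline" in calls[0].flags

    def test_allele_aware_matching(self):
        calls = call_variants([make_site(alt="G")], CallerThresholds(), "CL")
        somatic = filter_germline(calls, {("chr1", 100, "A", "T")})
        assert len(somatic) == 1 and not calls[0].flags

    def test_empty_db_keeps_everything(self):
        calls = call_variants([make_site()], CallerThresholds(), "CL")
        assert filter_germline(calls, set()) == calls

    def test_unnormalized_representations_match(self):
        # same 1-base deletion in a TT run, two anchorings
        seq = "GGTTA" + "C" * 95
        p1 = normalize_variant(3, "TT", "T", seq)
        p2 = normalize_variant(2, "GT", "G", seq)
        assert p1 == p2

    def test_left_shift_of_insertion(self):
        seq = "GAAAC"
        # A-insertion given at the right edge of the A-run vs at its left edge
        assert normalize_variant(4, "A", "AA", seq) == normalize_variant(2, "A", "AA", seq)


class TestRecurrence:
    def _calls(self, lines, pos=100):
        out = {}
        for cl in lines:
            out[cl] = call_variants([make_site(pos=pos)], CallerThresholds(), cl)
        return out

    def test_gt_k_lines_excluded_unless_whitelisted(self):
        by_line = self._calls(["A", "B", "C", "D"])
        kept = flag_recurrent(by_line, k=3)
        assert all(kept[cl] == [] for cl in by_line)
        assert all("recurrent_suspect" in by_line[cl][0].flags for cl in by_line)

    def test_whitelisted_hotspot_retained(self):
        by_line = self._calls(["A", "B", "C", "D"])
        kept = flag_recurrent(by_line, k=3, whitelist=[("chr1", 100, "A", "T")])
        assert all(len(kept[cl]) == 1 for cl in by_line)
        assert "whitelisted" in by_line["A"][0].flags

    def test_exactly_k_lines_untouched(self):
        by_line = self._calls(["A", "B", "C"])
        kept = flag_recurrent(by_line, k=3)
        assert all(len(kept[cl]) == 1 and not by_line[cl][0].flags for cl in by_line)


class TestCoverageAndRate:
    def _sites(self, depths, start=1):
        return [PileupSite("chr1", start + i, "A",
                           tuple(Observation("A", 30, 30, "+") for _ in range(d)))
                for i, d in enumerate(depths)]

    def test_uniform_depth(self):
        stats = coverage_summary(self._sites([30] * 10), [("chr1", 0, 10)])
        assert stats.mean_depth == 30.0
        assert stats.pct_covered == 100.0 and stats.pct_covered_10x == 100.0

    def test_half_uncovered(self):
        stats = coverage_summary(self._sites([20] * 5), [("chr1", 0, 10)])
        assert stats.pct_covered == 50.0 and stats.mean_depth == 10.0

    def test_depth_exactly_10_counts_as_10x(self):
        stats = coverage_summary(self._sites([10]), [("chr1", 0, 1)])
        assert stats.pct_covered_10x == 100.0

    def test_empty_target_rejected(self):
        with pytest.raises(SurfscanError):
            coverage_summary([], [])

    @pytest.mark.parametrize("n,expected", [(41, 6.72e-06), (43, 7.05e-06), (0, 0.0)])
    def test_rate_over_panel_target(self, n, expected):
        assert mutation_rate(n, 6_101_190) == pytest.approx(expected, rel=5e-3)

    def test_rate_requires_positive_target(self):
        with pytest.raises(SurfscanError):
            mutation_rate(1, 0)
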