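"""Epitope logic: windowing laws, PSSM scorers, cleavage gate and the
uniqueness / differential decision rule."""
import math

import numpy as np
import pytest

from surfscan.config import ScorerConfig
from surfscan.epitopes import (AMINO_ACIDS, PeptidePair, affinity_ic50,
                               call_mutated_epitopes, cleavage_ok, enumerate_9mers,
                               extract_peptides, packaged_pssm, percent_optimum)
from surfscan.errors import ScoringError


def profile_matrix(default=1.0, **residue_values) -> np.ndarray:
    """9x20 matrix whose columns are constant across positions."""
    vals = {aa: residue_values.get(aa, default) for aa in AMINO_ACIDS}
    return np.tile(np.array([vals[a] for a in AMINO_ACIDS]), (9, 1)).astype(float)


def pair(ref, mut, origin="missense", offset=None):
    if offset is None:
        offset = next(i for i, (a, b) in enumerate(zip(ref, mut)) if a != b)
    return PeptidePair("G", "CL", "chr1:1:A>C", origin, ref, mut, offset)


ALWAYS = lambda w, c: True


class TestWindowing:
    @pytest.mark.parametrize("length,expected", [(21, 13), (9, 1), (8, 0), (0, 0)])
    def test_window_count_law(self, length, expected):
        assert len(enumerate_9mers("A" * length)) == expected

    def test_mutation_overlapping_windows_of_centered_21mer(self):
        ref = "A" * 21
        mut = ref[:10] + "C" + ref[11:]
        pssm = profile_matrix(default=5.0, G=0.0)
        cfg = ScorerConfig(percent_optimum_threshold=1, ic50_threshold=50000)
        calls = call_mutated_epitopes(pair(ref, mut), pssm, cfg, ALWAYS)
        assert len(calls) == 9
        assert [c.window_start for c in calls] == list(range(2, 11))

    def test_missense_pair_extraction_centred(self):
        from surfscan.consequence import ConsequenceRecord, Variant

        ref_prot = "".join(AMINO_ACIDS[i % 20] for i in range(200))
        mut_prot = ref_prot[:49] + ("W" if ref_prot[49] != "W" else "Y") + ref_prot[50:]
        rec = ConsequenceRecord(Variant("chr1", 1, "A", "C"), "G", "missense",
                                codon_index=49)
        p = extract_peptides(rec, ref_prot, mut_prot)
        assert len(p.mutant_peptide) == 21 and p.mutation_offset == 10

    def test_missense_near_n_terminus_truncates_left(self):
        from surfscan.consequence import ConsequenceRecord, Variant

        ref_prot = "MAAAAAAAAAAAAAAAAAAA"
        mut_prot = ref_prot[:3] + "W" + ref_prot[4:]
        rec = ConsequenceRecord(Variant("chr1", 1, "A", "C"), "G", "missense",
                                codon_index=3)
        p = extract_peptides(rec, ref_prot, mut_prot)
        assert len(p.mutant_peptide) == 14 and p.mutation_offset == 3

    def test_synonymous_leak_yields_no_pair(self):
        from surfscan.consequence import ConsequenceRecord, Variant

        prot = "MAAAAAAAAAAA"
        rec = ConsequenceRecord(Variant("chr1", 1, "A", "C"), "G", "missense",
                                codon_index=5)
        assert extract_peptides(rec, prot, prot) is None


class TestScorers:
    def test_optimal_peptide_scores_100(self):
        pssm = profile_matrix(default=1.0, L=7.0)
        assert percent_optimum("L" * 9, pssm) == pytest.approx(100.0)

    def test_uniform_matrix_everything_100(self):
        pssm = profile_matrix(default=3.0)
        assert percent_optimum("ACDEFGHIK", pssm) == pytest.approx(100.0)

    def test_matches_manual_position_sum(self):
        rng = np.random.default_rng(11)
        pssm = rng.uniform(0.1, 5.0, size=(9, 20))
        pep = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 9))
        manual = sum(pssm[i, AMINO_ACIDS.index(a)] for i, a in enumerate(pep))
        expected = 100.0 * manual / pssm.max(axis=1).sum()
        assert percent_optimum(pep, pssm) == pytest.approx(expected)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ScoringError):
            percent_optimum("AAAAAAAAX", profile_matrix())
        with pytest.raises(ScoringError):
            percent_optimum("AAAA", profile_matrix())

    def test_ic50_closed_forms(self):
        pssm = profile_matrix(default=1.0, G=0.0, L=7.0)
        assert affinity_ic50("L" * 9, pssm) == pytest.approx(1.0)        # x = 1
        assert affinity_ic50("G" * 9, pssm) == pytest.approx(50000.0)    # x = 0
        # algebraic boundary: x = 1 - ln(500)/ln(50000)  ->  exactly 500 nM
        xb = 1 - math.log(500) / math.log(50000)
        pssm2 = profile_matrix(default=7.0 * xb, G=0.0, L=7.0)
        assert affinity_ic50("A" * 9, pssm2) == pytest.approx(500.0)

    def test_ic50_strictly_decreasing_in_score(self):
        pssm = profile_matrix(default=1.0, G=0.0, L=7.0, A=3.0, C=4.0)
        assert affinity_ic50("C" * 9, pssm) < affinity_ic50("A" * 9, pssm)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ScoringError):
            affinity_ic50("A" * 9, profile_matrix(default=2.0))  # max == min

    def test_packaged_matrix_loads(self):
        pssm = packaged_pssm()
        assert pssm.shape == (9, 20)
        assert 0 < percent_optimum("LLLLLLLLL", pssm) <= 100


class TestCleavage:
    @pytest.mark.parametrize("pep,expected", [
        ("AAAAAAAAL", True), ("AAAAAAAAK", True), ("AAAAAAAAP", False),
        ("AAAAAAAAD", False),
    ])
    def test_default_cterm_rule(self, pep, expected):
        assert cleavage_ok(pep) is expected

    def test_custom_predictor_overrides(self):
        assert cleavage_ok("AAAAAAAAP", predictor=lambda w, c: True) is True


class TestDecisions:
    def test_frameshift_novel_window_called_unique(self):
        # novel tail absent from the reference peptide's 9-mer set
        ref = "AAAAAAAAAA"
        mut = "AAAAA" + "LLLLLLLLL"
        p = pair(ref, mut, origin="frameshift", offset=5)
        pssm = profile_matrix(default=4.5, G=0.0, L=9.0)
        calls = call_mutated_epitopes(p, pssm, ScorerConfig(), ALWAYS)
        uniq = [c for c in calls if c.decision == "called_unique"]
        assert uniq, "expected at least one unique novel epitope"
        assert all(c.reference_peptide is None for c in uniq)

    def test_percent_optimum_50_binds(self):
        # all-A peptide sits exactly at 50% of the optimum
        pssm = profile_matrix(default=4.5, G=0.0, L=9.0)
        assert percent_optimum("A" * 9, pssm) == pytest.approx(50.0)
        p = pair("C", "C" + "A" * 9, origin="frameshift", offset=1)
        calls = call_mutated_epitopes(p, pssm, ScorerConfig(), ALWAYS)
        win = next(c for c in calls if c.peptide == "A" * 9)
        assert win.decision == "called_unique"

    def test_ic50_just_over_500_rejected(self):
        # solve for a residue value giving pct = 50 but IC50 ~ 501 nM
        x501 = 1 - math.log(501) / math.log(50000)
        smax = 81.0
        s = smax / 2                       # pct exactly 50
        smin = (s - x501 * smax) / (1 - x501)
        pssm = profile_matrix(default=s / 9, G=smin / 9, L=smax / 9)
        assert percent_optimum("A" * 9, pssm) == pytest.approx(50.0)
        assert affinity_ic50("A" * 9, pssm) == pytest.approx(501.0, rel=1e-6)
        p = pair("C", "C" + "A" * 9, origin="frameshift", offset=1)
        calls = call_mutated_epitopes(p, pssm, ScorerConfig(), ALWAYS)
        win = next(c for c in calls if c.peptide == "A" * 9)
        assert win.decision == "rejected"

    def test_differential_ratio_exactly_1_2_passes_ge_semantics(self):
        # S_ref = 15, S_mut = 18: both scorer ratios >= 1.2
        pssm = profile_matrix(default=0.0, A=6.0, M=9.0, L=9.0)
        ref = "GGGGAGGGL"
        mut = "GGGGMGGGL"
        cfg = ScorerConfig(percent_optimum_threshold=20, ic50_threshold=50000)
        calls = call_mutated_epitopes(pair(ref, mut), pssm, cfg, ALWAYS)
        assert calls[0].percent_optimum / calls[0].ref_percent_optimum == \
            pytest.approx(1.2)
        assert calls[0].decision == "called_differential"
        strict = ScorerConfig(percent_optimum_threshold=20, ic50_threshold=50000,
                              strict_differential=True)
        calls = call_mutated_epitopes(pair(ref, mut), pssm, strict, ALWAYS)
        assert calls[0].decision == "rejected"

    def test_differential_requires_both_scorers(self):
        # inflate the reference percent-optimum so only the IC50 ratio passes
        pssm = profile_matrix(default=0.0, A=6.0, M=6.5, L=9.0)
        calls = call_mutated_epitopes(pair("GGGGAGGGL", "GGGGMGGGL"), pssm,
                                      ScorerConfig(percent_optimum_threshold=5,
                                                   ic50_threshold=50000), ALWAYS)
        r1 = calls[0].percent_optimum / calls[0].ref_percent_optimum
        assert r1 < 1.2  # scorer 1 fails the factor
        assert calls[0].decision == "rejected"

    def test_called_differential_implies_both_ratios(self):
        rng = np.random.default_rng(3)
        cfg = ScorerConfig(percent_optimum_threshold=10, ic50_threshold=49000)
        for _ in range(30):
            pssm = rng.uniform(0.0, 10.0, (9, 20))
            ref = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 15))
            k = int(rng.integers(0, 15))
            sub = AMINO_ACIDS[int(rng.integers(0, 20))]
            if sub == ref[k]:
                continue
            mut = ref[:k] + sub + ref[k + 1:]
            for c in call_mutated_epitopes(pair(ref, mut, offset=k), pssm, cfg, ALWAYS):
                if c.decision == "called_differential":
                    assert c.percent_optimum >= 1.2 * c.ref_percent_optimum
                    assert (1 / c.ic50) >= 1.2 * (1 / c.ref_ic50)

    def test_identical_inputs_identical_calls(self):
        pssm = packaged_pssm()
        p = pair("GGGGAGGGL", "GGGGMGGGL")
        c1 = call_mutated_epitopes(p, pssm)
        c2 = call_mutated_epitopes(p, pssm)
        assert c1 == c2


class TestExpressionGate:
    def test_flag_attached_per_line(self):
        from surfscan.epitopes import EpitopeCall, gate_epitope_expression
        from surfscan.integration import ExpressionFlags

        call = EpitopeCall("A" * 9, 0, 60.0, 100.0, True, None, None, None,
                           "called_unique")
        flags = ExpressionFlags({("G", "CL1"): True, ("G", "CL2"): False},
                                {"G": True})
        assert gate_epitope_expression([call], "G", "CL1", flags)[0].expressed is True
        assert gate_epitope_expression([call], "G", "CL2", flags)[0].expressed is False
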