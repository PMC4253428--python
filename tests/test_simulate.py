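"""Generator contracts: reference/gene-model structure, variant spiking,
pileup evidence, expression boundaries and verdict fabrication."""
import numpy as np
import pytest

from surfscan.config import SimConfig
from surfscan.errors import ConfigError, LookupError_
from surfscan.genes import translate_cds
from surfscan.pileup import parse_pileup
from surfscan.simulate import (STOPS, fabricate_impact_verdicts, generate_reference,
                               simulate_expression, simulate_pileup, spike_variants)


class TestGenerateReference:
    def test_gene_model_structure(self, small_panel):
        reference, models, _ = small_panel
        seq = reference["chr1"]
        assert len(models) == 12
        spans = []
        for m in models:
            assert m.cds_len % 3 == 0
            cds = m.cds_sequence(seq)
            assert cds.startswith("ATG")
            assert cds[-3:] in STOPS
            prot = m.protein(seq)
            assert prot.startswith("M") and "*" not in prot
            assert all(0 <= s < e <= len(seq) for s, e in m.exons)
            spans.append(m.span)
        # genes laid out without overlap
        spans.sort()
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_genes=5, n_cell_lines=2, seed=3)
        r1, m1 = generate_reference(cfg)
        r2, m2 = generate_reference(cfg)
        assert r1 == r2 and m1 == m2

    @pytest.mark.parametrize("bad", [
        dict(n_genes=0), dict(n_cell_lines=0), dict(vaf=0.0), dict(vaf=1.5),
        dict(somatic_load_mutator=5, somatic_load_normal=10),
        dict(indel_fraction=1.2), dict(mean_cds_length=12),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            SimConfig(**bad).validate()


class TestSpikeVariants:
    def test_germline_somatic_disjoint_and_consistent(self, small_panel):
        reference, models, truth = small_panel
        seq = reference["chr1"]
        germ_pos = {v.position for v in truth.germline}
        som_pos = {v.position for vs in truth.somatic.values() for v in vs}
        assert not germ_pos & som_pos
        cds_pos = {p for m in models for s, e in m.exons for p in range(s, e)}
        for vs in truth.somatic.values():
            for v in vs:
                assert seq[v.position - 1:v.position - 1 + len(v.ref)] == v.ref
                assert v.position - 1 in cds_pos
                if v.var_type != "SNV":
                    assert len(v.ref) != len(v.alt)

    def test_mutator_lines_carry_higher_load(self):
        mut_means, norm_means = [], []
        for seed in range(10):
            cfg = SimConfig(n_cell_lines=2, n_genes=20, mutator_fraction=0.5,
                            somatic_load_mutator=100, somatic_load_normal=10,
                            seed=seed)
            reference, models = generate_reference(cfg)
            truth = spike_variants(reference, models, cfg)
            for cl, vs in truth.somatic.items():
                (mut_means if truth.mutator_flags[cl] else norm_means).append(len(vs))
        assert np.mean(mut_means) > np.mean(norm_means)


class TestSimulatePileup:
    def test_spiked_snv_support_on_both_strands(self):
        cfg = SimConfig(n_cell_lines=2, n_genes=6, depth_mean=200, vaf=0.5,
                        error_rate=0.0, seed=5)
        reference, models = generate_reference(cfg)
        truth = spike_variants(reference, models, cfg)
        cl = sorted(truth.somatic)[0]
        snv_pos = {v.position: v.alt for v in truth.somatic[cl] if v.var_type == "SNV"}
        sites = {s.position: s for s in
                 parse_pileup(simulate_pileup(reference, models, truth, cfg, cl))}
        assert snv_pos, "fixture must spike at least one SNV"
        for pos, alt in snv_pos.items():
            obs = sites[pos].observations
            fwd = sum(1 for o in obs if o.base == alt and o.strand == "+")
            rev = sum(1 for o in obs if o.base == alt and o.strand == "-")
            assert fwd >= 3 and rev >= 3

    def test_non_variant_sites_all_reference(self, small_panel, small_config):
        reference, models, truth = small_panel
        cl = sorted(truth.somatic)[0]
        var_pos = {v.position for v in truth.germline} | \
                  {v.position for v in truth.somatic[cl]}
        del_span = set()
        for v in [*truth.germline, *truth.somatic[cl]]:
            if v.var_type == "DEL":
                del_span.update(range(v.position + 1, v.position + len(v.ref)))
        for site in parse_pileup(simulate_pileup(reference, models, truth,
                                                 small_config, cl)):
            if site.position in var_pos or site.position in del_span:
                continue
            assert all(o.base == site.ref_base and o.indel is None
                       for o in site.observations)

    def test_same_seed_identical_text(self, small_panel, small_config):
        reference, models, truth = small_panel
        cl = sorted(truth.somatic)[0]
        t1 = list(simulate_pileup(reference, models, truth, small_config, cl))
        t2 = list(simulate_pileup(reference, models, truth, small_config, cl))
        assert t1 == t2

    def test_unknown_cell_line_rejected(self, small_panel, small_config):
        reference, models, truth = small_panel
        with pytest.raises(LookupError_):
            next(simulate_pileup(reference, models, truth, small_config, "NOPE"))


class TestExpressionAndVerdicts:
    def test_boundary_fixtures(self, small_panel, small_config):
        _, models, _ = small_panel
        expr = simulate_expression(models, small_config)
        g1 = expr[expr.gene_id == "GENE001"]
        assert all((g1.platform == "rnaseq") == (g1.value == 3.0))
        assert all((g1.platform == "array") == (g1.value == 5.5))
        g2 = expr[expr.gene_id == "GENE002"]
        assert set(g2.value) <= {2.999, 5.49}  # strictly below both thresholds

    def test_expressed_fraction_realised(self, small_panel):
        _, models, _ = small_panel
        cfg = SimConfig(n_cell_lines=4, n_genes=12, fraction_expressed=0.5, seed=1)
        expr = simulate_expression(models, cfg)
        thr = expr.platform.map({"rnaseq": 3.0, "array": 5.5})
        frac = (expr.value >= thr).mean()
        assert 0.25 < frac < 0.75

    def test_full_agreement_verdicts(self, small_panel, small_config):
        _, _, truth = small_panel
        verdicts, hidden = fabricate_impact_verdicts(truth, 1.0, small_config)
        hidden_map = {(r.cell_line, r.variant_key): r.truth_impact
                      for r in hidden.itertuples(index=False)}
        for (cl, key), grp in verdicts.groupby(["cell_line", "variant_key"]):
            assert set(grp.verdict) == {hidden_map[(cl, key)]}
            if set(grp.var_class) <= {"frameshift", "inframe_indel"}:
                assert list(grp.algorithm) == ["sift"]
            else:
                assert sorted(grp.algorithm) == ["mutation_assessor", "polyphen2", "sift"]
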