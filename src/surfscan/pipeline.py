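"""File-based pipeline stages: simulate -> call -> annotate -> integrate ->
epitopes -> report.

Every stage reads and writes plain-text formats (FASTA, BED, VCF, mpileup
text, TSV) in a single run directory, so the CLI subcommands, the numbered
analysis scripts and the tests all drive the same code.  All randomness
flows from ``SimConfig.seed``; no stage records wall-clock state, so two
runs with the same seed produce byte-identical output trees.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from . import __version__
from .calling import (VariantCall, call_variants, coverage_summary, filter_germline,
                      flag_recurrent, load_germline_db, CoverageStats)
from .config import CallerThresholds, ScorerConfig, SimConfig, dump_yaml_config
from .consequence import (Variant, annotate_variant, classify_consequence,
                          mutant_protein)
from .epitopes import (call_mutated_epitopes, extract_peptides, load_pssm,
                       packaged_pssm, gate_epitope_expression)
from .errors import StageError
from .genes import GeneModel, read_bed, read_gene_table, write_bed, write_gene_table
from .integration import gate_expression, novel_genes, recurrence_summary
from .pileup import parse_pileup
from .report import (CellLineSummary, aggregate, summarize_cell_line, SUMMARY_COLUMNS)
from .simulate import (TruthSet, cell_line_names, fabricate_impact_verdicts,
                       generate_reference, platform_of, simulate_expression,
                       simulate_gene_lists, simulate_pileup, spike_variants)

__all__ = ["stage_simulate", "stage_call", "stage_annotate", "stage_integrate",
           "stage_epitopes", "stage_report", "run_pipeline"]


def _write_fasta(reference: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _write_vcf(records: Sequence[tuple[str, int, str, str]], contigs: Mapping[str, int],
               path: Path, extra_filters: Mapping[int, str] | None = None) -> None:
    header = pysam.VariantHeader()
    header.add_line('##source=surfscan')
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=FWD_HQ,Number=1,Type=Integer,Description="High-quality forward-strand support">')
    header.add_line('##INFO=<ID=REV_HQ,Number=1,Type=Integer,Description="High-quality reverse-strand support">')
    header.add_line('##FILTER=<ID=germline,Description="Known germline variant">')
    header.add_line('##FILTER=<ID=recurrent,Description="Recurrent across >k lines, not whitelisted">')
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(records):
            contig, pos, ref, alt, *info = rec
            r = out.new_record(contig=contig, start=pos - 1, alleles=(ref, alt))
            if info:
                dp, fwd, rev = info
                r.info["DP"], r.info["FWD_HQ"], r.info["REV_HQ"] = dp, fwd, rev
            if extra_filters and i in extra_filters:
                r.filter.add(extra_filters[i])
            else:
                r.filter.add("PASS")
            out.write(r)


def _truth_df(truth: TruthSet) -> pd.DataFrame:
    rows = []
    for cl in sorted(truth.somatic):
        for v in truth.somatic[cl]:
            rows.append((cl, v.contig, v.position, v.ref, v.alt, v.var_type,
                         v.consequence, v.gene_id))
    return pd.DataFrame(rows, columns=["cell_line", "contig", "position", "ref",
                                       "alt", "var_type", "consequence", "gene_id"])


def stage_simulate(config: SimConfig, outdir: str | Path) -> None:
    """Generate every pipeline input with known ground truth."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference, models = generate_reference(config)
    _write_fasta(reference, out / "reference.fa")
    write_gene_table(models, out / "genes.tsv")
    write_bed(models, out / "targets.bed")
    truth = spike_variants(reference, models, config)
    contigs = {name: len(seq) for name, seq in reference.items()}
    _write_vcf([(v.contig, v.position, v.ref, v.alt) for v in truth.germline],
               contigs, out / "germline.vcf")
    _truth_df(truth).to_csv(out / "truth_somatic.tsv", sep="\t", index=False)
    lines = cell_line_names(config.n_cell_lines)
    meta = pd.DataFrame({
        "cell_line": lines,
        "platform": [platform_of(cl, config.n_cell_lines) for cl in lines],
        "mutator": ["Yes" if truth.mutator_flags[cl] else "No" for cl in lines],
    })
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    pdir = out / "pileups"
    pdir.mkdir(exist_ok=True)
    for cl in lines:
        with open(pdir / f"{cl}.pileup", "w") as fh:
            for line in simulate_pileup(reference, models, truth, config, cl):
                fh.write(line + "\n")
    simulate_expression(models, config).to_csv(out / "expression.tsv", sep="\t", index=False)
    verdicts, hidden = fabricate_impact_verdicts(truth, agreement=0.9, config=config)
    verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
    hidden.to_csv(out / "verdict_truth.tsv", sep="\t", index=False)
    druggable, known = simulate_gene_lists(models, config)
    (out / "druggable_genes.tsv").write_text("\n".join(druggable) + "\n")
    (out / "known_genes.tsv").write_text("\n".join(known) + "\n")
    dump_yaml_config({"simulate": config}, out / "config.yaml")


def _load_reference(outdir: Path) -> dict[str, str]:
    fa = Fasta(str(outdir / "reference.fa"))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _calls_to_df(calls_by_line: Mapping[str, Sequence[VariantCall]]) -> pd.DataFrame:
    rows = []
    for cl in sorted(calls_by_line):
        for c in calls_by_line[cl]:
            rows.append((cl, c.contig, c.position, c.ref, c.alt, c.var_type,
                         c.fwd_hq_support, c.rev_hq_support, c.depth,
                         ",".join(sorted(c.flags)) or ".",
                         "yes" if c.is_somatic else "no"))
    return pd.DataFrame(rows, columns=["cell_line", "contig", "position", "ref", "alt",
                                       "var_type", "fwd_hq", "rev_hq", "depth",
                                       "flags", "somatic"])


def stage_call(outdir: str | Path, thresholds: CallerThresholds | None = None,
               whitelist: Sequence = ()) -> None:
    """Call variants per line, filter germline matches, flag recurrence."""
    out = Path(outdir)
    thresholds = (thresholds or CallerThresholds()).validate()
    pdir = out / "pileups"
    if not pdir.is_dir():
        raise StageError("variant_calling inputs missing: no pileups/ directory")
    if not (out / "germline.vcf").exists():
        raise StageError("variant_calling inputs missing: germline.vcf")
    reference = _load_reference(out)
    germline = load_germline_db(out / "germline.vcf", reference)
    targets = read_bed(out / "targets.bed")
    all_calls: dict[str, list[VariantCall]] = {}
    cov_rows = []
    for pfile in sorted(pdir.glob("*.pileup")):
        cl = pfile.stem
        with open(pfile) as fh:
            sites = list(parse_pileup(fh))
        calls = call_variants(sites, thresholds, cl)
        filter_germline(calls, germline, reference)
        all_calls[cl] = calls
        cov = coverage_summary(sites, targets)
        cov_rows.append((cl, cov.mean_depth, cov.pct_covered, cov.pct_covered_10x,
                         cov.on_target_bases))
    flag_recurrent(all_calls, thresholds.recurrence_k, whitelist)
    df = _calls_to_df(all_calls)
    df.to_csv(out / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(cov_rows, columns=["cell_line", "mean_depth", "pct_covered",
                                    "pct_covered_10x", "on_target_bases"]
                 ).to_csv(out / "coverage.tsv", sep="\t", index=False)
    contigs = {name: len(seq) for name, seq in reference.items()}
    vdir = out / "calls_vcf"
    vdir.mkdir(exist_ok=True)
    for cl, calls in all_calls.items():
        recs, filters = [], {}
        for i, c in enumerate(sorted(calls, key=lambda c: (c.contig, c.position, c.alt))):
            recs.append((c.contig, c.position, c.ref, c.alt,
                         c.depth, c.fwd_hq_support, c.rev_hq_support))
            if "germline" in c.flags:
                filters[i] = "germline"
            elif "recurrent_suspect" in c.flags and "whitelisted" not in c.flags:
                filters[i] = "recurrent"
        _write_vcf(recs, contigs, vdir / f"{cl}.vcf", filters)


def stage_annotate(outdir: str | Path, nonsense_auto_impact: bool = False) -> None:
    """Map somatic calls to gene models, classify, and apply the impact consensus."""
    out = Path(outdir)
    for req in ("calls.tsv", "genes.tsv", "reference.fa", "verdicts.tsv"):
        if not (out / req).exists():
            raise StageError(f"consequence inputs missing: {req}")
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    models = read_gene_table(out / "genes.tsv")
    reference = _load_reference(out)
    verdicts = pd.read_csv(out / "verdicts.tsv", sep="\t")
    vmap: dict[tuple[str, str], dict[str, str]] = {}
    for r in verdicts.itertuples(index=False):
        vmap.setdefault((r.cell_line, r.variant_key), {})[r.algorithm] = r.verdict
    rows = []
    for r in calls[calls.somatic == "yes"].itertuples(index=False):
        var = Variant(r.contig, int(r.position), r.ref, r.alt)
        rec = annotate_variant(var, models, reference[r.contig],
                               vmap.get((r.cell_line, var.key), {}),
                               nonsense_auto_impact)
        if rec is None:
            continue
        rows.append((r.cell_line, var.key, r.contig, r.position, r.ref, r.alt,
                     var.var_type, rec.gene_id, rec.var_class, rec.codon_index,
                     rec.codon_change, rec.protein_change,
                     rec.verdicts.get("sift", "unavailable"),
                     rec.verdicts.get("polyphen2", "unavailable"),
                     rec.verdicts.get("mutation_assessor", "unavailable"),
                     "yes" if rec.impact_consensus else "no"))
    pd.DataFrame(rows, columns=[
        "cell_line", "variant_key", "contig", "position", "ref", "alt", "var_type",
        "gene_id", "var_class", "codon_index", "codon_change", "protein_change",
        "sift", "polyphen2", "mutation_assessor", "impact_consensus",
    ]).to_csv(out / "annotated.tsv", sep="\t", index=False)


def _expression_flags(out: Path):
    expression = pd.read_csv(out / "expression.tsv", sep="\t")
    genes = [m.gene_id for m in read_gene_table(out / "genes.tsv")]
    return gate_expression(genes, expression)


def stage_integrate(outdir: str | Path) -> None:
    """Expression gating, druggability, recurrence and novelty tables."""
    out = Path(outdir)
    for req in ("annotated.tsv", "expression.tsv", "druggable_genes.tsv",
                "known_genes.tsv", "metadata.tsv"):
        if not (out / req).exists():
            raise StageError(f"integration inputs missing: {req}")
    ann = pd.read_csv(out / "annotated.tsv", sep="\t")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t")
    flags = _expression_flags(out)
    druggable = set((out / "druggable_genes.tsv").read_text().split())
    known = set((out / "known_genes.tsv").read_text().split())
    n_lines = len(meta)
    coding = ann[ann.var_class != "synonymous"]
    mutated_in: dict[str, set] = {}
    mut_expr: dict[str, set] = {}
    for r in coding.itertuples(index=False):
        mutated_in.setdefault(r.gene_id, set()).add(r.cell_line)
        if flags.expressed_in(r.gene_id, r.cell_line):
            mut_expr.setdefault(r.gene_id, set()).add(r.cell_line)
    mut_expr_genes = sorted(g for g, ls in mut_expr.items() if ls)
    novel = set(novel_genes(mut_expr_genes, known))
    rows = []
    for g in sorted(mutated_in):
        ls, le = mutated_in[g], mut_expr.get(g, set())
        rows.append((g, ",".join(sorted(ls)), len(le), len(le) / n_lines,
                     "yes" if g in druggable else "no",
                     "yes" if g in novel else "no",
                     "yes" if flags.per_gene.get(g, False) else "no"))
    pd.DataFrame(rows, columns=["gene_id", "mutated_in", "n_lines_mutated_expressed",
                                "fraction", "druggable", "novel", "expressed_any"]
                 ).to_csv(out / "gene_status.tsv", sep="\t", index=False)
    recurrence_summary(mut_expr, n_lines).to_csv(
        out / "recurrence.tsv", sep="\t", index=False)


def stage_epitopes(outdir: str | Path, scorer: ScorerConfig | None = None,
                   pssm_path: str | Path | None = None) -> None:
    """Peptide windowing, dual-scorer binding, cleavage gating and decisions."""
    out = Path(outdir)
    if not (out / "annotated.tsv").exists():
        raise StageError("epitopes inputs missing: annotated.tsv")
    scorer = (scorer or ScorerConfig()).validate()
    pssm = load_pssm(pssm_path) if pssm_path else packaged_pssm()
    ann = pd.read_csv(out / "annotated.tsv", sep="\t")
    models = {m.gene_id: m for m in read_gene_table(out / "genes.tsv")}
    reference = _load_reference(out)
    flags = _expression_flags(out)
    rows = []
    for r in ann[ann.var_class.isin(["missense", "frameshift"])].itertuples(index=False):
        model = models[r.gene_id]
        var = Variant(r.contig, int(r.position), r.ref, r.alt)
        ref_seq = reference[r.contig]
        rec = classify_consequence(var, model, ref_seq)
        ref_prot = model.protein(ref_seq)
        mut_prot = mutant_protein(model, var, ref_seq)
        pair = extract_peptides(rec, ref_prot, mut_prot, scorer.flank, r.cell_line)
        if pair is None:
            continue
        calls = call_mutated_epitopes(pair, pssm, scorer)
        gate_epitope_expression(calls, r.gene_id, r.cell_line, flags)
        for e in calls:
            rows.append((r.cell_line, r.gene_id, r.variant_key, pair.origin,
                         e.peptide, e.window_start,
                         round(e.percent_optimum, 4), round(e.ic50, 4),
                         "yes" if e.cleaved else "no",
                         e.reference_peptide or ".",
                         round(e.ref_percent_optimum, 4) if e.ref_percent_optimum is not None else ".",
                         round(e.ref_ic50, 4) if e.ref_ic50 is not None else ".",
                         e.decision, "yes" if e.expressed else "no"))
    pd.DataFrame(rows, columns=[
        "cell_line", "gene_id", "variant_key", "origin", "peptide", "window_start",
        "percent_optimum", "ic50", "cleaved", "reference_9mer",
        "ref_percent_optimum", "ref_ic50", "decision", "expressed",
    ]).to_csv(out / "epitopes.tsv", sep="\t", index=False)


def stage_report(outdir: str | Path) -> None:
    """Per-line summary table plus panel aggregate (JSON)."""
    out = Path(outdir)
    for req in ("calls.tsv", "annotated.tsv", "epitopes.tsv", "coverage.tsv",
                "metadata.tsv", "targets.bed"):
        if not (out / req).exists():
            raise StageError(f"report inputs missing: {req}")
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    ann = pd.read_csv(out / "annotated.tsv", sep="\t")
    epis = pd.read_csv(out / "epitopes.tsv", sep="\t")
    cov = pd.read_csv(out / "coverage.tsv", sep="\t").set_index("cell_line")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t").set_index("cell_line")
    flags = _expression_flags(out)
    druggable = set((out / "druggable_genes.tsv").read_text().split())
    target_size = sum(e - s for _, s, e in read_bed(out / "targets.bed"))
    rows = []
    keys_by_line: dict[str, list] = {}
    for cl in meta.index:
        sub = calls[calls.cell_line == cl]
        som = sub[sub.somatic == "yes"]
        asub = ann[ann.cell_line == cl]
        esub = epis[(epis.cell_line == cl) & (epis.decision.str.startswith("called"))]
        nonsyn = asub[asub.var_class.isin(["missense", "nonsense"])]
        indel_recs = asub[asub.var_class.isin(["frameshift", "inframe_indel"])]
        druggable_muts = asub[(asub.var_class != "synonymous") &
                              (asub.gene_id.isin(druggable))]
        expr_druggable = [r for r in druggable_muts.itertuples(index=False)
                          if flags.expressed_in(r.gene_id, cl)]
        c = cov.loc[cl]
        coverage = CoverageStats(float(c.mean_depth), float(c.pct_covered),
                                 float(c.pct_covered_10x), int(c.on_target_bases))
        snvs = sub[sub.var_type == "SNV"]
        summary = CellLineSummary(
            cell_line=cl,
            mutator=meta.loc[cl, "mutator"] == "Yes",
            snvs=len(snvs),
            pct_snvs_germline=(100.0 * snvs["flags"].str.contains("germline").sum()
                               / len(snvs)) if len(snvs) else 0.0,
            somatic_snvs=len(som[som.var_type == "SNV"]),
            somatic_nonsyn_snvs=len(nonsyn),
            nonsense_snvs=len(asub[asub.var_class == "nonsense"]),
            indels=len(sub[sub.var_type != "SNV"]),
            somatic_indels=len(som[som.var_type != "SNV"]),
            frameshift_indels=len(asub[asub.var_class == "frameshift"]),
            impact_nonsyn=len(nonsyn[nonsyn.impact_consensus == "yes"]),
            impact_indels=len(indel_recs[indel_recs.impact_consensus == "yes"]),
            druggable_mutations=len(druggable_muts),
            expressed_druggable_mutations=len(expr_druggable),
            mutated_epitopes=len(esub),
            expressed_mutated_epitopes=len(esub[esub.expressed == "yes"]),
            mutation_rate=len(som[som.var_type == "SNV"]) / target_size,
            coverage=coverage,
        )
        rows.append(summary.as_row())
        keys_by_line[cl] = som.apply(
            lambda r: (r.contig, r.position, r.ref, r.alt), axis=1).tolist() \
            if len(som) else []
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    rep = aggregate(df, keys_by_line)
    payload = {"n_lines": rep.n_lines, "means": rep.means, "totals": rep.totals,
               "unique_totals": rep.unique_totals}
    (out / "aggregate.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: SimConfig, outdir: str | Path,
                 thresholds: CallerThresholds | None = None,
                 scorer: ScorerConfig | None = None,
                 whitelist: Sequence = ()) -> Path:
    """Execute all stages in order on a fresh simulation; returns the run dir."""
    out = Path(outdir)
    thresholds = (thresholds or CallerThresholds()).validate()
    scorer = (scorer or ScorerConfig()).validate()
    stage_simulate(config, out)
    stage_call(out, thresholds, whitelist)
    stage_annotate(out)
    stage_integrate(out)
    stage_epitopes(out, scorer)
    stage_report(out)
    log = [
        {"event": "run", "surfscan_version": __version__, "seed": config.seed},
        {"event": "thresholds", **asdict(thresholds)},
        {"event": "scorer", **{k: v for k, v in asdict(scorer).items()}},
        {"event": "config", **asdict(config)},
    ]
    with open(out / "run_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return out
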