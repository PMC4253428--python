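# surfscan

Somatic-mutation scanning of genes coding for cell-surface proteins
("surfaceome") in panels of tumour cell lines, for cancer-genomics analysts
who need a tested, reproducible version of the classic targeted-sequencing
workflow: stringent pileup-based somatic variant calling, coding-consequence
and functional-impact annotation, integration with expression and
druggable-gene data, and MHC class I mutated-epitope (neoepitope)
prediction.

Because cell-line panels usually lack matched normals, "somatic" status is
approximated by a deterministic filter cascade rather than a paired
statistical model:

1. **Calling** — from `samtools mpileup` text evidence (with per-read base
   and mapping qualities), a variant is called when at least
   *k* = 3 high-quality reads (base quality Q ≥ 25 **and** mapping quality
   q ≥ 20) support the alternate allele on **each** strand (a laxer
   ≥3-total-with-both-strands mode is available).
2. **Germline removal** — exact allele-aware matching against a known
   germline VCF, after indel left-normalization.
3. **Recurrence screening** — variants present in more than 3 cell lines are
   flagged as probable alignment artifacts and removed unless whitelisted
   (the stand-in for manual inspection of genuine hotspots).
4. **Consequence & impact** — variants are mapped onto single-transcript
   gene models and classified (synonymous / missense / nonsense /
   frameshift / in-frame); a substitution is *impactful* when ≥ 2 of
   {SIFT, PolyPhen-2, MutationAssessor} call it damaging, an InDel when
   SIFT does (verdicts are consumed as tables).
5. **Expression & druggability** — a gene counts as expressed at
   FPKM ≥ 3 (RNA-seq lines) or log-intensity ≥ 5.5 (array lines);
   druggability is membership in a supplied drug–gene interaction list, and
   novel genes are those absent from a supplied known-mutated list.
6. **Epitopes** — peptides around missense/frameshift mutations (10-residue
   flanks) are decomposed into 9-mers and scored by two pluggable
   PSSM-based scorers: percent-of-optimum, 100·S/S_max, and an IC50
   transform, cap^(1−x) nM with x the min–max-normalised score and
   cap = 50 000. A candidate passes when %opt ≥ 50, IC50 ≤ 500 nM and a
   proteasomal-cleavage gate accepts it; it is **called** when it is unique
   to the mutant sequence (novel frameshift tail) or out-binds its
   same-start reference window by ≥ 1.2× under *both* scorers.

A first-class synthetic-data module generates every input with known ground
truth (toy surfaceome, spiked germline + somatic variants with
mutator/non-mutator loads, pileup evidence, threshold-straddling expression,
verdict tables), so the whole pipeline is testable end-to-end without any
sequencing data.

## Worked example

Run the pipeline end-to-end on a simulated 6-line panel (the numbered
scripts under `analysis/` run the same stages one at a time):

```sh
surfscan run --simulate --seed 1 --outdir results/panel
python analysis/06_summarize_panel.py
```

which prints the per-line summary table:

```
cell_line mutator  somatic_snvs  somatic_nonsyn_snvs  somatic_indels  frameshift_indels  expressed_druggable_mutations  mutated_epitopes  expressed_mutated_epitopes
     CL01      No            10                    8               1                  1                              3                 1                           1
     CL02      No             4                    4               1                  1                              0                 1                           0
     CL03     Yes            27                   20               5                  4                              5                 7                           7
     CL04      No             3                    2               2                  1                              1                 0                           0
     CL05      No             7                    5               1                  0                              2                 0                           0
     CL06     Yes            28                   22               4                  2                              5                 1                           0
```

The two mutator-phenotype lines (CL03, CL06) carry the expected ~5× higher
somatic load; `aggregate.json` holds the per-line means and the
cross-line-deduplicated variant total, and `epitopes.tsv` the per-window
scores and decisions. Truth-recovery diagnostics are printed by
`analysis/02_call_variants.py` (recovery < 1 at 30X is expected: a spiked
variant is only callable when sampling leaves ≥ 3 high-quality reads on
each strand).

Package data include two transcribed per-cell-line summary tables from the
published 23-line colorectal panel this pipeline emulates;
`analysis/07_reference_panel_stats.py` recomputes their aggregate
statistics (per-line averages of 174 non-synonymous SNVs, 28 InDels and 11
expressed druggable mutations; 57% of the 3,594-gene surfaceome mutated).

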