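# Methods

## Scope and model

surfscan implements a deterministic somatic-mutation analysis for targeted
sequencing of cell-line panels without matched normals. There is no
genotype-likelihood model: somatic status is operationalised as a filter
cascade — read-support thresholds, germline-database subtraction and
cross-line recurrence screening — followed by consequence annotation,
expression/druggability integration and MHC class I mutated-epitope
prediction. All internal coordinates are 0-based half-open; VCF and pileup
I/O use their native 1-based conventions, which removes any off-by-one
ambiguity between modules.

## Variant calling

Evidence is consumed as samtools-mpileup *text* with both base-quality and
mapping-quality columns (the `-s` dialect; strand is encoded by base case,
indels by `+n`/`-n` tokens attached to the anchoring read). Input is assumed
duplicate-removed; duplicates are upstream of this pipeline's scope.

A call requires high-quality support — base quality ≥ `min_base_quality`
(default 25, inclusive) AND mapping quality ≥ `min_map_quality` (default
20, inclusive) — under one of two strand rules:

* `per_strand` (default): ≥ `min_support_per_strand` (default 3) HQ reads
  on **each** strand. This is the literal reading of "3 high-quality reads
  on both strands"; the phrase is ambiguous, so
* `total_with_both_strands`: ≥ 3 HQ reads in total with ≥ 1 on each strand
  is exposed as a configuration option.

Germline subtraction matches (contig, position, ref, alt) exactly after
allele normalization (shared prefix/suffix trimming plus reference-aware
left shifting of indels); unnormalized database records are normalized
internally with a logged warning. Variants recurring in more than
`recurrence_k` = 3 cell lines are flagged as probable alignment artifacts
and excluded unless present in a user-supplied whitelist — the programmatic
replacement for manual inspection of genuine hotspot mutations.

Coverage summaries report mean depth over the target, percent of target
covered (depth ≥ 1) and percent covered at ≥ 10× (the ">10X" convention is
implemented inclusively). The mutation rate is somatic SNVs divided by the
*configured target size* in bases, not by covered bases: for the packaged
reference panel a constant 6,101,190 bp denominator reproduces exactly the
two printed per-line rates that are self-consistent with their SNV counts
(41 → 6.72e-06, 43 → 7.05e-06); the remaining printed rates are internally
inconsistent (apparently row-shifted) and are not used as checks.

## Consequence annotation

Gene models are single transcripts (one per gene, no isoform arbitration)
with ordered CDS exons; translation uses the standard nuclear code only.
SNVs are classified synonymous/missense/nonsense by codon substitution
(plus-strand alleles are complemented on reverse-strand genes); InDels are
frameshift iff the allele-length difference is not a multiple of three.
Mutant proteins are built by rebuilding the full mutant CDS (the edit must
lie within one exon, which the generator guarantees for its small indels)
and translating to the first stop codon; frameshift read-through past the
original stop into downstream genomic sequence is not modelled. Protein
changes are reported in HGVS-like notation (p.Lys5Ter, p.Val7fs).

Functional impact is a consensus over externally supplied verdicts:
missense and nonsense substitutions are impactful when at least two of
{SIFT, PolyPhen-2, MutationAssessor} say damaging; InDels when SIFT does.
Nonsense variants get **no** automatic impact label — the consensus rule is
applied uniformly, with an opt-in `nonsense_auto_impact` override — because
blanket-labelling stop-gains is not implied by the reported impact
arithmetic of the study this pipeline emulates. Missing verdicts count as
tolerated with a logged warning.

## Expression, druggability, recurrence

A gene is expressed in a line when FPKM ≥ 3 (RNA-seq lines) or array
log-intensity ≥ 5.5 (array lines); both thresholds are inclusive, and each
line is assayed on exactly one platform. A gene is globally expressed when
it passes in at least one line. "Mutated and expressed" is evaluated
per-line (mutation and expression in the *same* line). Recurrence
fractions use all panel lines in the denominator and strict inequality at
the >10% and >20% cut-offs (3/23 = 13% qualifies). Druggability is set
membership in a supplied drug–gene list; novel genes are mutated-expressed
genes absent from a supplied known-mutated list. The mutator phenotype is
per-line metadata (it derives from MSI/MMR/POLε status, not from a count
threshold) and is never computed.

## Epitope prediction

Peptide pairs are built per mutation: missense → a 21-mer centred on the
substituted residue (truncated at termini); frameshift → up to 10
reference residues before the shifted codon plus the entire novel tail to
the stop. Peptides are processed individually, never as concatamers —
batch concatenation (used historically for web-server submission) creates
junction artifacts that then have to be excluded; per-peptide processing
removes that artifact class by construction.

Trained MHC binding predictors are out of scope; the decision logic is the
contribution. Two pluggable scorers share one 9×20 PSSM:

* percent-of-optimum = 100·S/S_max with S the additive score and S_max the
  sum of per-position column maxima (binder iff ≥ 50);
* IC50 = cap^(1−x) nM with x = (S−S_min)/(S_max−S_min) clipped to [0, 1]
  and cap = 50 000 nM — the conventional affinity range; strictly
  decreasing in S (binder iff ≤ 500 nM).

The packaged matrix is a **synthetic** HLA-A*02:01-like example (uniform
[0, 10) entries with boosted P2 Leu/Met and P9 Val/Leu/Ile anchors),
generated deterministically; it is calibrated so that a typical random
9-mer sits near 50% of optimum, giving realistic non-degenerate pass
rates. Proteasomal cleavage is a pluggable predicate; the default rule
accepts 9-mers whose C-terminal residue is hydrophobic or basic
({L,V,I,F,Y,W,M,K,R}).

Every mutant 9-mer overlapping a mutated/novel residue is scored. A window
passing both binder thresholds and cleavage is *called*:

* `called_unique` when no full-length same-start reference window exists
  (novel frameshift tail or terminus) and the 9-mer is absent from the
  reference peptide's own 9-mer set (whole-proteome uniqueness is a
  documented extension, not the default, for desk-scale practicality);
* `called_differential` when a counterpart exists and mutant affinity ≥
  1.2× reference affinity under **both** scorers, with affinity =
  percent-optimum for scorer 1 and 1/IC50 for scorer 2 so that "higher" is
  increasing on both scales. The factor uses ≥ by default ("at least 20%
  higher"); a strict-inequality switch is provided. By default the raw
  reference affinities are compared; `require_reference_candidate` makes
  the reference window pass the binder thresholds first, else the mutant
  window falls back to the uniqueness branch.

Stop-gain variants generate no novel sequence and yield no peptides.
Called epitopes are finally gated by the source gene's expression in the
mutation's cell line.

## Synthetic panel generator

The generator emulates the shape of a 23-line targeted-capture study at
desk scale. Everything derives from a single seed; identical configs give
byte-identical files. Defaults (units, value, rationale):

| parameter | default | rationale |
|---|---|---|
| n_cell_lines | 6 | desk-scale panel preserving a mutator/non-mutator split |
| n_genes / mean_cds_length | 40 / 450 bp | ~18 kb target; runs in seconds |
| depth_mean | 30× | the panel's reported average coverage |
| vaf | 0.5 | clonal heterozygous cell-line variants (purity 1) |
| somatic_load_mutator / normal | 40 / 8 per line | ~5× contrast, matching the panel's mutator ratio |
| mutator_fraction | 0.4 | 9 of 23 lines in the reference panel |
| indel_fraction | 0.13 | 595 InDels vs 3,944 SNVs panel-wide |
| germline_density | 1.0 / kb | typical heterozygous-site density |
| base/map quality means | 35 / 50 (sd 6 / 8, clipped) | realistic Phred ranges leaving a tail below the Q25/q20 cut-offs |
| error_rate | 0.0 | uniform miscall rate; optional |
| fraction_expressed | 0.6 | majority of surface genes detectably expressed |
| impact_rate_snv / indel | 0.4 / 0.8 | observed impact fractions (36% substitutions, 80% InDels) |

Gene models are 1–3-exon spliced CDSs (ATG … stop, length ≡ 0 mod 3) on a
single contig (multi-contig layout is supported by the data structures).
Germline variants (~10% indels) double as the known-polymorphism database;
somatic variants are drawn per line at Poisson loads, disjoint from
germline positions, excluding start/stop codons, with intended consequence
classes recorded at spike time. Expression tables deliberately include one
gene exactly at each platform threshold and one just below. Verdict tables
agree with a hidden truth impact label with probability `agreement`
(pipeline default 0.9); the hidden labels are written to a separate file.

What the generator does **not** emulate — and hence what green tests do not
show about real data: read-level alignment artifacts (reads are independent
per position, with no tracking across deletions), mapping bias, strand
bias, context-dependent error, copy-number/structural variation, subclonal
VAF distributions, isoform complexity, and FASTQ/SAM-level processing. It
validates the decision logic, not sequencing physics.

## Numerical and design choices

* Panel averages are rounded half-away-from-zero to integers, matching how
  such averages are conventionally quoted; the percentage helper does the
  same on 100·a/b.
* Cross-line aggregate totals are reported both as column sums and as
  deduplicated unique-variant counts (shared variants make column sums
  exceed unique totals); only the ordering law is asserted, since the two
  coincide only on recurrence-free panels.
* Degenerate inputs: empty pileups yield empty call lists; an empty target
  region, a zero/negative target size, an all-equal PSSM (IC50 transform)
  or a non-positive matrix optimum raise typed errors naming the problem;
  unknown cell lines and malformed pileup lines raise with the offending
  identifier or line number.
* Ordering is made deterministic everywhere ties could occur: calls sort
  by (contig, position, alt), gene sets and novel-gene lists are sorted,
  and epitope windows are emitted in start order.
* Problem sizes in the tests and the acceptance script (3–6 lines, 8–25
  genes, depth 30–200) were chosen as the smallest panels that exercise
  every branch — mutator contrast, both platforms, all consequence
  classes — while completing in seconds.

## Known limitations

* Single transcript per gene; splice-site, UTR and regulatory effects are
  out of scope.
* The germline filter is only as complete as the supplied database —
  exactly as in the emulated design, rare real germline variants absent
  from it will masquerade as somatic.
* PSSM scorers are monotone stand-ins for trained neural predictors: they
  reproduce the thresholds-and-consensus decision structure, not absolute
  nM accuracy, and ship with one synthetic allele matrix.
* The epitope uniqueness check is local to the mutation's peptide, not
  proteome-wide.
* The caller is intentionally non-probabilistic; no base-quality
  recalibration, realignment or tumour/normal pairing.
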