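"""Synthetic cell-line panel generator.

Produces every input the pipeline consumes with known ground truth: a toy
surfaceome (reference FASTA + gene models), spiked germline and somatic
variants (the germline set doubles as the known-polymorphism database),
samtools-mpileup-dialect read evidence per cell line, expression tables on
two platforms straddling the FPKM >= 3 / array >= 5.5 thresholds,
functional-impact verdict tables with a configurable agreement rate, and
druggable / known-mutated gene lists.

Everything is a pure function of the :class:`~surfscan.config.SimConfig`
(including its seed): identical configs give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .consequence import Variant, classify_consequence
from .errors import ConfigError, GenerationError, LookupError_
from .genes import GeneModel, revcomp

__all__ = ["TruthVariant", "TruthSet", "generate_reference", "spike_variants",
           "simulate_pileup", "simulate_expression", "fabricate_impact_verdicts",
           "simulate_gene_lists", "cell_line_names", "platform_of"]

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
CONTIG = "chr1"

RNASEQ_THRESHOLD = 3.0
ARRAY_THRESHOLD = 5.5


@dataclass(frozen=True)
class TruthVariant:
    contig: str
    position: int          # 1-based, VCF conventions
    ref: str
    alt: str
    var_type: str          # SNV / INS / DEL
    consequence: str       # intended class from the gene model
    gene_id: str

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref}>{self.alt}"

    def as_variant(self) -> Variant:
        return Variant(self.contig, self.position, self.ref, self.alt)


@dataclass
class TruthSet:
    germline: list[TruthVariant]
    somatic: dict[str, list[TruthVariant]]   # cell line -> variants
    mutator_flags: dict[str, bool]

    def all_somatic_positions(self) -> set[tuple[str, int]]:
        return {(v.contig, v.position) for vs in self.somatic.values() for v in vs}


def cell_line_names(n: int) -> list[str]:
    return [f"CL{i + 1:02d}" for i in range(n)]


def platform_of(cell_line: str, n_cell_lines: int) -> str:
    """Platform assignment: first half of the panel RNA-seq, rest array."""
    idx = int(cell_line[2:]) - 1
    return "rnaseq" if idx < (n_cell_lines + 1) // 2 else "array"


# --- reference + gene models ------------------------------------------------

def _random_cds(rng: np.random.Generator, length: int) -> str:
    """A CDS of the given length: ATG + non-stop codons + one stop codon."""
    n_internal = length // 3 - 2
    codons = ["ATG"]
    for _ in range(n_internal):
        while True:
            c = "".join(rng.choice(BASES, 3))
            if c not in STOPS:
                break
        codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def generate_reference(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Build a single-contig toy genome with ``n_genes`` spliced CDS models."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    genome: list[str] = []
    models: list[GeneModel] = []
    cursor = 0

    def spacer(lo=50, hi=150):
        nonlocal cursor
        n = int(rng.integers(lo, hi))
        genome.append("".join(rng.choice(BASES, n)))
        cursor += n

    spacer()
    for g in range(config.n_genes):
        length = int(rng.normal(config.mean_cds_length, config.mean_cds_length / 5))
        length = max(30, length - length % 3)
        cds = _random_cds(rng, length)
        n_exons = int(rng.integers(1, 4))
        # split the CDS into n_exons pieces of >= 6 bases each
        if n_exons > 1 and length >= 6 * n_exons:
            cuts = sorted(rng.choice(np.arange(6, length - 5), n_exons - 1, replace=False))
        else:
            n_exons, cuts = 1, []
        bounds = [0, *cuts, length]
        pieces = [cds[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
        strand = "+" if rng.random() < 0.5 else "-"
        # lay out exon/intron structure in transcript orientation
        region_parts: list[tuple[str, bool]] = []
        for i, p in enumerate(pieces):
            if i:
                intron = "".join(rng.choice(BASES, int(rng.integers(30, 81))))
                region_parts.append((intron, False))
            region_parts.append((p, True))
        region = "".join(p for p, _ in region_parts)
        # transcript-orientation exon intervals within the region
        local, off = [], 0
        for p, is_exon in region_parts:
            if is_exon:
                local.append((off, off + len(p)))
            off += len(p)
        if strand == "-":
            region = revcomp(region)
            L = len(region)
            local = sorted((L - e, L - s) for s, e in local)
        exons = tuple((cursor + s, cursor + e) for s, e in local)
        genome.append(region)
        cursor += len(region)
        models.append(GeneModel(f"GENE{g + 1:03d}", CONTIG, strand, exons))
        spacer()
    return {CONTIG: "".join(genome)}, models


# --- variant spiking --------------------------------------------------------

def _cds_positions(model: GeneModel) -> list[int]:
    """Genomic positions of the CDS, excluding the start and stop codons."""
    pos = [p for s, e in model.exons for p in range(s, e)]
    tx = sorted(pos, reverse=(model.strand == "-"))  # transcript orientation
    return sorted(tx[3:-3])


def _draw_snv(rng: np.random.Generator, ref_seq: str, pos0: int) -> tuple[str, str]:
    ref = ref_seq[pos0]
    alts = [b for b in "ACGT" if b != ref]
    return ref, alts[int(rng.integers(3))]


def _draw_indel(rng: np.random.Generator, ref_seq: str, pos0: int,
                exon: tuple[int, int]) -> tuple[str, str] | None:
    """Anchored insertion or deletion of 1-3 bases, contained in the exon."""
    size = int(rng.integers(1, 4))
    anchor = ref_seq[pos0]
    if rng.random() < 0.5:
        ins = "".join(rng.choice(BASES, size))
        return anchor, anchor + ins
    if pos0 + 1 + size > exon[1]:
        return None
    return ref_seq[pos0:pos0 + 1 + size], anchor


def spike_variants(reference: dict[str, str], models: Sequence[GeneModel],
                   config: SimConfig) -> TruthSet:
    """Spike germline and per-line somatic variants into the CDS space.

    Germline and somatic position sets are disjoint; every variant's REF
    allele matches the reference; intended consequence classes are computed
    from the gene models at spike time.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    ref_seq = reference[CONTIG]
    by_pos: dict[int, GeneModel] = {}
    for m in models:
        for p in _cds_positions(m):
            by_pos[p] = m
    all_positions = np.array(sorted(by_pos))
    if len(all_positions) == 0:
        raise GenerationError("gene models contain no usable CDS positions")

    target_kb = sum(m.cds_len for m in models) / 1000.0
    n_germ = int(rng.poisson(config.germline_density * target_kb))
    n_germ = min(n_germ, len(all_positions) // 3)
    germ_pos = rng.choice(all_positions, size=n_germ, replace=False)
    used: set[int] = set()
    germline: list[TruthVariant] = []
    for pos0 in sorted(int(p) for p in germ_pos):
        model = by_pos[pos0]
        exon = model.exon_of(pos0)
        if rng.random() < 0.1:  # a minority of germline variants are InDels
            drawn = _draw_indel(rng, ref_seq, pos0, exon)
            if drawn is None:
                continue
            ref, alt = drawn
        else:
            ref, alt = _draw_snv(rng, ref_seq, pos0)
        span = range(pos0, pos0 + len(ref))
        if used.intersection(span):
            continue
        used.update(span)
        rec = classify_consequence(Variant(CONTIG, pos0 + 1, ref, alt), model, ref_seq)
        germline.append(TruthVariant(CONTIG, pos0 + 1, ref, alt,
                                     Variant(CONTIG, pos0 + 1, ref, alt).var_type,
                                     rec.var_class, model.gene_id))

    lines = cell_line_names(config.n_cell_lines)
    n_mut = int(round(config.n_cell_lines * config.mutator_fraction))
    mutator_idx = set(rng.choice(config.n_cell_lines, size=n_mut, replace=False).tolist())
    mutator_flags = {cl: (i in mutator_idx) for i, cl in enumerate(lines)}

    free = np.array(sorted(set(int(p) for p in all_positions) - used))
    somatic: dict[str, list[TruthVariant]] = {}
    for i, cl in enumerate(lines):
        load = config.somatic_load_mutator if mutator_flags[cl] else config.somatic_load_normal
        n_som = int(rng.poisson(load))
        if n_som > len(free):
            raise GenerationError(
                f"CDS too short to place {n_som} somatic variants for {cl}")
        picks = rng.choice(free, size=n_som, replace=False)
        vs: list[TruthVariant] = []
        taken: set[int] = set()
        for pos0 in sorted(int(p) for p in picks):
            model = by_pos[pos0]
            exon = model.exon_of(pos0)
            if rng.random() < config.indel_fraction:
                drawn = _draw_indel(rng, ref_seq, pos0, exon)
                if drawn is None:
                    drawn = _draw_snv(rng, ref_seq, pos0)
                ref, alt = drawn
            else:
                ref, alt = _draw_snv(rng, ref_seq, pos0)
            span = set(range(pos0, pos0 + len(ref)))
            if span & (used | taken):
                continue
            taken |= span
            rec = classify_consequence(Variant(CONTIG, pos0 + 1, ref, alt), model, ref_seq)
            vs.append(TruthVariant(CONTIG, pos0 + 1, ref, alt,
                                   Variant(CONTIG, pos0 + 1, ref, alt).var_type,
                                   rec.var_class, model.gene_id))
        somatic[cl] = vs
    return TruthSet(germline, somatic, mutator_flags)


# --- pileup simulation ------------------------------------------------------

def _qual_string(rng: np.random.Generator, n: int, mean: float, sd: float,
                 lo: int, hi: int) -> np.ndarray:
    q = np.rint(rng.normal(mean, sd, n)).astype(int)
    return np.clip(q, lo, hi)


def simulate_pileup(reference: dict[str, str], models: Sequence[GeneModel],
                    truth: TruthSet, config: SimConfig,
                    cell_line: str) -> Iterator[str]:
    """Yield samtools-mpileup-dialect lines (with mapping-quality column).

    Reads are independent per position (no read tracking across a deletion):
    the alternate allele appears with probability ``vaf`` on a random strand,
    base/mapping qualities are clipped Gaussians, and deletion-spanning
    positions show ``*`` placeholders at the same allele fraction.
    """
    if cell_line not in truth.somatic:
        raise LookupError_(f"unknown cell line {cell_line!r}")
    config.validate()
    line_idx = sorted(truth.somatic).index(cell_line)
    rng = np.random.default_rng([config.seed, 303, line_idx])
    ref_seq = reference[CONTIG]

    variants: dict[int, TruthVariant] = {}
    deleted: dict[int, int] = {}  # position -> count of deletions spanning it
    for v in [*truth.germline, *truth.somatic[cell_line]]:
        variants[v.position - 1] = v
        if v.var_type == "DEL":
            for p in range(v.position, v.position - 1 + len(v.ref)):
                deleted[p] = deleted.get(p, 0) + 1

    positions = sorted({p for m in models for s, e in m.exons for p in range(s, e)})
    for pos0 in positions:
        refbase = ref_seq[pos0]
        depth = int(rng.poisson(config.depth_mean))
        if depth == 0:
            yield f"{CONTIG}\t{pos0 + 1}\t{refbase}\t0\t*\t*\t*"
            continue
        fwd = rng.random(depth) < 0.5
        bq = _qual_string(rng, depth, config.base_quality_mean, 6.0, 2, 41)
        mq = _qual_string(rng, depth, config.map_quality_mean, 8.0, 0, 60)
        v = variants.get(pos0)
        carrier = (rng.random(depth) < config.vaf) if v is not None else np.zeros(depth, bool)
        star = (rng.random(depth) < config.vaf) if pos0 in deleted else np.zeros(depth, bool)
        err = rng.random(depth) < config.error_rate
        chunks: list[str] = []
        for i in range(depth):
            if star[i]:
                chunks.append("*")
                continue
            base = refbase
            token = ""
            if v is not None and carrier[i]:
                if v.var_type == "SNV":
                    base = v.alt
                elif v.var_type == "INS":
                    ins = v.alt[1:]
                    token = f"+{len(ins)}{ins if fwd[i] else ins.lower()}"
                else:  # DEL anchor
                    dseq = v.ref[1:]
                    token = f"-{len(dseq)}{dseq if fwd[i] else dseq.lower()}"
            if err[i]:
                others = [b for b in "ACGT" if b != base]
                base = others[int(rng.integers(3))]
            if base == refbase:
                c = "." if fwd[i] else ","
            else:
                c = base.upper() if fwd[i] else base.lower()
            chunks.append(c + token)
        bq_str = "".join(chr(q + 33) for q in bq)
        mq_str = "".join(chr(q + 33) for q in mq)
        yield (f"{CONTIG}\t{pos0 + 1}\t{refbase}\t{depth}\t"
               f"{''.join(chunks)}\t{bq_str}\t{mq_str}")


# --- expression -------------------------------------------------------------

def simulate_expression(models: Sequence[GeneModel], config: SimConfig) -> pd.DataFrame:
    """Tidy expression table: one row per (gene, cell line) on the line's platform.

    A configured fraction of (gene, line) pairs sits above the platform
    threshold.  Two deliberate boundary fixtures: the first gene is emitted
    exactly at threshold everywhere (3.0 / 5.5 -> expressed), the second
    just below (2.999 / 5.49 -> not expressed).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 404])
    lines = cell_line_names(config.n_cell_lines)
    rows = []
    for m in models:
        gi = int(m.gene_id[4:]) - 1
        for cl in lines:
            platform = platform_of(cl, config.n_cell_lines)
            thr = RNASEQ_THRESHOLD if platform == "rnaseq" else ARRAY_THRESHOLD
            if gi == 0:
                value = thr
            elif gi == 1:
                value = 2.999 if platform == "rnaseq" else 5.49
            elif rng.random() < config.fraction_expressed:
                value = thr + float(rng.exponential(2.0 if platform == "rnaseq" else 1.5))
            else:
                value = float(rng.uniform(0, 0.95 * thr))
            rows.append((m.gene_id, cl, platform, round(value, 3)))
    return pd.DataFrame(rows, columns=["gene_id", "cell_line", "platform", "value"])


# --- impact verdicts --------------------------------------------------------

def fabricate_impact_verdicts(truth: TruthSet, agreement: float,
                              config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stand-in verdict tables for the three impact predictors.

    SNVs (missense/nonsense) get all three verdicts, InDels only SIFT.  With
    probability ``agreement`` every emitted verdict equals a hidden truth
    impact label; otherwise each predictor answers independently at random.
    Returns ``(verdicts, hidden_truth)``; the hidden labels are kept apart so
    the public table carries no leakage.
    """
    if not 0.0 <= agreement <= 1.0:
        raise ConfigError(f"agreement must lie in [0, 1], got {agreement!r}")
    rng = np.random.default_rng([config.seed, 505])
    from .consequence import ALGORITHMS
    vrows, trows = [], []
    for cl in sorted(truth.somatic):
        for v in truth.somatic[cl]:
            if v.consequence == "synonymous":
                continue
            is_indel = v.var_type != "SNV"
            p_damaging = config.impact_rate_indel if is_indel else config.impact_rate_snv
            truth_label = "damaging" if rng.random() < p_damaging else "tolerated"
            algos = ("sift",) if is_indel else ALGORITHMS
            agree = rng.random() < agreement
            for a in algos:
                verdict = truth_label if agree else \
                    ("damaging" if rng.random() < 0.5 else "tolerated")
                vrows.append((cl, v.key, v.consequence, a, verdict))
            trows.append((cl, v.key, truth_label))
    verdicts = pd.DataFrame(
        vrows, columns=["cell_line", "variant_key", "var_class", "algorithm", "verdict"])
    hidden = pd.DataFrame(trows, columns=["cell_line", "variant_key", "truth_impact"])
    return verdicts, hidden


# --- gene lists -------------------------------------------------------------

def simulate_gene_lists(models: Sequence[GeneModel],
                        config: SimConfig) -> tuple[list[str], list[str]]:
    """(druggable genes, known-mutated genes) — random subsets of the panel."""
    rng = np.random.default_rng([config.seed, 606])
    gids = [m.gene_id for m in models]
    druggable = sorted(g for g in gids if rng.random() < config.druggable_fraction)
    known = sorted(g for g in gids if rng.random() < config.known_fraction)
    return druggable, known
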