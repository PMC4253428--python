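"""Coding-consequence annotation of somatic variants.

Variants (VCF conventions: 1-based position, plus-strand alleles, anchored
indels) are mapped onto single-transcript gene models, classified as
synonymous / missense / nonsense / frameshift / in-frame, and turned into
mutant protein sequences.  Functional impact uses the external-predictor
consensus rule: a missense or nonsense substitution is impactful when at
least two of {SIFT, PolyPhen-2, MutationAssessor} call it damaging, an
InDel when SIFT alone does.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.SeqUtils import seq3

from .errors import ConsistencyError
from .genes import GeneModel, revcomp, translate_cds

logger = logging.getLogger(__name__)

__all__ = ["Variant", "ConsequenceRecord", "map_to_cds", "classify_consequence",
           "mutant_cds", "mutant_protein", "consensus_impact", "annotate_variant",
           "ALGORITHMS", "variant_key"]

ALGORITHMS = ("sift", "polyphen2", "mutation_assessor")
SNV_CLASSES = ("synonymous", "missense", "nonsense")
INDEL_CLASSES = ("frameshift", "inframe_indel")


@dataclass(frozen=True)
class Variant:
    """A genomic small variant in VCF conventions (plus-strand alleles)."""
    contig: str
    position: int  # 1-based
    ref: str
    alt: str

    @property
    def pos0(self) -> int:
        return self.position - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def var_type(self) -> str:
        if self.is_snv:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref}>{self.alt}"


def variant_key(contig: str, position: int, ref: str, alt: str) -> str:
    return f"{contig}:{position}:{ref}>{alt}"


@dataclass
class ConsequenceRecord:
    variant: Variant
    gene_id: str
    var_class: str                 # synonymous/missense/nonsense/frameshift/inframe_indel
    codon_change: str = ""
    protein_change: str = ""
    codon_index: int = 0           # 0-based codon of the (first) affected residue
    verdicts: dict = field(default_factory=dict)
    impact_consensus: bool | None = None


def _check_ref(variant: Variant, ref_seq: str) -> None:
    obs = ref_seq[variant.pos0:variant.pos0 + len(variant.ref)]
    if obs.upper() != variant.ref.upper():
        raise ConsistencyError(
            f"{variant.key}: REF allele {variant.ref!r} does not match reference {obs!r}")


def map_to_cds(variant: Variant, model: GeneModel) -> tuple[int, int] | None:
    """(CDS offset, codon index) of the variant's anchor base, or None if non-coding.

    The offset is in mRNA orientation; on reverse-strand genes the caller
    must complement plus-strand alleles before codon lookup.
    """
    off = model.cds_offset(variant.pos0)
    if off is None:
        return None
    return off, off // 3


def mutant_cds(model: GeneModel, variant: Variant, ref_seq: str) -> str:
    """Rebuild the full mutant CDS by applying the edit inside its exon.

    The edited bases must lie within a single CDS exon (the generator and
    caller guarantee this for the small InDels considered here).
    """
    _check_ref(variant, ref_seq)
    exon = model.exon_of(variant.pos0)
    if exon is None:
        raise ConsistencyError(f"{variant.key}: anchor base outside CDS exons of {model.gene_id}")
    s, e = exon
    if variant.pos0 + len(variant.ref) > e:
        raise ConsistencyError(f"{variant.key}: edit crosses the exon boundary of {model.gene_id}")
    pieces = []
    for (xs, xe) in model.exons:
        seq = ref_seq[xs:xe]
        if (xs, xe) == exon:
            loc = variant.pos0 - xs
            seq = seq[:loc] + variant.alt + seq[loc + len(variant.ref):]
        pieces.append(seq)
    concat = "".join(pieces)
    return revcomp(concat) if model.strand == "-" else concat


def mutant_protein(model: GeneModel, variant: Variant, ref_seq: str) -> str:
    """Mutant protein: translation of the rebuilt mutant CDS to the first stop.

    Covers every class uniformly — missense/nonsense substitution, in-frame
    InDels, and frameshifts whose novel-frame tail runs to the first stop
    encountered (or the end of the CDS when none occurs).
    """
    return translate_cds(mutant_cds(model, variant, ref_seq), to_stop=True)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def classify_consequence(variant: Variant, model: GeneModel, ref_seq: str) -> ConsequenceRecord:
    """Classify a coding variant and derive codon/protein change notation."""
    _check_ref(variant, ref_seq)
    mapped = map_to_cds(variant, model)
    if mapped is None:
        raise ConsistencyError(f"{variant.key}: not inside the CDS of {model.gene_id}")
    off, codon_idx = mapped
    cds = model.cds_sequence(ref_seq)
    if variant.is_snv:
        alt_base = revcomp(variant.alt) if model.strand == "-" else variant.alt
        codon = cds[codon_idx * 3: codon_idx * 3 + 3]
        within = off % 3
        alt_codon = codon[:within] + alt_base + codon[within + 1:]
        ref_aa = translate_cds(codon, to_stop=False)
        alt_aa = translate_cds(alt_codon, to_stop=False)
        if alt_aa == ref_aa:
            klass = "synonymous"
        elif alt_aa == "*":
            klass = "nonsense"
        else:
            klass = "missense"  # includes rare stop-loss; no separate class
        change = f"p.{_aa3(ref_aa)}{codon_idx + 1}{_aa3(alt_aa)}"
        return ConsequenceRecord(variant, model.gene_id, klass,
                                 codon_change=f"{codon}>{alt_codon}",
                                 protein_change=change, codon_index=codon_idx)
    # InDel: frameshift iff the length difference is not a whole number of codons
    delta = len(variant.alt) - len(variant.ref)
    klass = "frameshift" if delta % 3 != 0 else "inframe_indel"
    # first residue whose codon is touched by the edit (mRNA orientation)
    if model.strand == "-":
        # the most 5' edited CDS base is the one with the largest plus coordinate
        first_off = model.cds_offset(variant.pos0)
        edited = [model.cds_offset(p) for p in
                  range(variant.pos0, variant.pos0 + len(variant.ref))]
        first_off = min(o for o in edited if o is not None)
    else:
        first_off = off
    codon_idx = first_off // 3
    ref_aa = translate_cds(cds[codon_idx * 3: codon_idx * 3 + 3], to_stop=False) or "X"
    suffix = "fs" if klass == "frameshift" else ("del" if delta < 0 else "ins")
    change = f"p.{_aa3(ref_aa)}{codon_idx + 1}{suffix}"
    return ConsequenceRecord(variant, model.gene_id, klass,
                             protein_change=change, codon_index=codon_idx)


def consensus_impact(var_class: str, verdicts: Mapping[str, str],
                     nonsense_auto_impact: bool = False) -> bool:
    """Functional-impact consensus.

    missense/nonsense: damaging by >= 2 of the three predictors.
    frameshift/in-frame InDel: damaging by SIFT.
    Missing verdicts count as tolerated (warning logged); a nonsense
    override is available but off by default.
    """
    if var_class == "synonymous":
        return False
    if var_class == "nonsense" and nonsense_auto_impact:
        return True
    if var_class in INDEL_CLASSES:
        v = verdicts.get("sift")
        if v is None:
            logger.warning("missing SIFT verdict for an InDel; counting as tolerated")
        return v == "damaging"
    missing = [a for a in ALGORITHMS if a not in verdicts]
    if missing:
        logger.warning("missing verdicts %s; counting as tolerated", missing)
    n_damaging = sum(1 for a in ALGORITHMS if verdicts.get(a) == "damaging")
    return n_damaging >= 2


def annotate_variant(variant: Variant, models: Sequence[GeneModel], ref_seq: str,
                     verdicts: Mapping[str, str] | None = None,
                     nonsense_auto_impact: bool = False) -> ConsequenceRecord | None:
    """Locate the containing gene model, classify, and apply the consensus rule.

    Returns None for non-coding variants (anchor outside every CDS exon).
    """
    for model in models:
        if model.contains(variant.pos0):
            rec = classify_consequence(variant, model, ref_seq)
            rec.verdicts = dict(verdicts or {})
            rec.impact_consensus = consensus_impact(
                rec.var_class, rec.verdicts, nonsense_auto_impact)
            return rec
    return None
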