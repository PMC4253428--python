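"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (literal
threshold scans, full-sequence rebuild + hand-written codon table) and
share no code path with the package internals they check.
"""
from __future__ import annotations

import numpy as np

# Standard nuclear codon table, written out by hand.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_to_stop(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i:i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def rebuild_mutant_protein(model, variant, ref_seq: str) -> str:
    """Apply the edit to the genome string, re-extract exons, translate.

    Exon coordinates after the edited base shift by the indel length delta;
    the edit is assumed to sit inside one exon (as the generator enforces).
    """
    pos0 = variant.position - 1
    delta = len(variant.alt) - len(variant.ref)
    genome = ref_seq[:pos0] + variant.alt + ref_seq[pos0 + len(variant.ref):]
    new_exons = []
    for s, e in model.exons:
        ns = s + delta if s > pos0 else s
        ne = e + delta if e > pos0 else e
        new_exons.append((ns, ne))
    cds = "".join(genome[s:e] for s, e in new_exons)
    if model.strand == "-":
        cds = rc(cds)
    return translate_to_stop(cds)


def classify_by_protein_diff(model, variant, ref_seq: str) -> str:
    """Consequence class obtained only from allele lengths and protein diff."""
    if len(variant.ref) != len(variant.alt):
        return "frameshift" if abs(len(variant.ref) - len(variant.alt)) % 3 else "inframe_indel"
    ref_cds = "".join(ref_seq[s:e] for s, e in model.exons)
    if model.strand == "-":
        ref_cds = rc(ref_cds)
    ref_prot_full = []
    for i in range(0, len(ref_cds), 3):
        ref_prot_full.append(CODON_TABLE[ref_cds[i:i + 3]])
    mut = rebuild_mutant_protein(model, variant, ref_seq)
    ref = translate_to_stop(ref_cds)
    if mut == ref:
        return "synonymous"
    if len(mut) < len(ref) and ref.startswith(mut):
        return "nonsense"
    return "missense"


def scan_calls(sites, min_bq, min_mq, min_support, strand_mode):
    """Literal re-scan of pileup observations with explicit loops.

    Returns a set of (contig, position, ref, alt, type) tuples.
    """
    found = set()
    for site in sites:
        if site.ref_base not in "ACGT":
            continue
        counts = {}
        for o in site.observations:
            if o.base_quality < min_bq or o.map_quality < min_mq:
                continue
            keys = []
            if o.base in "ACGT" and o.base != site.ref_base:
                keys.append((site.ref_base, o.base, "SNV"))
            if o.indel is not None:
                if o.indel.startswith("+"):
                    keys.append((site.ref_base, site.ref_base + o.indel[1:], "INS"))
                else:
                    keys.append((site.ref_base + o.indel[1:], site.ref_base, "DEL"))
            for k in keys:
                fwd, rev = counts.get(k, (0, 0))
                if o.strand == "+":
                    fwd += 1
                else:
                    rev += 1
                counts[k] = (fwd, rev)
        for (ref, alt, t), (fwd, rev) in counts.items():
            if strand_mode == "per_strand":
                ok = fwd >= min_support and rev >= min_support
            else:
                ok = (fwd + rev) >= min_support and fwd >= 1 and rev >= 1
            if ok:
                found.add((site.contig, site.position, ref, alt, t))
    return found


def random_sites(rng: np.random.Generator, n_sites: int, max_depth: int = 20):
    """Random small pileup sites with a mix of SNV/indel observations."""
    from surfscan.pileup import Observation, PileupSite
    sites = []
    for i in range(n_sites):
        ref = "ACGT"[rng.integers(4)]
        depth = int(rng.integers(0, max_depth + 1))
        obs = []
        for _ in range(depth):
            r = rng.random()
            base = ref if r < 0.55 else ("ACGT"[rng.integers(4)] if r < 0.9 else "*")
            indel = None
            if base != "*" and rng.random() < 0.15:
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, int(rng.integers(1, 4))))
                indel = ("+" if rng.random() < 0.5 else "-") + seq
            strand = "+" if (base == "*" or rng.random() < 0.5) else "-"
            obs.append(Observation(base,
                                   int(rng.integers(0, 42)),
                                   int(rng.integers(0, 61)),
                                   strand,
                                   indel))
        sites.append(PileupSite("chr1", 100 + i, ref, tuple(obs)))
    return sites
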