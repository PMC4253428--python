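"""Gene models: CDS exon structure, coordinate mapping and translation.

Internal coordinates are 0-based half-open; file formats (VCF, pileup)
are 1-based.  A gene model is a single transcript whose concatenated CDS
starts with ATG, ends at a stop codon and has length divisible by 3.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = ["GeneModel", "write_gene_table", "read_gene_table",
           "write_bed", "read_bed", "revcomp", "translate_cds"]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str, to_stop: bool = True) -> str:
    """Translate a CDS codon-by-codon under the standard nuclear code.

    Trailing bases short of a full codon (frameshifted CDS) are ignored;
    with ``to_stop`` translation ends before the first stop codon.
    """
    usable = len(cds) - len(cds) % 3
    prot = str(Seq(cds[:usable]).translate())
    if to_stop:
        stop = prot.find("*")
        if stop != -1:
            return prot[:stop]
    return prot


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str                       # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # CDS exon intervals, genomic order, 0-based half-open

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        last = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e}) in {self.gene_id}")
            if last is not None and s < last:
                raise ValueError(f"overlapping/unsorted exons in {self.gene_id}")
            last = e

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def cds_sequence(self, ref: Mapping[str, str] | str) -> str:
        """CDS in transcript (mRNA) orientation."""
        seq = ref if isinstance(ref, str) else ref[self.contig]
        concat = "".join(seq[s:e] for s, e in self.exons)
        return revcomp(concat) if self.strand == "-" else concat

    def protein(self, ref: Mapping[str, str] | str) -> str:
        return translate_cds(self.cds_sequence(ref), to_stop=True)

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset of a genomic position within the mRNA-orientation CDS.

        Returns None when the position is not inside a CDS exon.
        """
        plus_off = 0
        for s, e in self.exons:
            if s <= pos0 < e:
                plus_off += pos0 - s
                break
            plus_off += e - s
        else:
            return None
        return self.cds_len - 1 - plus_off if self.strand == "-" else plus_off

    def exon_of(self, pos0: int) -> tuple[int, int] | None:
        for s, e in self.exons:
            if s <= pos0 < e:
                return (s, e)
        return None


# --- plain-text I/O ---------------------------------------------------------

_HEADER = "gene_id\tcontig\tstrand\texon_starts\texon_ends"


def write_gene_table(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = [_HEADER]
    for m in models:
        starts = ",".join(str(s) for s, _ in m.exons)
        ends = ",".join(str(e) for _, e in m.exons)
        lines.append(f"{m.gene_id}\t{m.contig}\t{m.strand}\t{starts}\t{ends}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise ValueError(f"unexpected gene-table header in {path}")
        for line in fh:
            gid, contig, strand, starts, ends = line.rstrip("\n").split("\t")
            exons = tuple(zip((int(x) for x in starts.split(",")),
                              (int(x) for x in ends.split(","))))
            models.append(GeneModel(gid, contig, strand, exons))
    return models


def write_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """BED6 of CDS exons (one row per exon)."""
    rows = []
    for m in models:
        for i, (s, e) in enumerate(m.exons):
            rows.append(f"{m.contig}\t{s}\t{e}\t{m.gene_id}_exon{i}\t0\t{m.strand}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals as (contig, start, end), 0-based half-open."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])))
    return out
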