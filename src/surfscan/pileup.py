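"""samtools-mpileup text-dialect parsing.

The expected dialect is seven tab-separated columns (the ``-s`` style):
contig, 1-based position, reference base, depth, read bases, base-quality
string, mapping-quality string.  Read-base grammar handled here:

* ``.``/``,`` — reference match on the forward / reverse strand;
* ``ACGTN`` / ``acgtn`` — mismatch, case encoding strand;
* ``*`` — placeholder within a deletion (consumes a quality);
* ``+n<seq>`` / ``-n<seq>`` — insertion / deletion attached to the
  preceding read observation;
* ``^X`` (start-of-read + mapping-quality char) and ``$`` — consumed.

No installed library parses this text form (BAM-backed pileup engines do
not apply), so the decoder lives here.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from .errors import PileupDialectError, PileupParseError

__all__ = ["Observation", "PileupSite", "parse_pileup", "format_site"]

_BASE_CHARS = set(".,ACGTNacgtn*<>")


@dataclass(frozen=True)
class Observation:
    """One read's evidence at a site.

    ``base`` is the plus-strand allele ('A'..'N', or '*' inside a deletion);
    ``indel`` is None or a VCF-flavoured suffix: '+SEQ' for an insertion
    after this base, '-SEQ' for a deletion of the following bases.
    """
    base: str
    base_quality: int
    map_quality: int
    strand: str  # '+' or '-'
    indel: str | None = None


@dataclass(frozen=True)
class PileupSite:
    contig: str
    position: int  # 1-based
    ref_base: str
    observations: tuple[Observation, ...]

    @property
    def depth(self) -> int:
        return len(self.observations)


def _scan_bases(bases: str, ref: str, lineno: int) -> list[tuple[str, str, str | None]]:
    """Decode the read-base column into (base, strand, indel) triples."""
    out: list[tuple[str, str, str | None]] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(lineno, "dangling '^' start marker")
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c not in _BASE_CHARS:
            raise PileupParseError(lineno, f"unexpected character {c!r} in read bases")
        if c in ".,":
            base, strand = ref.upper(), ("+" if c == "." else "-")
        elif c in "*<>":
            base, strand = "*", "+"
        else:
            base, strand = c.upper(), ("+" if c.isupper() else "-")
        i += 1
        indel = None
        if i < n and bases[i] in "+-":
            sign = bases[i]
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            if j == i:
                raise PileupParseError(lineno, f"indel token missing length after {sign!r}")
            length = int(bases[i:j])
            seq = bases[j:j + length]
            if len(seq) != length or not all(ch.upper() in "ACGTN" for ch in seq):
                raise PileupParseError(lineno, "indel token shorter than its declared length")
            indel = sign + seq.upper()
            i = j + length
        out.append((base, strand, indel))
    return out


def parse_pileup(stream: TextIO | Iterable[str]) -> Iterator[PileupSite]:
    """Parse an mpileup stream into :class:`PileupSite` records.

    Raises :class:`PileupParseError` (with the line number) on malformed
    lines and :class:`PileupDialectError` when the mapping-quality column
    is absent.
    """
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 6:
            raise PileupDialectError(
                f"line {lineno}: six columns found; the mapping-quality column is "
                "required (samtools mpileup -s)")
        if len(fields) < 7:
            raise PileupParseError(lineno, f"expected 7 columns, found {len(fields)}")
        contig, pos_s, ref, depth_s, bases, bquals, mquals = fields[:7]
        try:
            pos, depth = int(pos_s), int(depth_s)
        except ValueError:
            raise PileupParseError(lineno, "position/depth not integers") from None
        if depth == 0:
            yield PileupSite(contig, pos, ref.upper(), ())
            continue
        triples = _scan_bases(bases, ref, lineno)
        if not (len(triples) == len(bquals) == len(mquals) == depth):
            raise PileupParseError(
                lineno, f"depth {depth} disagrees with {len(triples)} bases, "
                        f"{len(bquals)} base qualities, {len(mquals)} map qualities")
        obs = tuple(
            Observation(base, ord(bq) - 33, ord(mq) - 33, strand, indel)
            for (base, strand, indel), bq, mq in zip(triples, bquals, mquals))
        yield PileupSite(contig, pos, ref.upper(), obs)


def format_site(site: PileupSite) -> str:
    """Render a site back to the mpileup -s text dialect (round-trip helper)."""
    if site.depth == 0:
        return f"{site.contig}\t{site.position}\t{site.ref_base}\t0\t*\t*\t*"
    chunks, bqs, mqs = [], [], []
    for o in site.observations:
        if o.base == "*":
            c = "*"
        elif o.base == site.ref_base:
            c = "." if o.strand == "+" else ","
        else:
            c = o.base if o.strand == "+" else o.base.lower()
        if o.indel:
            seq = o.indel[1:]
            c += o.indel[0] + str(len(seq)) + (seq if o.strand == "+" else seq.lower())
        chunks.append(c)
        bqs.append(chr(o.base_quality + 33))
        mqs.append(chr(o.map_quality + 33))
    return (f"{site.contig}\t{site.position}\t{site.ref_base}\t{site.depth}\t"
            f"{''.join(chunks)}\t{''.join(bqs)}\t{''.join(mqs)}")
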