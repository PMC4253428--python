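"""Somatic point-mutation detection on pileup evidence.

The caller is a deterministic filter cascade, not a probabilistic model:
a variant is emitted when enough high-quality reads (base quality >= 25,
mapping quality >= 20 by default) support the alternate allele under the
configured strand rule, then candidate calls are cleaned of known germline
polymorphisms (allele-aware, after indel normalization) and of variants
recurring across more than ``k`` cell lines unless whitelisted.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .config import CallerThresholds
from .errors import SurfscanError
from .pileup import PileupSite

logger = logging.getLogger(__name__)

__all__ = ["VariantCall", "CoverageStats", "call_variants", "normalize_variant",
           "load_germline_db", "filter_germline", "flag_recurrent",
           "coverage_summary", "mutation_rate"]

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantCall:
    contig: str
    position: int          # 1-based
    ref: str
    alt: str
    var_type: str          # SNV / INS / DEL
    fwd_hq_support: int
    rev_hq_support: int
    depth: int
    cell_line: str
    flags: set = dc_field(default_factory=set)

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def is_somatic(self) -> bool:
        return ("germline" not in self.flags and
                ("recurrent_suspect" not in self.flags or "whitelisted" in self.flags))


@dataclass(frozen=True)
class CoverageStats:
    mean_depth: float
    pct_covered: float      # percent of target with depth >= 1
    pct_covered_10x: float  # percent of target with depth >= 10
    on_target_bases: int


def _support_ok(fwd: int, rev: int, thresholds: CallerThresholds) -> bool:
    k = thresholds.min_support_per_strand
    if thresholds.strand_mode == "per_strand":
        return fwd >= k and rev >= k
    return fwd + rev >= k and fwd >= 1 and rev >= 1


def call_variants(sites: Iterable[PileupSite], thresholds: CallerThresholds,
                  cell_line: str) -> list[VariantCall]:
    """Emit one call per (site, alternate allele) meeting the strand rule.

    High-quality support = reads with base quality >= ``min_base_quality``
    AND mapping quality >= ``min_map_quality``.  Output is ordered by
    (contig, position, alt).
    """
    thresholds.validate()
    calls: list[VariantCall] = []
    for site in sites:
        if site.ref_base not in "ACGT":
            continue
        support: dict[tuple[str, str, str], list[int]] = defaultdict(lambda: [0, 0])
        for o in site.observations:
            hq = (o.base_quality >= thresholds.min_base_quality and
                  o.map_quality >= thresholds.min_map_quality)
            if not hq:
                continue
            s = 0 if o.strand == "+" else 1
            if o.base in "ACGT" and o.base != site.ref_base:
                support[(site.ref_base, o.base, "SNV")][s] += 1
            if o.indel is not None:
                if o.indel[0] == "+":
                    key = (site.ref_base, site.ref_base + o.indel[1:], "INS")
                else:
                    key = (site.ref_base + o.indel[1:], site.ref_base, "DEL")
                support[key][s] += 1
        for (ref, alt, vtype), (fwd, rev) in sorted(support.items(), key=lambda kv: kv[0][1]):
            if _support_ok(fwd, rev, thresholds):
                calls.append(VariantCall(site.contig, site.position, ref, alt, vtype,
                                         fwd, rev, site.depth, cell_line))
    calls.sort(key=lambda c: (c.contig, c.position, c.alt))
    return calls


# --- germline filtering -----------------------------------------------------

def normalize_variant(position: int, ref: str, alt: str,
                      seq: str | None = None) -> tuple[int, str, str]:
    """Trim shared prefix/suffix and left-shift indels (when ``seq`` given).

    ``seq`` is the full contig sequence; position is 1-based.  Resolves the
    representational ambiguity of anchored indels before key matching.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if seq is not None and len(ref) != len(alt):
        while (min(len(ref), len(alt)) == 1 and ref[-1] == alt[-1]
               and position > 1):
            prev = seq[position - 2].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            position -= 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def load_germline_db(vcf_path: str | Path,
                     reference: Mapping[str, str] | None = None) -> set[VariantKey]:
    """Load a known-germline VCF into a set of normalized variant keys."""
    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            seq = reference.get(rec.contig) if reference else None
            for alt in rec.alts or ():
                pos, ref, a = normalize_variant(rec.pos, rec.ref, alt, seq)
                if (pos, ref, a) != (rec.pos, rec.ref.upper(), alt.upper()):
                    logger.warning("germline record %s:%s %s>%s normalized to %s:%s %s>%s",
                                   rec.contig, rec.pos, rec.ref, alt, rec.contig, pos, ref, a)
                keys.add((rec.contig, pos, ref, a))
    return keys


def filter_germline(calls: Sequence[VariantCall], germline: set[VariantKey] | str | Path,
                    reference: Mapping[str, str] | None = None) -> list[VariantCall]:
    """Flag exact (normalized) germline matches; return the somatic remainder."""
    if not isinstance(germline, set):
        germline = load_germline_db(germline, reference)
    else:
        normed = set()
        for contig, pos, ref, alt in germline:
            seq = reference.get(contig) if reference else None
            normed.add((contig, *normalize_variant(pos, ref, alt, seq)))
        germline = normed
    somatic = []
    for c in calls:
        seq = reference.get(c.contig) if reference else None
        pos, ref, alt = normalize_variant(c.position, c.ref, c.alt, seq)
        if (c.contig, pos, ref, alt) in germline:
            c.flags.add("germline")
        else:
            somatic.append(c)
    return somatic


# --- recurrence across cell lines -------------------------------------------

def flag_recurrent(calls_by_line: Mapping[str, Sequence[VariantCall]], k: int = 3,
                   whitelist: Iterable[VariantKey] = ()) -> dict[str, list[VariantCall]]:
    """Flag variants seen in more than ``k`` cell lines as suspect artifacts.

    Whitelisted keys (the stand-in for manual inspection of genuine hotspot
    mutations) are flagged but retained; other suspects are excluded from
    the returned somatic sets.
    """
    wl = set(whitelist)
    lines_per_key: dict[VariantKey, set[str]] = defaultdict(set)
    for line, calls in calls_by_line.items():
        for c in calls:
            lines_per_key[c.key].add(line)
    kept: dict[str, list[VariantCall]] = {}
    for line, calls in calls_by_line.items():
        out = []
        for c in calls:
            if len(lines_per_key[c.key]) > k:
                c.flags.add("recurrent_suspect")
                if c.key in wl:
                    c.flags.add("whitelisted")
                    out.append(c)
            else:
                out.append(c)
        kept[line] = out
    return kept


# --- summaries --------------------------------------------------------------

def coverage_summary(sites: Iterable[PileupSite],
                     targets: Sequence[tuple[str, int, int]]) -> CoverageStats:
    """Depth statistics over the target intervals (0-based half-open)."""
    size = sum(e - s for _, s, e in targets)
    if size <= 0:
        raise SurfscanError("empty target region")
    depth_at: dict[tuple[str, int], int] = {}
    for site in sites:
        depth_at[(site.contig, site.position)] = site.depth
    total = covered = covered10 = 0
    for contig, s, e in targets:
        for pos0 in range(s, e):
            d = depth_at.get((contig, pos0 + 1), 0)
            total += d
            covered += d >= 1
            covered10 += d >= 10
    return CoverageStats(mean_depth=total / size,
                         pct_covered=100.0 * covered / size,
                         pct_covered_10x=100.0 * covered10 / size,
                         on_target_bases=total)


def mutation_rate(somatic_calls: Sequence[VariantCall] | int, target_size: int) -> float:
    """Somatic SNVs per targeted base."""
    if target_size <= 0:
        raise SurfscanError(f"target_size must be positive, got {target_size}")
    if isinstance(somatic_calls, int):
        n = somatic_calls
    else:
        n = sum(1 for c in somatic_calls if c.var_type == "SNV")
    return n / target_size
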