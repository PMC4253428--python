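"""Per-cell-line summaries and panel-level aggregate statistics.

Column names of the summary table are a stable, documented schema (see
``SUMMARY_COLUMNS``).  Aggregate means are rounded half-away-from-zero to
match the integer style in which panel averages are conventionally quoted.
Two reference tables transcribed from the published 23-line colorectal
panel that this pipeline emulates ship as package data and drive the
printed-average checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .calling import CoverageStats, VariantCall, mutation_rate
from .consequence import ConsequenceRecord
from .epitopes import EpitopeCall
from .errors import StageError

__all__ = ["CellLineSummary", "AggregateReport", "summarize_cell_line", "aggregate",
           "round_half_away", "pct", "load_panel_snv_indel_table",
           "load_panel_impact_table", "SUMMARY_COLUMNS", "PANEL_TARGET_BP"]

#: Constant targeted-region size (bases) consistent with the published
#: per-line mutation rates of the reference panel (~6 Mb capture design).
PANEL_TARGET_BP = 6_101_190

SUMMARY_COLUMNS = [
    "cell_line", "mutator", "snvs", "pct_snvs_germline", "somatic_snvs",
    "somatic_nonsyn_snvs", "nonsense_snvs", "indels", "somatic_indels",
    "frameshift_indels", "impact_nonsyn", "impact_indels",
    "druggable_mutations", "expressed_druggable_mutations",
    "mutated_epitopes", "expressed_mutated_epitopes", "mutation_rate",
    "mean_depth", "pct_covered", "pct_covered_10x",
]

COUNT_COLUMNS = [
    "snvs", "somatic_snvs", "somatic_nonsyn_snvs", "nonsense_snvs", "indels",
    "somatic_indels", "frameshift_indels", "impact_nonsyn", "impact_indels",
    "druggable_mutations", "expressed_druggable_mutations",
    "mutated_epitopes", "expressed_mutated_epitopes",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pct(a: float, b: float) -> int:
    """Integer percentage a/b, rounded half away from zero."""
    if b == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * a / b)


@dataclass
class CellLineSummary:
    cell_line: str
    mutator: bool
    snvs: int
    pct_snvs_germline: float
    somatic_snvs: int
    somatic_nonsyn_snvs: int
    nonsense_snvs: int
    indels: int
    somatic_indels: int
    frameshift_indels: int
    impact_nonsyn: int
    impact_indels: int
    druggable_mutations: int
    expressed_druggable_mutations: int
    mutated_epitopes: int
    expressed_mutated_epitopes: int
    mutation_rate: float
    coverage: CoverageStats

    def __post_init__(self):
        checks = [
            self.somatic_snvs <= self.snvs,
            self.somatic_indels <= self.indels,
            self.nonsense_snvs <= self.somatic_nonsyn_snvs,
            self.frameshift_indels <= self.somatic_indels,
            self.expressed_druggable_mutations <= self.druggable_mutations,
            self.expressed_mutated_epitopes <= self.mutated_epitopes,
        ]
        if not all(checks):
            raise StageError(f"inconsistent tallies for {self.cell_line}: {self}")

    def as_row(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "mutator": "Yes" if self.mutator else "No",
            "snvs": self.snvs,
            "pct_snvs_germline": self.pct_snvs_germline,
            "somatic_snvs": self.somatic_snvs,
            "somatic_nonsyn_snvs": self.somatic_nonsyn_snvs,
            "nonsense_snvs": self.nonsense_snvs,
            "indels": self.indels,
            "somatic_indels": self.somatic_indels,
            "frameshift_indels": self.frameshift_indels,
            "impact_nonsyn": self.impact_nonsyn,
            "impact_indels": self.impact_indels,
            "druggable_mutations": self.druggable_mutations,
            "expressed_druggable_mutations": self.expressed_druggable_mutations,
            "mutated_epitopes": self.mutated_epitopes,
            "expressed_mutated_epitopes": self.expressed_mutated_epitopes,
            "mutation_rate": self.mutation_rate,
            "mean_depth": self.coverage.mean_depth,
            "pct_covered": self.coverage.pct_covered,
            "pct_covered_10x": self.coverage.pct_covered_10x,
        }


@dataclass
class AggregateReport:
    n_lines: int
    means: dict = field(default_factory=dict)          # column -> rounded integer mean
    totals: dict = field(default_factory=dict)         # column -> column sum
    unique_totals: dict = field(default_factory=dict)  # dedup across lines, when keys given


def summarize_cell_line(cell_line: str,
                        all_calls: Sequence[VariantCall],
                        somatic_calls: Sequence[VariantCall],
                        records: Sequence[ConsequenceRecord],
                        druggable_genes: set,
                        expression_flags,
                        epitope_calls: Sequence[EpitopeCall],
                        gene_of_record: Mapping[str, str] | None,
                        mutator: bool,
                        coverage: CoverageStats,
                        target_size: int) -> CellLineSummary:
    """Assemble the per-line tallies from the upstream stage outputs.

    ``records`` are the consequence annotations of this line's somatic
    calls; ``epitope_calls`` its (already expression-gated) epitope calls.
    """
    for name, value in [("calling", all_calls), ("consequence", records),
                        ("coverage", coverage)]:
        if value is None:
            raise StageError(f"missing output from stage {name!r}")
    snvs = [c for c in all_calls if c.var_type == "SNV"]
    indels = [c for c in all_calls if c.var_type != "SNV"]
    germ_snvs = sum(1 for c in snvs if "germline" in c.flags)
    som_snv = [c for c in somatic_calls if c.var_type == "SNV"]
    som_indel = [c for c in somatic_calls if c.var_type != "SNV"]
    nonsyn = [r for r in records if r.var_class in ("missense", "nonsense")]
    nonsense = [r for r in records if r.var_class == "nonsense"]
    frameshift = [r for r in records if r.var_class == "frameshift"]
    indel_recs = [r for r in records if r.var_class in ("frameshift", "inframe_indel")]
    impact_nonsyn = sum(1 for r in nonsyn if r.impact_consensus)
    impact_indel = sum(1 for r in indel_recs if r.impact_consensus)
    druggable = [r for r in records if r.var_class != "synonymous"
                 and r.gene_id in druggable_genes]
    expressed_druggable = [
        r for r in druggable
        if expression_flags is not None
        and expression_flags.expressed_in(r.gene_id, cell_line)]
    epis = [e for e in epitope_calls if e.called]
    expressed_epis = [e for e in epis if e.expressed]
    return CellLineSummary(
        cell_line=cell_line,
        mutator=mutator,
        snvs=len(snvs),
        pct_snvs_germline=(100.0 * germ_snvs / len(snvs)) if snvs else 0.0,
        somatic_snvs=len(som_snv),
        somatic_nonsyn_snvs=len(nonsyn),
        nonsense_snvs=len(nonsense),
        indels=len(indels),
        somatic_indels=len(som_indel),
        frameshift_indels=len(frameshift),
        impact_nonsyn=impact_nonsyn,
        impact_indels=impact_indel,
        druggable_mutations=len(druggable),
        expressed_druggable_mutations=len(expressed_druggable),
        mutated_epitopes=len(epis),
        expressed_mutated_epitopes=len(expressed_epis),
        mutation_rate=mutation_rate(len(som_snv), target_size),
        coverage=coverage,
    )


def aggregate(summaries: pd.DataFrame | Sequence[CellLineSummary],
              variant_keys_by_line: Mapping[str, Sequence] | None = None,
              ) -> AggregateReport:
    """Panel aggregate: per-column totals and rounded means over cell lines.

    ``variant_keys_by_line`` (optional) deduplicates variants shared across
    lines; unique totals are therefore <= column sums, with equality iff no
    variant recurs.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([s.as_row() for s in summaries])
    if len(summaries) == 0:
        raise StageError("aggregate requires at least one cell-line summary")
    rep = AggregateReport(n_lines=len(summaries))
    for col in COUNT_COLUMNS:
        if col in summaries.columns:
            total = float(summaries[col].sum())
            rep.totals[col] = int(total)
            rep.means[col] = round_half_away(total / len(summaries))
    if variant_keys_by_line is not None:
        seen = set()
        for keys in variant_keys_by_line.values():
            seen.update(keys)
        rep.unique_totals["variants"] = len(seen)
    return rep


# --- packaged reference tables ----------------------------------------------

def _load_table(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("surfscan.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t")


def load_panel_snv_indel_table() -> pd.DataFrame:
    """Published per-line SNV/InDel counts of the 23-line reference panel."""
    return _load_table("panel23_snv_indel.tsv")


def load_panel_impact_table() -> pd.DataFrame:
    """Published per-line impact/druggable/epitope counts of the reference panel."""
    return _load_table("panel23_impact_druggable_epitopes.tsv")
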