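"""Expression gating, druggability annotation, recurrence and novelty.

A gene counts as expressed in a cell line when its RNA-seq FPKM is >= 3 or
its array log-intensity is >= 5.5, depending on the platform assayed for
that line; a gene is globally expressed when it passes in at least one
line.  Downstream tallies (druggable mutations, recurrently mutated genes,
novel genes) are restricted to mutated-and-expressed genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionFlags", "GeneStatus", "gate_expression", "annotate_druggable",
           "recurrence_summary", "novel_genes",
           "RNASEQ_THRESHOLD", "ARRAY_THRESHOLD"]

RNASEQ_THRESHOLD = 3.0
ARRAY_THRESHOLD = 5.5


@dataclass
class ExpressionFlags:
    per_line: dict[tuple[str, str], bool]   # (gene, cell line) -> expressed
    per_gene: dict[str, bool]               # gene -> expressed in >= 1 line

    def expressed_in(self, gene: str, cell_line: str) -> bool:
        flag = self.per_line.get((gene, cell_line))
        if flag is None:
            logger.warning("no expression value for %s in %s; counting as unexpressed",
                           gene, cell_line)
            return False
        return flag


@dataclass
class GeneStatus:
    gene_id: str
    mutated_in: set = field(default_factory=set)
    expressed_in: set = field(default_factory=set)
    mutated_and_expressed_fraction: float = 0.0
    druggable: bool = False
    novel: bool = False


def gate_expression(genes: Iterable[str], expression: pd.DataFrame,
                    rnaseq_threshold: float = RNASEQ_THRESHOLD,
                    array_threshold: float = ARRAY_THRESHOLD) -> ExpressionFlags:
    """Apply the platform thresholds to a tidy (gene, cell_line, platform, value) table.

    Thresholds are inclusive (a value exactly at threshold is expressed).
    Genes absent from the table are flagged unexpressed with a warning.
    """
    genes = list(genes)
    per_line: dict[tuple[str, str], bool] = {}
    for row in expression.itertuples(index=False):
        thr = rnaseq_threshold if row.platform == "rnaseq" else array_threshold
        per_line[(row.gene_id, row.cell_line)] = bool(row.value >= thr)
    seen = {g for g, _ in per_line}
    for g in genes:
        if g not in seen:
            logger.warning("gene %s missing from the expression table", g)
    per_gene = {g: any(flag for (gg, _), flag in per_line.items() if gg == g)
                for g in genes}
    return ExpressionFlags(per_line, per_gene)


def annotate_druggable(statuses: Mapping[str, GeneStatus],
                       druggable: Iterable[str]) -> dict[str, GeneStatus]:
    """Set the druggable flag by membership in the drug–gene interaction list."""
    dg = set(druggable)
    for g, st in statuses.items():
        st.druggable = g in dg
    return dict(statuses)


def recurrence_summary(mutated_expressed_lines: Mapping[str, set],
                       n_lines: int) -> pd.DataFrame:
    """Per-gene frequency of being mutated-and-expressed across the panel.

    ``mutated_expressed_lines`` maps gene -> set of lines where the gene is
    both mutated and expressed.  The >10% and >20% membership columns use
    strict inequality on the fraction (3/23 = 13% qualifies for >10%).
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    rows = []
    for gene in sorted(mutated_expressed_lines):
        lines = mutated_expressed_lines[gene]
        f = len(lines) / n_lines
        rows.append((gene, len(lines), f, f > 0.10, f > 0.20))
    return pd.DataFrame(rows, columns=[
        "gene_id", "n_lines_mutated_expressed", "fraction", "gt10pct", "gt20pct"])


def novel_genes(mutated_expressed: Iterable[str], known: Iterable[str]) -> list[str]:
    """Mutated-and-expressed genes absent from the known-mutated list, sorted."""
    return sorted(set(mutated_expressed) - set(known))
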