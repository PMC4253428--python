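"""Mutated-epitope prediction for MHC class I (single configured allele).

Peptides around missense and frameshift mutations (10-residue flanks) are
decomposed into 9-mers, scored by two pluggable PSSM-based scorers —
percent-of-optimum and an IC50 transform — gated by a proteasomal-cleavage
predicate, and called as mutated epitopes when they either have no
reference counterpart (novel frameshift sequence) or out-bind their
same-start reference window by the differential factor under BOTH scorers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ScorerConfig
from .consequence import ConsequenceRecord
from .errors import ScoringError

__all__ = ["PeptidePair", "EpitopeCall", "load_pssm", "packaged_pssm",
           "extract_peptides", "enumerate_9mers", "percent_optimum",
           "affinity_ic50", "cleavage_ok", "call_mutated_epitopes",
           "gate_epitope_expression", "AMINO_ACIDS"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NINE = 9


@dataclass(frozen=True)
class PeptidePair:
    gene_id: str
    cell_line: str
    variant_key: str
    origin: str              # 'missense' or 'frameshift'
    reference_peptide: str
    mutant_peptide: str
    mutation_offset: int     # 0-based index of the (first) mutated residue in mutant_peptide


@dataclass
class EpitopeCall:
    peptide: str             # mutant 9-mer
    window_start: int        # start within the mutant peptide
    percent_optimum: float
    ic50: float
    cleaved: bool
    reference_peptide: str | None   # same-start reference 9-mer, if it exists
    ref_percent_optimum: float | None
    ref_ic50: float | None
    decision: str            # called_unique / called_differential / rejected
    expressed: bool | None = None

    @property
    def called(self) -> bool:
        return self.decision.startswith("called")


# --- PSSM handling ----------------------------------------------------------

def load_pssm(path: str | Path) -> np.ndarray:
    """Read a 9x20 position-specific scoring matrix from TSV.

    Rows = peptide positions 1-9, columns = the 20 residues (one-letter,
    header row).  Returned as float ndarray indexed [position, residue].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(AMINO_ACIDS):
        df = df[list(AMINO_ACIDS)]
    mat = df.to_numpy(dtype=float)
    if mat.shape != (NINE, len(AMINO_ACIDS)):
        raise ScoringError(f"PSSM must be 9x20, got {mat.shape}")
    if not np.all(np.isfinite(mat)):
        raise ScoringError("PSSM contains non-finite entries")
    return mat


def packaged_pssm() -> np.ndarray:
    """The packaged synthetic HLA-A*02:01-like example matrix."""
    with resources.as_file(resources.files("surfscan.data")
                           .joinpath("hla_a0201_synthetic_pssm.tsv")) as p:
        return load_pssm(p)


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _raw_score(nine_mer: str, pssm: np.ndarray) -> float:
    if len(nine_mer) != NINE:
        raise ScoringError(f"peptide must be 9 residues, got {nine_mer!r}")
    try:
        return float(sum(pssm[i, _AA_INDEX[a]] for i, a in enumerate(nine_mer)))
    except KeyError as exc:
        raise ScoringError(f"non-standard residue {exc.args[0]!r} in {nine_mer!r}") from None


def percent_optimum(nine_mer: str, pssm: np.ndarray) -> float:
    """Additive PSSM score as a percentage of the matrix optimum.

    100 x S / S_max, where S_max is the sum of per-position column maxima.
    """
    s_max = float(pssm.max(axis=1).sum())
    if s_max <= 0:
        raise ScoringError("PSSM optimum must be positive for percent-optimum scoring")
    return 100.0 * _raw_score(nine_mer, pssm) / s_max


def affinity_ic50(nine_mer: str, pssm: np.ndarray, cap: float = 50000.0) -> float:
    """Monotone PSSM-to-IC50 transform (nM): cap ** (1 - x).

    x is the min-max normalised score (per-position column minima/maxima),
    clipped to [0, 1]; the strongest peptide maps to 1 nM, the weakest to
    ``cap`` nM, and IC50 is strictly decreasing in the raw score between.
    """
    s_max = float(pssm.max(axis=1).sum())
    s_min = float(pssm.min(axis=1).sum())
    if s_max == s_min:
        raise ScoringError("degenerate PSSM: identical column extrema")
    x = (_raw_score(nine_mer, pssm) - s_min) / (s_max - s_min)
    x = min(1.0, max(0.0, x))
    return cap ** (1.0 - x)


# --- peptide construction ---------------------------------------------------

def extract_peptides(record: ConsequenceRecord, reference_protein: str,
                     mutant_protein: str, flank: int = 10,
                     cell_line: str = "") -> PeptidePair | None:
    """Build the mutant/reference peptide pair around a mutation.

    missense: a (2*flank+1)-mer centred on the substituted residue
    (truncated at the protein termini).  frameshift: up to ``flank``
    reference residues before the shifted codon plus the entire novel tail
    to the stop.  Synonymous and nonsense records yield no pair.
    """
    k = record.codon_index
    if record.var_class == "missense":
        if k >= len(mutant_protein) or k >= len(reference_protein):
            return None
        if mutant_protein[k] == reference_protein[k]:
            return None  # synonymous leak: no mutated residue
        start = max(0, k - flank)
        ref_pep = reference_protein[start:k + flank + 1]
        mut_pep = mutant_protein[start:k + flank + 1]
        return PeptidePair(record.gene_id, cell_line, record.variant.key,
                           "missense", ref_pep, mut_pep, k - start)
    if record.var_class == "frameshift":
        start = max(0, k - flank)
        mut_pep = mutant_protein[start:]
        ref_pep = reference_protein[start:start + len(mut_pep)]
        if not mut_pep:
            return None
        return PeptidePair(record.gene_id, cell_line, record.variant.key,
                           "frameshift", ref_pep, mut_pep, k - start)
    return None


def enumerate_9mers(peptide: str) -> list[tuple[str, int]]:
    """All contiguous 9-mers with their start offsets (max(0, L-8) windows)."""
    return [(peptide[i:i + NINE], i) for i in range(len(peptide) - NINE + 1)]


def cleavage_ok(nine_mer: str, context: str = "",
                predictor: Callable[[str, str], bool] | None = None,
                cterm_set: str = "LVIFYWMKR") -> bool:
    """Proteasomal-cleavage gate.

    Pluggable: a custom ``predictor(nine_mer, context)`` replaces the
    default rule, which accepts peptides whose C-terminal residue is in
    ``cterm_set`` (hydrophobic/basic residues favoured by the proteasome).
    """
    if predictor is not None:
        return bool(predictor(nine_mer, context))
    return nine_mer[-1] in cterm_set


def _passes_binders(pct: float, ic50: float, config: ScorerConfig) -> bool:
    return pct >= config.percent_optimum_threshold and ic50 <= config.ic50_threshold


def call_mutated_epitopes(pair: PeptidePair, pssm: np.ndarray,
                          config: ScorerConfig | None = None,
                          cleavage_predictor: Callable[[str, str], bool] | None = None,
                          ) -> list[EpitopeCall]:
    """Score and decide every mutant 9-mer that overlaps mutated/novel residues.

    Candidate = passes both binder thresholds (percent-optimum and IC50) and
    the cleavage gate.  Decision:

    * no full-length same-start reference window (novel frameshift tail) and
      the 9-mer is absent from the reference peptide's own 9-mer set
      -> ``called_unique``;
    * otherwise ``called_differential`` iff mutant affinity >= factor x
      reference affinity under BOTH scorers (percent-optimum, and 1/IC50);
    * else ``rejected``.
    """
    config = (config or ScorerConfig()).validate()
    ref_set = {w for w, _ in enumerate_9mers(pair.reference_peptide)}
    out: list[EpitopeCall] = []
    L = len(pair.mutant_peptide)
    for window, s in enumerate_9mers(pair.mutant_peptide):
        if pair.origin == "missense":
            if not (s <= pair.mutation_offset <= s + NINE - 1):
                continue
        else:  # frameshift: everything from mutation_offset on is novel
            if s + NINE - 1 < pair.mutation_offset:
                continue
        pct = percent_optimum(window, pssm)
        ic50 = affinity_ic50(window, pssm, config.ic50_cap)
        context = pair.mutant_peptide[s + NINE:s + NINE + 1]
        cleaved = cleavage_ok(window, context, cleavage_predictor,
                              config.cleavage_cterm)
        ref_win = pair.reference_peptide[s:s + NINE]
        has_counterpart = len(ref_win) == NINE
        ref_pct = percent_optimum(ref_win, pssm) if has_counterpart else None
        ref_ic50 = affinity_ic50(ref_win, pssm, config.ic50_cap) if has_counterpart else None
        decision = "rejected"
        if _passes_binders(pct, ic50, config) and cleaved:
            usable_counterpart = has_counterpart
            if usable_counterpart and config.require_reference_candidate:
                usable_counterpart = _passes_binders(ref_pct, ref_ic50, config)
            if not usable_counterpart:
                if window not in ref_set:
                    decision = "called_unique"
            else:
                r1 = pct / ref_pct if ref_pct > 0 else math.inf
                r2 = (1.0 / ic50) / (1.0 / ref_ic50)
                f = config.differential_factor
                ok = (r1 > f and r2 > f) if config.strict_differential else \
                     (r1 >= f and r2 >= f)
                if ok:
                    decision = "called_differential"
        out.append(EpitopeCall(window, s, pct, ic50, cleaved,
                               ref_win if has_counterpart else None,
                               ref_pct, ref_ic50, decision))
    return out


def gate_epitope_expression(calls: Sequence[EpitopeCall], gene_id: str,
                            cell_line: str, flags) -> list[EpitopeCall]:
    """Attach the source gene's per-line expression flag to each call."""
    expressed = flags.expressed_in(gene_id, cell_line)
    for c in calls:
        c.expressed = expressed
    return list(calls)
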