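"""Exception hierarchy for the surfscan pipeline."""


class SurfscanError(Exception):
    """Base class for all surfscan errors."""


class ConfigError(SurfscanError):
    """Invalid configuration value; the message names the offending field."""


class GenerationError(SurfscanError):
    """Synthetic-data generation could not satisfy its constraints."""


class LookupError_(SurfscanError):
    """Unknown cell line or gene identifier."""


class PileupParseError(SurfscanError):
    """Malformed pileup line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"pileup line {lineno}: {message}")


class PileupDialectError(SurfscanError):
    """Stream is not the expected mpileup dialect (e.g. missing the mapping-quality column)."""


class ConsistencyError(SurfscanError):
    """A variant's REF allele disagrees with the reference sequence."""


class ScoringError(SurfscanError):
    """Peptide or matrix unsuitable for PSSM scoring."""


class StageError(SurfscanError):
    """A pipeline stage is missing its inputs; the message names the stage."""
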