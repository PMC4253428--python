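"""Expression gating, druggability and recurrence across the panel.

Restricts mutated genes to those expressed (FPKM >= 3 on RNA-seq lines,
intensity >= 5.5 on array lines), flags druggable-list membership and
derives the recurrently mutated (>10%, >20% of lines) and novel gene sets.
"""
from pathlib import Path

import pandas as pd

from surfscan.pipeline import stage_integrate

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main():
    stage_integrate(OUT)
    status = pd.read_csv(OUT / "gene_status.tsv", sep="\t")
    rec = pd.read_csv(OUT / "recurrence.tsv", sep="\t")
    print(f"gene status written to {OUT/'gene_status.tsv'} ({len(status)} mutated genes)")
    print(f"  mutated and expressed in >10% of lines: {int(rec.gt10pct.sum())}")
    print(f"  mutated and expressed in >20% of lines: {int(rec.gt20pct.sum())}")
    print(f"  druggable mutated genes: {(status.druggable == 'yes').sum()}")
    print(f"  novel (absent from the known-mutated list): {(status.novel == 'yes').sum()}")


if __name__ == "__main__":
    main()
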