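"""Mutated-epitope prediction over missense and frameshift variants.

Windows each mutation (10-residue flanks), scores all mutant 9-mers with
the dual PSSM scorers (percent-optimum >= 50, IC50 <= 500 nM), gates by
proteasomal cleavage, and calls epitopes that are novel or out-bind their
reference counterpart by >= 1.2x under both scorers.
"""
from pathlib import Path

import pandas as pd

from surfscan.pipeline import stage_epitopes

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main():
    stage_epitopes(OUT)
    epis = pd.read_csv(OUT / "epitopes.tsv", sep="\t")
    called = epis[epis.decision.str.startswith("called")]
    print(f"epitope calls written to {OUT/'epitopes.tsv'} "
          f"({len(epis)} scored windows, {len(called)} called)")
    print(called.decision.value_counts().to_string())
    if len(called):
        expressed = called[called.expressed == "yes"]
        print(f"expressed epitopes: {len(expressed)}/{len(called)} "
              f"({100 * len(expressed) / len(called):.0f}%)")
        by_origin = called.origin.value_counts()
        print(f"by origin: {by_origin.to_dict()}")


if __name__ == "__main__":
    main()
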