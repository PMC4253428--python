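"""Coding-consequence annotation of the somatic calls.

Classifies each call (synonymous / missense / nonsense / frameshift /
in-frame) against the gene models and applies the impact consensus
(2-of-3 predictors for substitutions, SIFT for InDels).
"""
from pathlib import Path

import pandas as pd

from surfscan.pipeline import stage_annotate

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main():
    stage_annotate(OUT)
    ann = pd.read_csv(OUT / "annotated.tsv", sep="\t")
    print(f"annotations written to {OUT/'annotated.tsv'}")
    print(ann.var_class.value_counts().to_string())
    impact = ann[ann.impact_consensus == "yes"]
    print(f"{len(impact)} of {len(ann)} annotated variants have consensus impact "
          f"({100 * len(impact) / len(ann):.0f}%)")
    truth = pd.read_csv(OUT / "truth_somatic.tsv", sep="\t")
    merged = ann.merge(truth.assign(
        variant_key=truth.contig + ":" + truth.position.astype(str) + ":"
        + truth.ref + ">" + truth.alt),
        on=["cell_line", "variant_key"], suffixes=("", "_truth"))
    agree = (merged.var_class == merged.consequence).mean()
    print(f"agreement with intended truth classes: {agree:.3f}")


if __name__ == "__main__":
    main()
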