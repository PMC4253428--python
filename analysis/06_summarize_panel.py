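"""Per-cell-line summary table and panel aggregate for the simulated panel."""
import json
from pathlib import Path

import pandas as pd

from surfscan.pipeline import stage_report

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main():
    stage_report(OUT)
    summary = pd.read_csv(OUT / "summary.tsv", sep="\t")
    agg = json.loads((OUT / "aggregate.json").read_text())
    cols = ["cell_line", "mutator", "somatic_snvs", "somatic_nonsyn_snvs",
            "somatic_indels", "frameshift_indels", "expressed_druggable_mutations",
            "mutated_epitopes", "expressed_mutated_epitopes"]
    print(summary[cols].to_string(index=False))
    print("\nper-line means:", agg["means"])
    print("unique variants across the panel:", agg["unique_totals"].get("variants"))


if __name__ == "__main__":
    main()
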