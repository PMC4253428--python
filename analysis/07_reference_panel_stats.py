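"""Aggregate statistics of the packaged 23-line reference-panel tables.

Recomputes the per-line averages and the self-consistent mutation rates
from the transcribed tables and writes them to results/.
"""
import json
from pathlib import Path

from surfscan.report import (PANEL_TARGET_BP, aggregate, load_panel_impact_table,
                             load_panel_snv_indel_table, pct)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    t2 = load_panel_snv_indel_table()
    t3 = load_panel_impact_table()
    rep2, rep3 = aggregate(t2), aggregate(t3)
    rates = (t2.set_index("cell_line")["somatic_snvs"] / PANEL_TARGET_BP)
    stats = {
        "n_lines": rep2.n_lines,
        "mean_somatic_nonsyn_snvs_per_line": rep2.means["somatic_nonsyn_snvs"],
        "mean_somatic_indels_per_line": rep2.means["somatic_indels"],
        "mean_expressed_druggable_mutations_per_line":
            rep3.means["expressed_druggable_mutations"],
        "pct_surfaceome_genes_mutated": pct(2061, 3594),
        "mutation_rate_caco2": rates["CACO2"],
        "mutation_rate_colo205": rates["COLO205"],
        "column_totals_snv_indel": rep2.totals,
        "column_totals_impact": rep3.totals,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "reference_panel_stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True) + "\n")
    print(json.dumps(stats, indent=2, sort_keys=True))
    print("\nPer-line averages across the 23-line panel: "
          f"{stats['mean_somatic_nonsyn_snvs_per_line']} non-synonymous SNVs, "
          f"{stats['mean_somatic_indels_per_line']} InDels, "
          f"{stats['mean_expressed_druggable_mutations_per_line']} expressed druggable mutations.")


if __name__ == "__main__":
    main()
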