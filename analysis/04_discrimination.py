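#!/usr/bin/env python
"""Cultivated-vs-wild discrimination over the BODYGUARD gene tables.

Applies the uniform-and-distinct rule to every coding SNP site of the three
packaged gene tables and writes the per-gene reports (table-style TSV plus
JSON) under results/discrimination/.  Counts are given at both granularities
— codon-change rows and individual substituted positions — because the two
differ for rows bundling several SNPs into one codon.
"""

import json
from pathlib import Path

from gojivar.discrimination import gene_discrimination_report
from gojivar.genomic_io import CohortMap, load_packaged_site_tables
from gojivar.report import render_gene_table

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "discrimination"

COHORTS = CohortMap(
    {
        **{f"Lb{i}": "cultivated" for i in range(1, 6)},
        **{f"Lb{i}w": "wild" for i in range(6, 9)},
    }
)


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for gene_id, matrix in load_packaged_site_tables().items():
        report = gene_discrimination_report(matrix, COHORTS)
        render_gene_table(matrix, report, OUTDIR / f"gene_{gene_id}.tsv")
        payload = {
            "gene_id": gene_id,
            "n_rows": report.n_rows,
            "n_discriminating_rows": report.n_discriminating_rows,
            "percent_discriminating": report.percent_discriminating,
            "n_positions": report.n_positions,
            "n_discriminating_positions": report.n_discriminating_positions,
            "non_discriminating_rows": report.non_discriminating_row_labels,
            "cross_tab": report.cross_tab,
        }
        (OUTDIR / f"gene_{gene_id}.json").write_text(json.dumps(payload, indent=2) + "\n")
        print(report.summary_line())
        non_disc = report.cross_tab["non_discriminating"]
        print(f"  non-discriminating rows: {non_disc['silent']} silent, "
              f"{non_disc['non_silent']} non-silent "
              f"({', '.join(report.non_discriminating_row_labels)})")
    print("reports written under", OUTDIR)


if __name__ == "__main__":
    main()
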