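#!/usr/bin/env python
"""Codon-change classification of the three BODYGUARD gene tables.

Classifies every coding SNP of the packaged chromosome 4, 8 and 9 gene
tables — synonymous/missense plus amino-acid polarity and charge changes —
and writes one consequence summary TSV under results/consequences/.
"""

from pathlib import Path

from gojivar.consequence import AMINO_ACID_PROPERTIES, classify_site_row
from gojivar.genomic_io import load_packaged_site_tables

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "consequences"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    out = OUTDIR / "consequences.tsv"
    with open(out, "w") as fh:
        fh.write("gene\tpositions\tcodons\tamino_acids\teffect\tpolarity_change\tcharge_change\n")
        for gene_id, matrix in load_packaged_site_tables().items():
            silent = missense = polarity = charge = 0
            for row in matrix.rows:
                change = classify_site_row(row, gene_id)
                silent += change.effect == "synonymous"
                missense += change.effect == "missense"
                polarity += bool(change.polarity_change)
                charge += bool(change.charge_change)
                fh.write(
                    f"{gene_id}\t{row.printed_positions}\t"
                    f"{'/'.join((row.ref_codon, *row.alt_codons))}\t"
                    f"{'/'.join((change.ref_aa, *change.alt_aas))}\t{change.effect}\t"
                    f"{change.polarity_change}\t{change.charge_change}\n"
                )
            print(f"{gene_id} (chr {matrix.chromosome}): {matrix.n_rows} codon-change rows, "
                  f"{silent} silent, {missense} missense, "
                  f"{polarity} polarity-changing, {charge} charge-changing")
    print("wrote", out)


if __name__ == "__main__":
    main()
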