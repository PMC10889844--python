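"""Coding-consequence engine.

Projects genomic SNPs into spliced CDS coordinates, groups SNPs that hit the
same codon, assembles reference/alternate codons, translates them under the
standard genetic code, and classifies the effect (synonymous / missense /
nonsense / stop-loss) together with amino-acid polarity and charge changes.

Amino acids are partitioned into four property classes — nonpolar, polar,
basic and acidic — the partition conventionally used when discussing whether
a substitution preserves side-chain chemistry.  A charge change is any move
between the basic and acidic classes or between a charged and an uncharged
class; a polarity change is a move between the polar and nonpolar classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genomic_io import CdsModel, SiteRow

__all__ = [
    "AMINO_ACID_PROPERTIES",
    "CodingPosition",
    "CodonChange",
    "NON_CODING",
    "project_to_cds",
    "group_codon_variants",
    "build_codon_change",
    "codon_change_from_codons",
    "classify_effect",
    "classify_site_row",
]

# Three-letter code -> property class.  Total, disjoint partition of the 20
# standard amino acids.
AMINO_ACID_PROPERTIES: dict[str, str] = {
    **{aa: "nonpolar" for aa in ("Gly", "Ala", "Val", "Leu", "Ile", "Pro", "Phe", "Met", "Trp")},
    **{aa: "polar" for aa in ("Ser", "Thr", "Cys", "Tyr", "Asn", "Gln")},
    **{aa: "basic" for aa in ("Lys", "Arg", "His")},
    **{aa: "acidic" for aa in ("Asp", "Glu")},
}

NON_CODING = "non_coding"


def translate_codon(codon: str) -> str:
    """Translate one codon to its three-letter amino acid ('Ter' for stop)."""
    if set(codon) - set("ACGT"):
        return "Xaa"
    aa1 = str(Seq(codon).translate())
    return "Ter" if aa1 == "*" else seq3(aa1)


@dataclass(frozen=True)
class CodingPosition:
    gene_id: str
    cds_position: int  # 1-based offset in the spliced coding sequence

    @property
    def codon_index(self) -> int:
        return (self.cds_position + 2) // 3

    @property
    def offset_in_codon(self) -> int:
        return (self.cds_position - 1) % 3 + 1


@dataclass
class CodonChange:
    gene_id: str
    codon_index: int
    ref_codon: str
    alt_codons: tuple[str, ...]
    cds_positions: tuple[int, ...]
    effect: str | None = None
    polarity_change: bool | None = None
    charge_change: bool | None = None

    @property
    def ref_aa(self) -> str:
        return translate_codon(self.ref_codon)

    @property
    def alt_aas(self) -> tuple[str, ...]:
        return tuple(translate_codon(c) for c in self.alt_codons)


def project_to_cds(
    chromosome: str, genomic_position: int, cds: CdsModel
) -> CodingPosition | str:
    """Project a genomic position into spliced CDS coordinates.

    Returns :data:`NON_CODING` when the position lies outside every CDS
    segment (intron/UTR/intergenic), so callers can tally such variants
    separately instead of treating them as failures.  On the minus strand the
    first coding base is the highest genomic coordinate; the caller is
    responsible for complementing alleles.
    """
    if chromosome != cds.chromosome:
        return NON_CODING
    offset = 0  # spliced bases before the containing segment, in genomic order
    hit = None
    for start, end in cds.segments:
        if start <= genomic_position <= end:
            hit = offset + (genomic_position - start)
            break
        offset += end - start + 1
    if hit is None:
        return NON_CODING
    if cds.strand == "-":
        hit = cds.cds_length - 1 - hit
    return CodingPosition(gene_id=cds.gene_id, cds_position=hit + 1)


def group_codon_variants(
    coding_positions: Iterable[CodingPosition],
) -> list[list[CodingPosition]]:
    """Group coding SNPs of one gene by the codon they fall in.

    Groups are returned ordered by codon index, positions sorted within each.
    """
    by_codon: dict[int, list[CodingPosition]] = {}
    seen: set[int] = set()
    for pos in coding_positions:
        if pos.cds_position in seen:
            raise ValueError(f"duplicate CDS position {pos.cds_position}")
        seen.add(pos.cds_position)
        by_codon.setdefault(pos.codon_index, []).append(pos)
    return [
        sorted(by_codon[idx], key=lambda p: p.cds_position)
        for idx in sorted(by_codon)
    ]


def build_codon_change(
    group: Sequence[tuple[CodingPosition, str]],
    cds_sequence: str,
    combine: bool = True,
) -> CodonChange:
    """Assemble the codon change for a group of same-codon SNPs.

    ``group`` pairs each coding position with its alternate base (already
    strand-oriented).  With ``combine=True`` all alternate alleles are
    substituted into the reference codon together (the haplotype carrying
    every change, as when two adjacent substitutions rewrite one codon);
    with ``combine=False`` each substitution yields its own alternate codon.
    """
    if not group:
        raise ValueError("empty codon group")
    positions = [pos for pos, _ in group]
    codon_index = positions[0].codon_index
    if any(p.codon_index != codon_index for p in positions):
        raise ValueError("codon group spans multiple codons")
    start = (codon_index - 1) * 3
    ref_codon = cds_sequence[start : start + 3]
    if len(ref_codon) != 3:
        raise ValueError(f"codon {codon_index} extends past the CDS end")
    alts: list[str] = []
    if combine:
        combined = list(ref_codon)
        for pos, alt_base in group:
            combined[pos.offset_in_codon - 1] = alt_base
        alts.append("".join(combined))
    else:
        for pos, alt_base in group:
            single = list(ref_codon)
            single[pos.offset_in_codon - 1] = alt_base
            alts.append("".join(single))
    for pos, alt_base in group:
        if alt_base == ref_codon[pos.offset_in_codon - 1]:
            raise ValueError(
                f"alternate base {alt_base} equals reference at CDS position {pos.cds_position}"
            )
    return CodonChange(
        gene_id=positions[0].gene_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codons=tuple(alts),
        cds_positions=tuple(p.cds_position for p in positions),
    )


def codon_change_from_codons(
    gene_id: str,
    codon_index: int,
    ref_codon: str,
    alt_codons: Sequence[str],
    cds_positions: Sequence[int] = (),
) -> CodonChange:
    """Build a CodonChange directly from known reference/alternate codons."""
    return CodonChange(
        gene_id=gene_id,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codons=tuple(alt_codons),
        cds_positions=tuple(cds_positions),
    )


def _property_class(aa: str) -> str | None:
    return AMINO_ACID_PROPERTIES.get(aa)


def classify_effect(change: CodonChange) -> CodonChange:
    """Fill effect and property-change flags on a codon change, in place.

    synonymous: every alternate amino acid equals the reference.
    nonsense: some alternate is a stop; stop_loss: the reference is a stop.
    Property flags are False for synonymous changes by construction.
    """
    ref_aa = change.ref_aa
    alt_aas = change.alt_aas
    if ref_aa == "Xaa" or "Xaa" in alt_aas:
        change.effect = "unknown"
        change.polarity_change = None
        change.charge_change = None
        return change
    if all(aa == ref_aa for aa in alt_aas):
        change.effect = "synonymous"
    elif ref_aa == "Ter":
        change.effect = "stop_loss"
    elif "Ter" in alt_aas:
        change.effect = "nonsense"
    else:
        change.effect = "missense"
    polarity = charge = False
    ref_class = _property_class(ref_aa)
    for alt_aa in alt_aas:
        alt_class = _property_class(alt_aa)
        if alt_aa == ref_aa or ref_class is None or alt_class is None:
            continue
        if {ref_class, alt_class} <= {"polar", "nonpolar"} and ref_class != alt_class:
            polarity = True
        charged = {"basic", "acidic"}
        if (ref_class in charged) != (alt_class in charged) or (
            ref_class in charged and alt_class in charged and ref_class != alt_class
        ):
            charge = True
    change.polarity_change = polarity
    change.charge_change = charge
    return change


def classify_site_row(row: SiteRow, gene_id: str) -> CodonChange:
    """Classify one coding-SNP table row via its printed codons."""
    change = codon_change_from_codons(
        gene_id=gene_id,
        codon_index=(row.positions[0] + 2) // 3,
        ref_codon=row.ref_codon,
        alt_codons=row.alt_codons,
        cds_positions=row.positions,
    )
    return classify_effect(change)
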