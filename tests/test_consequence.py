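"""CDS projection, codon assembly, translation and effect classification."""

import itertools

import pytest
from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from gojivar.consequence import (
    AMINO_ACID_PROPERTIES,
    NON_CODING,
    CodingPosition,
    build_codon_change,
    classify_effect,
    classify_site_row,
    codon_change_from_codons,
    group_codon_variants,
    project_to_cds,
    translate_codon,
)
from gojivar.genomic_io import CdsModel

# ---------------------------------------------------------------------------
# coordinate projection


def test_plus_strand_first_base():
    cds = CdsModel("g", "chr1", "+", ((101, 130),))
    projected = project_to_cds("chr1", 101, cds)
    assert projected.cds_position == 1
    assert projected.codon_index == 1
    assert projected.offset_in_codon == 1


def test_splice_arithmetic():
    cds = CdsModel("g", "chr1", "+", ((101, 106), (201, 203)))
    assert project_to_cds("chr1", 201, cds).cds_position == 7


def test_minus_strand_counts_from_highest_coordinate():
    cds = CdsModel("g", "chr1", "-", ((101, 130),))
    assert project_to_cds("chr1", 130, cds).cds_position == 1
    assert project_to_cds("chr1", 101, cds).cds_position == 30


def test_intron_is_non_coding_signal():
    cds = CdsModel("g", "chr1", "+", ((101, 106), (201, 203)))
    assert project_to_cds("chr1", 150, cds) == NON_CODING
    assert project_to_cds("chr2", 101, cds) == NON_CODING


def test_codon_index_and_offset_arithmetic():
    for cds_position in range(1, 31):
        p = CodingPosition("g", cds_position)
        assert p.codon_index == -(-cds_position // 3)
        assert (p.codon_index - 1) * 3 + p.offset_in_codon == cds_position


# ---------------------------------------------------------------------------
# codon grouping


def test_adjacent_positions_share_codon():
    groups = group_codon_variants([CodingPosition("g", 287), CodingPosition("g", 288)])
    assert len(groups) == 1
    assert groups[0][0].codon_index == 96


def test_distant_positions_split():
    groups = group_codon_variants([CodingPosition("g", 100), CodingPosition("g", 104)])
    assert len(groups) == 2


def test_duplicate_positions_rejected():
    with pytest.raises(ValueError):
        group_codon_variants([CodingPosition("g", 5), CodingPosition("g", 5)])


# ---------------------------------------------------------------------------
# codon assembly (the published worked examples)


def _cds_with_codon(codon_index, codon):
    return "ATG" * (codon_index - 1) + codon


def test_two_substitutions_one_codon_lys_to_arg():
    cds_seq = _cds_with_codon(96, "AAA")
    group = [(CodingPosition("g", 286), "C"), (CodingPosition("g", 287), "G")]
    change = build_codon_change(group, cds_seq)
    assert change.ref_codon == "AAA"
    assert change.alt_codons == ("CGA",)
    assert (change.ref_aa, change.alt_aas) == ("Lys", ("Arg",))


def test_three_substitutions_lys_to_asp():
    cds_seq = _cds_with_codon(131, "AAA")
    group = [(CodingPosition("g", 391), "G"), (CodingPosition("g", 392), "A"),
             (CodingPosition("g", 393), "C")]
    with pytest.raises(ValueError):
        # the middle substitution A->A is not a change
        build_codon_change(group, cds_seq)
    change = build_codon_change([group[0], group[2]], cds_seq)
    assert change.alt_codons == ("GAC",)
    assert (change.ref_aa, change.alt_aas) == ("Lys", ("Asp",))


def test_independent_alternates_enumerate_separately():
    cds_seq = _cds_with_codon(10, "TCT")
    separate = build_codon_change(
        [(CodingPosition("g", 28), "G"), (CodingPosition("g", 30), "A")],
        cds_seq, combine=False,
    )
    assert separate.alt_codons == ("GCT", "TCA")
    assert separate.alt_aas == ("Ala", "Ser")


def test_reference_mismatch_raises():
    cds_seq = _cds_with_codon(1, "AAA")
    with pytest.raises(ValueError):
        build_codon_change([(CodingPosition("g", 1), "A")], cds_seq)


# ---------------------------------------------------------------------------
# effect classification


@pytest.mark.parametrize(
    "ref, alt, effect, polarity, charge",
    [
        ("TTA", "CTA", "synonymous", False, False),   # Leu/Leu
        ("AAA", "GAA", "missense", False, True),      # Lys->Glu, basic->acidic
        ("TCT", "GCT", "missense", True, False),      # Ser->Ala, polar->nonpolar
        ("AAA", "AGA", "missense", False, False),     # Lys->Arg, basic->basic
        ("TAC", "TAA", "nonsense", False, False),     # Tyr->stop
        ("TAA", "CAA", "stop_loss", False, False),
    ],
)
def test_effect_and_property_flags(ref, alt, effect, polarity, charge):
    change = classify_effect(codon_change_from_codons("g", 1, ref, (alt,)))
    assert change.effect == effect
    assert change.polarity_change is polarity
    assert change.charge_change is charge


def test_property_table_partitions_twenty_amino_acids():
    assert len(AMINO_ACID_PROPERTIES) == 20
    assert set(AMINO_ACID_PROPERTIES.values()) == {"nonpolar", "polar", "basic", "acidic"}


def test_synonymous_flag_against_genetic_code_oracle():
    """All 64 codons x 9 single-base substitutions vs the code table itself."""
    table = CodonTable.unambiguous_dna_by_id[1]

    def oracle_aa(codon):
        return "Ter" if codon in table.stop_codons else seq3(table.forward_table[codon])

    checked = 0
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        for offset, new in itertools.product(range(3), "ACGT"):
            if codon[offset] == new:
                continue
            alt = codon[:offset] + new + codon[offset + 1 :]
            change = classify_effect(codon_change_from_codons("g", 1, codon, (alt,)))
            assert (change.effect == "synonymous") == (oracle_aa(codon) == oracle_aa(alt))
            if change.effect == "synonymous":
                assert oracle_aa(alt) != "Ter" or oracle_aa(codon) == "Ter"
            checked += 1
    assert checked == 576


def test_stop_gain_is_never_synonymous():
    change = classify_effect(codon_change_from_codons("g", 1, "TGG", ("TGA",)))
    assert change.effect == "nonsense"


def test_codon_with_n_is_unknown():
    change = classify_effect(codon_change_from_codons("g", 1, "ANA", ("AGA",)))
    assert change.effect == "unknown"


# ---------------------------------------------------------------------------
# packaged tables reproduce their printed codon/amino-acid columns


def test_fixture_rows_reproduce_printed_amino_acids(packaged_tables):
    for matrix in packaged_tables.values():
        for row in matrix.rows:
            change = classify_site_row(row, matrix.gene_id)
            printed = row.aa_printed.replace("(silent)", "").replace("(sIlent)", "").strip()
            derived = "/".join((change.ref_aa, *change.alt_aas))
            assert derived == printed, f"{matrix.gene_id} row {row.printed_positions}"


def test_fixture_silent_markers_match_classification(packaged_tables):
    for matrix in packaged_tables.values():
        for row in matrix.rows:
            change = classify_site_row(row, matrix.gene_id)
            printed_silent = "silent" in row.aa_printed.lower()
            assert (change.effect == "synonymous") == printed_silent
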