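"""IO layer: FASTA/GFF3/VCF/cohort parsing and the coding-SNP table loader."""

import pytest

from gojivar.genomic_io import (
    CdsModel,
    CohortMap,
    AnnotationError,
    FormatError,
    Genotype,
    SampleCall,
    VariantRecord,
    read_cds_annotation,
    read_cohorts,
    read_fasta,
    read_vcf,
    write_fasta,
    write_vcf,
)

# ---------------------------------------------------------------------------
# FASTA


def test_fasta_single_record(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1\nACGT\n")
    seqs = read_fasta(p)
    assert len(seqs) == 1
    assert seqs[0].name == "chr1"
    assert seqs[0].length == 4


def test_fasta_order_and_case_normalization(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">b\nacgt\n>a\nTTTT\n")
    seqs = read_fasta(p)
    assert [s.name for s in seqs] == ["b", "a"]
    assert seqs[0].sequence == "ACGT"


@pytest.mark.parametrize(
    "content, lineno",
    [(">chr1\nACXT\n", 2), (">\nACGT\n", 1), (">a\nACGT\n>a\nACGT\n", 3)],
)
def test_fasta_errors_name_line(tmp_path, content, lineno):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError, match=f":{lineno}:"):
        read_fasta(p)


def test_fasta_round_trip(tmp_path):
    from gojivar.genomic_io import GenomeSequence

    seqs = [GenomeSequence("c1", "ACGT" * 40), GenomeSequence("c2", "TTTAAAC")]
    p = tmp_path / "rt.fa"
    write_fasta(seqs, p)
    assert read_fasta(p) == seqs


# ---------------------------------------------------------------------------
# GFF3 CDS annotation


def _gff(tmp_path, body: str):
    p = tmp_path / "a.gff3"
    p.write_text("##gff-version 3\n" + body)
    return p


def test_single_exon_cds(tmp_path):
    p = _gff(tmp_path, "chr1\tx\tCDS\t101\t109\t.\t+\t0\tID=g1.c;Parent=g1\n")
    (model,) = read_cds_annotation(p)
    assert model.gene_id == "g1"
    assert model.cds_length == 9


def test_two_exon_cds_sorted(tmp_path):
    p = _gff(
        tmp_path,
        "chr1\tx\tCDS\t201\t203\t.\t+\t0\tParent=g1\n"
        "chr1\tx\tCDS\t101\t106\t.\t+\t0\tParent=g1\n",
    )
    (model,) = read_cds_annotation(p)
    assert model.segments == ((101, 106), (201, 203))
    assert model.cds_length == 9


def test_cds_length_not_multiple_of_three(tmp_path):
    p = _gff(tmp_path, "chr1\tx\tCDS\t101\t110\t.\t+\t0\tParent=g1\n")
    with pytest.raises(AnnotationError, match="g1"):
        read_cds_annotation(p)


def test_minus_strand_spliced_sequence():
    model = CdsModel("g", "c", "-", ((101, 106),))
    #  genomic 101..106 = ATGCAT -> minus-strand CDS is reverse complement
    chrom = "N" * 100 + "ATGCAT" + "N" * 10
    assert model.spliced_sequence(chrom) == "ATGCAT"[::-1].translate(str.maketrans("ACGT", "TGCA"))


# ---------------------------------------------------------------------------
# VCF


def _write_raw_vcf(tmp_path, body, fmt="GT:AD"):
    p = tmp_path / "v.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="m">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n" + body
    )
    return p


def test_vcf_het_alt_read_fraction(tmp_path):
    p = _write_raw_vcf(tmp_path, "chr1\t10\t.\tA\tG\t.\tPASS\tDP=50;MQ=40\tGT:AD\t0/1:31,69\n")
    (rec,) = read_vcf(p)
    call = rec.call_for("S1")
    assert call.genotype is Genotype.HET
    assert call.alt_read_fraction == pytest.approx(69.0)
    assert rec.supporting_reads == 50
    assert rec.rms_mapping_quality == pytest.approx(40.0)


@pytest.mark.parametrize(
    "gt, expected",
    [("0/0", Genotype.HOM_REF), ("1/1", Genotype.HOM_ALT), ("1/0", Genotype.HET),
     ("./.", Genotype.MISSING)],
)
def test_vcf_genotype_mapping(tmp_path, gt, expected):
    p = _write_raw_vcf(tmp_path, f"chr1\t10\t.\tA\tG\t.\tPASS\tDP=9\tGT\t{gt}\n")
    (rec,) = read_vcf(p)
    assert rec.call_for("S1").genotype is expected


def test_vcf_multiallelic_single_record(tmp_path):
    p = _write_raw_vcf(tmp_path, "chr1\t10\t.\tA\tT,TG\t.\tPASS\tDP=9\tGT\t1/2\n")
    (rec,) = read_vcf(p)
    assert rec.alt_alleles == ("T", "TG")


def test_vcf_round_trip(tmp_path):
    records = [
        VariantRecord(
            chromosome="chr1", position=5, ref_allele="A", alt_alleles=("G",),
            calls=(
                SampleCall("S1", Genotype.HET, alt_read_fraction=60.0,
                           allele_indices=(0, 1), allele_depths=(4, 6)),
                SampleCall("S2", Genotype.HOM_REF, allele_indices=(0, 0),
                           allele_depths=(10, 0)),
            ),
            supporting_reads=12, rms_mapping_quality=35.5,
        )
    ]
    p = tmp_path / "rt.vcf"
    write_vcf(records, ["S1", "S2"], p, contigs=[("chr1", 100)])
    assert list(read_vcf(p)) == records


# ---------------------------------------------------------------------------
# Cohorts


def test_cohorts_study_layout(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text(
        "sample\tcohort\n"
        + "".join(f"Lb{i}\tcultivated\n" for i in range(1, 6))
        + "".join(f"Lb{i}w\twild\n" for i in range(6, 9))
    )
    cohorts = read_cohorts(p)
    assert len(cohorts.assignments) == 8
    assert cohorts.cultivated == tuple(f"Lb{i}" for i in range(1, 6))
    assert cohorts.wild == ("Lb6w", "Lb7w", "Lb8w")


@pytest.mark.parametrize(
    "content",
    ["", "Lb1\tcultivated\nLb1\twild\n", "Lb1\tferal\n"],
    ids=["empty", "duplicate", "unknown-label"],
)
def test_cohorts_rejects_bad_tables(tmp_path, content):
    p = tmp_path / "c.tsv"
    p.write_text(content)
    with pytest.raises(FormatError):
        read_cohorts(p)


# ---------------------------------------------------------------------------
# Packaged coding-SNP tables


def test_table_row_counts(chr4_gene, chr8_gene, chr9_gene):
    assert chr4_gene.n_rows == 22
    assert chr8_gene.n_rows == 26
    assert chr9_gene.n_rows == 28


def test_table_position_counts(chr4_gene, chr8_gene, chr9_gene):
    # multi-SNP codons contribute one position per substituted base
    assert chr4_gene.n_positions == 22
    assert chr8_gene.n_positions == 28
    assert chr9_gene.n_positions == 30


def test_het_cell_token_parses(chr4_gene):
    row = chr4_gene.rows[0]
    assert row.positions == (517,)
    call = row.row_states["Lb1"]
    assert call.genotype is Genotype.HET
    assert call.alt_read_fraction == pytest.approx(69.0)


def test_reference_matching_token_is_hom_ref(chr4_gene):
    row = chr4_gene.rows[0]  # reference amino acid Asn; wild cells print Asn
    assert row.row_states["Lb6w"].genotype is Genotype.HOM_REF


def test_alternate_matching_token_is_hom_alt(chr4_gene):
    row = next(r for r in chr4_gene.rows if r.positions == (1312,))
    assert row.row_states["Lb1"].genotype is Genotype.HOM_ALT


def test_all_het_fractions_in_range(packaged_tables):
    for matrix in packaged_tables.values():
        for row in matrix.rows:
            for call in row.row_states.values():
                if call.alt_read_fraction is not None:
                    assert 0 <= call.alt_read_fraction <= 100


def test_corrections_are_applied(chr4_gene, chr9_gene):
    assert any("1761" in c for c in chr4_gene.corrections_applied)
    row = next(r for r in chr9_gene.rows if r.positions == (1285,))
    assert row.row_states["Lb7w"].alt_read_fraction == pytest.approx(75.0)


def test_split_token_gives_per_position_states(chr8_gene):
    # row 287-288: Lb7w prints "h14/Lys" = het at the first substituted
    # position, homozygous reference at the second
    row = next(r for r in chr8_gene.rows if r.printed_positions == "287-288")
    assert row.positions == (287, 288)
    assert row.position_states[287]["Lb7w"].genotype is Genotype.HET
    assert row.position_states[288]["Lb7w"].genotype is Genotype.HOM_REF
    assert row.row_states["Lb7w"].genotype is Genotype.HET


def test_multi_alt_codon_row(chr9_gene):
    row = next(r for r in chr9_gene.rows if r.printed_positions == "555-557")
    assert row.alt_codons == ("GCT", "TCA", "TCG")
    assert row.positions == (555, 557)
    # cultivated samples print Ala (GCT): alternate at 555, reference at 557
    assert row.position_states[555]["Lb1"].genotype is Genotype.HOM_ALT
    assert row.position_states[557]["Lb1"].genotype is Genotype.HOM_REF
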