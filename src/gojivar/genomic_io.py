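"""Input/output for every external format the pipeline touches.

Coordinates are 1-based inclusive throughout (VCF and GFF3 native); CDS
positions count spliced coding bases from the first base of the start codon.
The packaged coding-SNP tables for the three BODYGUARD genes are loaded into
:class:`SiteStateMatrix` form, preserving the published cells verbatim and
applying the auditable corrections shipped in ``fixtures/corrections.tsv``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "Genotype",
    "SampleCall",
    "GenomeSequence",
    "CdsModel",
    "VariantRecord",
    "CohortMap",
    "SiteRow",
    "SiteStateMatrix",
    "FormatError",
    "AnnotationError",
    "FixtureError",
    "read_fasta",
    "write_fasta",
    "read_cds_annotation",
    "write_cds_annotation",
    "read_vcf",
    "write_vcf",
    "read_cohorts",
    "write_cohorts",
    "read_site_table",
    "load_packaged_site_tables",
    "packaged_fixture_paths",
]

VALID_BASES = set("ACGTN")
CODON_RE = re.compile(r"^([A-Z][a-z]{2})\s*(?:\(\s*([ACGT]{3})\s*\))?$")
HET_RE = re.compile(r"^h(\d{1,3})$")


class FormatError(ValueError):
    """A malformed external file (FASTA/VCF/TSV)."""


class AnnotationError(ValueError):
    """A structurally invalid gene annotation."""


class FixtureError(ValueError):
    """An unparseable cell in a packaged coding-SNP table."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HOM_ALT = "hom_alt"
    HET = "het"
    MISSING = "missing"


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype at one variant site.

    ``alt_read_fraction`` is the percentage of reads supporting the alternate
    allele and is meaningful only for heterozygous calls; ``None`` means the
    evidence was not recorded (e.g. a VCF without an AD field).
    """

    sample_id: str
    genotype: Genotype
    alt_read_fraction: float | None = None
    allele_indices: tuple[int, ...] | None = None
    allele_depths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.alt_read_fraction is not None and not 0 <= self.alt_read_fraction <= 100:
            raise ValueError(
                f"alt_read_fraction must lie in [0, 100], got {self.alt_read_fraction}"
            )


@dataclass(frozen=True)
class GenomeSequence:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsModel:
    """A gene's coding segments on one chromosome.

    Segments are 1-based inclusive genomic intervals, stored sorted by
    genomic position regardless of strand; the spliced CDS runs 5'->3' of the
    mRNA, i.e. from the highest genomic coordinate downwards on the minus
    strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        segs = sorted(self.segments)
        object.__setattr__(self, "segments", tuple(segs))
        last_end = 0
        for start, end in segs:
            if start > end:
                raise AnnotationError(f"gene {self.gene_id}: segment {start}-{end} inverted")
            if start <= last_end:
                raise AnnotationError(f"gene {self.gene_id}: overlapping CDS segments")
            last_end = end
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def spliced_sequence(self, chromosome_sequence: str) -> str:
        """Extract the strand-oriented coding sequence from genomic sequence."""
        parts = [chromosome_sequence[s - 1 : e] for s, e in self.segments]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: tuple[SampleCall, ...]
    supporting_reads: int | None = None
    rms_mapping_quality: float | None = None

    def __post_init__(self) -> None:
        if not self.ref_allele or any(not a for a in self.alt_alleles):
            raise ValueError("ref and alt alleles must be non-empty")
        if not self.calls:
            raise ValueError("a variant record needs at least one sample call")

    def call_for(self, sample_id: str) -> SampleCall:
        for call in self.calls:
            if call.sample_id == sample_id:
                return call
        raise KeyError(sample_id)


@dataclass(frozen=True)
class CohortMap:
    """sample_id -> cohort, with cohorts restricted to cultivated/wild."""

    assignments: Mapping[str, str]

    VALID = frozenset({"cultivated", "wild"})

    def __post_init__(self) -> None:
        bad = {c for c in self.assignments.values() if c not in self.VALID}
        if bad:
            raise FormatError(f"unknown cohort label(s): {sorted(bad)}")

    def samples(self, cohort: str) -> tuple[str, ...]:
        return tuple(s for s, c in self.assignments.items() if c == cohort)

    @property
    def cultivated(self) -> tuple[str, ...]:
        return self.samples("cultivated")

    @property
    def wild(self) -> tuple[str, ...]:
        return self.samples("wild")

    def swapped(self) -> "CohortMap":
        flip = {"cultivated": "wild", "wild": "cultivated"}
        return CohortMap({s: flip[c] for s, c in self.assignments.items()})


@dataclass
class SiteRow:
    """One row of a coding-SNP table: a codon-change event.

    A row may span several substituted CDS positions when multiple SNPs hit
    the same printed codon; ``positions`` lists the individual substituted
    positions, ``row_states`` gives one collapsed state per sample (het wins
    over hom-alt over hom-ref) and ``position_states`` the per-position state.
    """

    printed_positions: str
    positions: tuple[int, ...]
    ref_codon: str
    alt_codons: tuple[str, ...]
    changed_offsets: tuple[int, ...]
    aa_printed: str
    ref_token: str
    cell_tokens: dict[str, str]
    row_states: dict[str, SampleCall]
    position_states: dict[int, dict[str, SampleCall]]
    notes: list[str] = field(default_factory=list)


@dataclass
class SiteStateMatrix:
    gene_id: str
    chromosome: str
    samples: tuple[str, ...]
    rows: list[SiteRow]
    corrections_applied: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_positions(self) -> int:
        return sum(len(r.positions) for r in self.rows)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA, upper-casing sequence and validating bases.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or characters outside {A,C,G,T,N}.
    """
    path = Path(path)
    names: list[str] = []
    with open(path) as fh:
        in_record = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path.name}:{lineno}: empty FASTA header")
                if name in names:
                    raise FormatError(f"{path.name}:{lineno}: duplicate record name {name!r}")
                names.append(name)
                in_record = True
            else:
                if not in_record:
                    raise FormatError(f"{path.name}:{lineno}: sequence before first header")
                bad = set(line.upper()) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path.name}:{lineno}: illegal sequence character(s) {sorted(bad)}"
                    )
    records = [
        GenomeSequence(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.sequence), width):
                fh.write(seq.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS subset)

_ATTR_RE = re.compile(r"(\w+)=([^;\s]+)")


def _gene_id_from_attributes(attrs: str) -> str | None:
    fields = dict(_ATTR_RE.findall(attrs))
    for key in ("gene_id", "gene", "Parent", "ID"):
        if key in fields:
            return fields[key]
    return None


def read_cds_annotation(path: str | Path) -> list[CdsModel]:
    """Read CDS features from a GFF3 subset, grouped per gene.

    Only ``CDS`` features are consumed; the gene identifier is taken from the
    first of the ``gene_id``/``gene``/``Parent``/``ID`` attributes present.
    """
    path = Path(path)
    grouped: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path.name}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            gene_id = _gene_id_from_attributes(attrs)
            if gene_id is None:
                raise FormatError(f"{path.name}:{lineno}: CDS feature without a gene identifier")
            entry = grouped.setdefault(gene_id, {"chromosome": chrom, "strand": strand, "segments": []})
            if entry["chromosome"] != chrom:
                raise AnnotationError(f"gene {gene_id}: CDS segments on multiple chromosomes")
            if entry["strand"] != strand:
                raise AnnotationError(f"gene {gene_id}: CDS segments on conflicting strands")
            entry["segments"].append((int(start), int(end)))
            if gene_id not in order:
                order.append(gene_id)
    return [
        CdsModel(
            gene_id=g,
            chromosome=grouped[g]["chromosome"],
            strand=grouped[g]["strand"],
            segments=tuple(sorted(grouped[g]["segments"])),
        )
        for g in order
    ]


def write_cds_annotation(models: Iterable[CdsModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_start = min(s for s, _ in m.segments)
            gene_end = max(e for _, e in m.segments)
            fh.write(
                f"{m.chromosome}\tgojivar\tgene\t{gene_start}\t{gene_end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};gene_id={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.segments, start=1):
                fh.write(
                    f"{m.chromosome}\tgojivar\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id};gene_id={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF

def _genotype_from_indices(indices: tuple[int | None, ...]) -> Genotype:
    if any(i is None for i in indices):
        return Genotype.MISSING
    nonref = [i for i in indices if i != 0]
    if not nonref:
        return Genotype.HOM_REF
    if len(nonref) == len(indices):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF v4.x file.

    Genotype comes from GT (mandatory), record-level read support from INFO
    DP, RMS mapping quality from INFO MQ, and the heterozygous alternate-read
    percentage from the AD FORMAT field when present.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path.name}: VCF lacks the mandatory GT FORMAT field")
        samples = list(vcf.header.samples)
        for rec in vcf:
            calls = []
            for sample_id in samples:
                data = rec.samples[sample_id]
                gt = data.get("GT")
                if gt is None:
                    raise FormatError(
                        f"{path.name}: record {rec.chrom}:{rec.pos} sample {sample_id} has no GT"
                    )
                genotype = _genotype_from_indices(tuple(gt))
                ad = data.get("AD")
                allele_depths = tuple(int(x) for x in ad) if ad is not None and None not in ad else None
                frac = None
                if genotype is Genotype.HET and allele_depths is not None:
                    alt_idx = next(i for i in gt if i not in (0, None))
                    total = sum(allele_depths)
                    if total > 0 and alt_idx < len(allele_depths):
                        frac = 100.0 * allele_depths[alt_idx] / total
                calls.append(
                    SampleCall(
                        sample_id=sample_id,
                        genotype=genotype,
                        alt_read_fraction=frac,
                        allele_indices=tuple(gt) if None not in gt else None,
                        allele_depths=allele_depths,
                    )
                )
            mq = rec.info.get("MQ")
            dp = rec.info.get("DP")
            yield VariantRecord(
                chromosome=rec.chrom,
                position=rec.pos,
                ref_allele=str(rec.ref).upper(),
                alt_alleles=tuple(str(a).upper() for a in (rec.alts or ())),
                calls=tuple(calls),
                supporting_reads=int(dp) if dp is not None else None,
                rms_mapping_quality=float(mq) if mq is not None else None,
            )


_GT_FOR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write a VCF v4.2 subset (INFO DP, MQ; FORMAT GT, AD) as plain text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gojivar\n")
        for name, length in contigs or ():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            info_parts = []
            if rec.supporting_reads is not None:
                info_parts.append(f"DP={rec.supporting_reads}")
            if rec.rms_mapping_quality is not None:
                info_parts.append(f"MQ={rec.rms_mapping_quality:g}")
            info = ";".join(info_parts) or "."
            by_sample = {c.sample_id: c for c in rec.calls}
            has_ad = any(c.allele_depths is not None for c in rec.calls)
            fmt = "GT:AD" if has_ad else "GT"
            cells = []
            for s in samples:
                call = by_sample.get(s)
                if call is None:
                    cells.append("./." + (":." if has_ad else ""))
                    continue
                gt = (
                    "/".join(str(i) for i in call.allele_indices)
                    if call.allele_indices is not None
                    else _GT_FOR[call.genotype]
                )
                if has_ad:
                    ad = ",".join(str(d) for d in call.allele_depths) if call.allele_depths else "."
                    cells.append(f"{gt}:{ad}")
                else:
                    cells.append(gt)
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref_allele}\t"
                f"{','.join(rec.alt_alleles)}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Cohort table

def read_cohorts(path: str | Path) -> CohortMap:
    """Read a `sample<TAB>cohort` TSV; a `sample/cohort` header row is optional."""
    path = Path(path)
    assignments: dict[str, str] = {}
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise FormatError(f"{path.name}: empty cohort table")
    if rows[0][0].lower() in {"sample", "sample_id"}:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path.name}: cohort table has a header but no samples")
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path.name}: cohort row {row!r} lacks a cohort column")
        sample, cohort = row[0].strip(), row[1].strip().lower()
        if sample in assignments:
            raise FormatError(f"{path.name}: duplicate sample_id {sample!r}")
        assignments[sample] = cohort
    return CohortMap(assignments)


def write_cohorts(cohorts: CohortMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcohort\n")
        for sample, cohort in cohorts.assignments.items():
            fh.write(f"{sample}\t{cohort}\n")


# ---------------------------------------------------------------------------
# Packaged coding-SNP tables

def _codon_aa3(codon: str) -> str:
    aa1 = str(Seq(codon).translate())
    return "Ter" if aa1 == "*" else seq3(aa1)


def _load_corrections(path: str | Path) -> list[dict[str, str]]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            out.append(row)
    return out


def packaged_fixture_paths() -> dict[str, Path]:
    """Paths of the three packaged gene tables plus the corrections file."""
    base = resources.files("gojivar") / "fixtures"
    return {
        "chr4": Path(str(base / "bdg3_chr4_LOC132634709.tsv")),
        "chr8": Path(str(base / "bdg4_chr8_LOC132607278.tsv")),
        "chr9": Path(str(base / "bdg3_chr9_LOC132609965.tsv")),
        "corrections": Path(str(base / "corrections.tsv")),
    }


def _parse_positions(printed: str, changed_offsets: tuple[int, ...], where: str) -> tuple[int, ...]:
    """Map a printed position (or range) to individual substituted positions.

    A printed range ``a-b`` anchors the codon's first base at ``a``; the
    substituted positions are then ``a + offset - 1`` for each codon offset at
    which some alternate codon differs from the reference.  Single printed
    positions require a single changed offset.
    """
    printed = printed.strip()
    if "-" in printed:
        a, _b = (int(x) for x in printed.split("-", 1))
        return tuple(a + off - 1 for off in changed_offsets)
    if len(changed_offsets) != 1:
        raise FixtureError(
            f"{where}: single printed position but {len(changed_offsets)} substituted offsets"
        )
    return (int(printed),)


def _resolve_codon_token(
    token: str,
    ref_codon: str,
    alt_codons: tuple[str, ...],
    where: str,
) -> str:
    """Resolve an amino-acid/codon cell token to the codon it denotes.

    When only the amino acid is printed and it equals the reference amino
    acid the reference codon is assumed (hom-ref tie-break for silent rows).
    """
    m = CODON_RE.match(token)
    if not m:
        raise FixtureError(f"{where}: unparseable cell token {token!r}")
    aa, codon = m.group(1), m.group(2)
    if codon is not None:
        if codon != ref_codon and codon not in alt_codons:
            raise FixtureError(f"{where}: codon {codon} is neither reference nor alternate")
        return codon
    if aa == _codon_aa3(ref_codon):
        return ref_codon
    matches = [alt for alt in alt_codons if _codon_aa3(alt) == aa]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise FixtureError(f"{where}: amino acid {aa} matches neither reference nor alternate")
    raise FixtureError(f"{where}: amino acid {aa} is ambiguous among alternate codons")


def _states_for_token(
    token: str,
    sample_id: str,
    row_positions: tuple[int, ...],
    changed_offsets: tuple[int, ...],
    ref_codon: str,
    alt_codons: tuple[str, ...],
    where: str,
) -> dict[int, SampleCall]:
    subtokens = token.split("/")
    if len(subtokens) == 1:
        subtokens = subtokens * len(row_positions)
    if len(subtokens) != len(row_positions):
        raise FixtureError(
            f"{where}: token {token!r} has {len(token.split('/'))} parts for "
            f"{len(row_positions)} substituted positions"
        )
    out: dict[int, SampleCall] = {}
    for sub, pos, offset in zip(subtokens, row_positions, changed_offsets):
        sub = sub.strip()
        het = HET_RE.match(sub)
        if het:
            frac = int(het.group(1))
            if frac > 100:
                raise FixtureError(f"{where}: heterozygous percentage {frac} exceeds 100")
            out[pos] = SampleCall(sample_id, Genotype.HET, alt_read_fraction=float(frac))
            continue
        codon = _resolve_codon_token(sub, ref_codon, alt_codons, where)
        base = codon[offset - 1]
        if base == ref_codon[offset - 1]:
            out[pos] = SampleCall(sample_id, Genotype.HOM_REF)
        else:
            alt_bases = {alt[offset - 1] for alt in alt_codons if alt[offset - 1] != ref_codon[offset - 1]}
            if base not in alt_bases:
                raise FixtureError(f"{where}: base {base} at offset {offset} matches no allele")
            out[pos] = SampleCall(sample_id, Genotype.HOM_ALT)
    return out


def _collapse_row_state(sample_id: str, states: Iterable[SampleCall]) -> SampleCall:
    states = list(states)
    hets = [s for s in states if s.genotype is Genotype.HET]
    if hets:
        return SampleCall(sample_id, Genotype.HET, alt_read_fraction=hets[0].alt_read_fraction)
    if any(s.genotype is Genotype.HOM_ALT for s in states):
        return SampleCall(sample_id, Genotype.HOM_ALT)
    return SampleCall(sample_id, Genotype.HOM_REF)


def read_site_table(
    path: str | Path,
    corrections_path: str | Path | None = None,
) -> SiteStateMatrix:
    """Load one packaged coding-SNP table into a :class:`SiteStateMatrix`.

    Cell token grammar: ``hNN`` is a heterozygous call with NN% alternate
    reads; any other token names an amino acid, optionally with its codon in
    parentheses, and is compared against the reference and alternate codons.
    Multi-position rows accept ``/``-separated per-position sub-tokens.
    """
    path = Path(path)
    if corrections_path is None:
        default = packaged_fixture_paths()["corrections"]
        corrections_path = default if default.exists() else None
    corrections = _load_corrections(corrections_path) if corrections_path else []

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            meta.update(_ATTR_RE.findall(line))
            header_idx = i + 1
        else:
            break
    gene_id = meta.get("gene_id", path.stem)
    chromosome = meta.get("chromosome", "?")
    table_label = meta.get("table", path.stem)

    columns = lines[header_idx].split("\t")
    samples = tuple(columns[5:])
    applied: list[str] = []
    relevant = [c for c in corrections if c["table"] == table_label]

    rows: list[SiteRow] = []
    for raw in lines[header_idx + 1 :]:
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(columns):
            raise FixtureError(f"{path.name}: row {cells[0]!r} has {len(cells)} columns")
        record = dict(zip(columns, cells))
        printed_positions = record["positions"]
        for corr in relevant:
            if corr["positions"] == printed_positions:
                col = corr["column"]
                if record.get(col) == corr["printed"]:
                    record[col] = corr["corrected"]
                    applied.append(
                        f"{table_label} {printed_positions} {col}: "
                        f"{corr['printed']!r} -> {corr['corrected']!r} ({corr['note']})"
                    )
        ref_codon = record["ref_codon"]
        alt_codons = tuple(record["alt_codons"].split(","))
        changed_offsets = tuple(
            sorted(
                {
                    off
                    for alt in alt_codons
                    for off in (1, 2, 3)
                    if alt[off - 1] != ref_codon[off - 1]
                }
            )
        )
        where = f"{path.name} row {printed_positions}"
        positions = _parse_positions(printed_positions, changed_offsets, where)
        notes: list[str] = []
        for pos, off in zip(positions, changed_offsets if len(positions) > 1 else (None,)):
            grid_offset = (pos - 1) % 3 + 1
            expected = off if off is not None else changed_offsets[0]
            if grid_offset != expected:
                notes.append(
                    f"printed position {pos} sits at codon offset {grid_offset} by "
                    f"arithmetic but the codon change implies offset {expected}"
                )
        position_states: dict[int, dict[str, SampleCall]] = {p: {} for p in positions}
        row_states: dict[str, SampleCall] = {}
        cell_tokens: dict[str, str] = {}
        for sample in samples:
            token = record[sample].strip()
            cell_tokens[sample] = token
            per_pos = _states_for_token(
                token, sample, positions, changed_offsets, ref_codon, alt_codons,
                f"{where} sample {sample}",
            )
            for pos, call in per_pos.items():
                position_states[pos][sample] = call
            row_states[sample] = _collapse_row_state(sample, per_pos.values())
        rows.append(
            SiteRow(
                printed_positions=printed_positions,
                positions=positions,
                ref_codon=ref_codon,
                alt_codons=alt_codons,
                changed_offsets=changed_offsets,
                aa_printed=record["aa_printed"],
                ref_token=record["ref_token"],
                cell_tokens=cell_tokens,
                row_states=row_states,
                position_states=position_states,
                notes=notes,
            )
        )
    prev = 0
    for row in rows:
        if row.positions[0] <= prev:
            raise FixtureError(f"{path.name}: positions not strictly increasing at {row.positions}")
        prev = row.positions[-1]
    return SiteStateMatrix(
        gene_id=gene_id,
        chromosome=chromosome,
        samples=samples,
        rows=rows,
        corrections_applied=applied,
    )


def load_packaged_site_tables() -> dict[str, SiteStateMatrix]:
    """Load the three packaged BODYGUARD gene tables, keyed by gene id."""
    paths = packaged_fixture_paths()
    out = {}
    for label in ("chr4", "chr8", "chr9"):
        matrix = read_site_table(paths[label], paths["corrections"])
        out[matrix.gene_id] = matrix
    return out
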