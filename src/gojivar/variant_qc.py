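"""Post-call variant classification and filtering.

Raw records are split per alternate allele, multi-nucleotide substitutions
are decomposed into per-base SNPs, and each biallelic record is classified as
SNP / insertion / deletion or rejected.  The filters mirror mpileup-style
post-call criteria: a variant is kept only when its record-level read support
is strictly greater than ``min_supporting_reads_exclusive`` and its RMS
mapping quality strictly greater than ``min_rms_mapping_quality_exclusive``;
InDels longer than ``max_indel_length`` are rejected outright.  The same
thresholds apply to SNPs and InDels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Iterator

from .genomic_io import Genotype, SampleCall, VariantRecord

__all__ = [
    "FilterThresholds",
    "VariantKind",
    "ClassifiedVariant",
    "Rejection",
    "split_multiallelic",
    "decompose_mnp",
    "normalize_records",
    "classify_variant",
    "apply_snp_filters",
    "filter_variants",
]

_SYMBOLIC = set("<>[].*")


@dataclass(frozen=True)
class FilterThresholds:
    min_supporting_reads_exclusive: int = 4
    min_rms_mapping_quality_exclusive: float = 20.0
    max_indel_length: int = 50

    def __post_init__(self) -> None:
        if (
            self.min_supporting_reads_exclusive <= 0
            or self.min_rms_mapping_quality_exclusive <= 0
            or self.max_indel_length <= 0
        ):
            raise ValueError("all filter thresholds must be positive")


class VariantKind(str, Enum):
    SNP = "snp"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class ClassifiedVariant:
    record: VariantRecord
    kind: VariantKind
    indel_length: int = 0

    @property
    def ref(self) -> str:
        return self.record.ref_allele

    @property
    def alt(self) -> str:
        return self.record.alt_alleles[0]


@dataclass(frozen=True)
class Rejection:
    record: VariantRecord
    reason: str

    @property
    def key(self) -> str:
        return f"{self.record.chromosome}:{self.record.position}"


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a record into one biallelic record per alternate allele.

    Per-sample genotypes are recoded against the retained allele; calls that
    carry a different alternate allele become missing on that split record.
    """
    if len(record.alt_alleles) <= 1:
        return [record]
    out = []
    for alt_index, alt in enumerate(record.alt_alleles, start=1):
        calls = []
        for call in record.calls:
            if call.allele_indices is None:
                new = replace(call, genotype=Genotype.MISSING, allele_indices=None,
                              alt_read_fraction=None, allele_depths=None)
            else:
                carried = set(call.allele_indices) - {0}
                if carried - {alt_index}:
                    new = replace(call, genotype=Genotype.MISSING, allele_indices=None,
                                  alt_read_fraction=None, allele_depths=None)
                else:
                    indices = tuple(1 if i == alt_index else 0 for i in call.allele_indices)
                    new = replace(call, genotype=_geno(indices), allele_indices=indices)
            calls.append(new)
        out.append(replace(record, alt_alleles=(alt,), calls=tuple(calls)))
    return out


def _geno(indices: tuple[int, ...]) -> Genotype:
    nonref = [i for i in indices if i != 0]
    if not nonref:
        return Genotype.HOM_REF
    if len(nonref) == len(indices):
        return Genotype.HOM_ALT
    return Genotype.HET


def decompose_mnp(record: VariantRecord) -> list[VariantRecord]:
    """Decompose an equal-length multi-base substitution into per-base SNPs.

    Bases identical between ref and alt emit nothing, so AAA>GAC yields SNPs
    at offsets 0 and 2 only.  Genotype calls carry over unchanged to every
    emitted SNP (the substituted bases travel on the same haplotype).
    """
    ref, alt = record.ref_allele, record.alt_alleles[0]
    if len(ref) != len(alt) or len(ref) == 1:
        return [record]
    out = []
    for offset, (r, a) in enumerate(zip(ref, alt)):
        if r != a:
            out.append(
                replace(record, position=record.position + offset,
                        ref_allele=r, alt_alleles=(a,))
            )
    return out


def normalize_records(records: Iterable[VariantRecord]) -> Iterator[VariantRecord]:
    """Split multiallelic records, then decompose MNP substitutions."""
    for record in records:
        for biallelic in split_multiallelic(record):
            yield from decompose_mnp(biallelic)


def classify_variant(
    record: VariantRecord, thresholds: FilterThresholds | None = None
) -> ClassifiedVariant | Rejection:
    """Classify a biallelic record as SNP/insertion/deletion or reject it."""
    thresholds = thresholds or FilterThresholds()
    if len(record.alt_alleles) != 1:
        raise ValueError("classify_variant requires a biallelic record")
    ref, alt = record.ref_allele, record.alt_alleles[0]
    if _SYMBOLIC & (set(ref) | set(alt)):
        return Rejection(record, "unsupported allele")
    if len(ref) == 1 and len(alt) == 1:
        return ClassifiedVariant(record, VariantKind.SNP, 0)
    length = abs(len(alt) - len(ref))
    if length == 0:
        return Rejection(record, "multi-nucleotide substitution not decomposed")
    if length > thresholds.max_indel_length:
        return Rejection(record, f"indel length {length} > {thresholds.max_indel_length}")
    kind = VariantKind.INSERTION if len(alt) > len(ref) else VariantKind.DELETION
    return ClassifiedVariant(record, kind, length)


def apply_snp_filters(
    variant: ClassifiedVariant, thresholds: FilterThresholds | None = None
) -> Rejection | None:
    """Return a Rejection if the variant fails the evidence filters, else None.

    Both comparisons are strict: support must exceed the read threshold and
    mapping quality must exceed the quality threshold.
    """
    thresholds = thresholds or FilterThresholds()
    rec = variant.record
    if rec.supporting_reads is None or rec.rms_mapping_quality is None:
        return Rejection(rec, "missing evidence")
    if rec.supporting_reads <= thresholds.min_supporting_reads_exclusive:
        return Rejection(rec, f"supporting reads {rec.supporting_reads} not > "
                              f"{thresholds.min_supporting_reads_exclusive}")
    if rec.rms_mapping_quality <= thresholds.min_rms_mapping_quality_exclusive:
        return Rejection(rec, f"mapping quality {rec.rms_mapping_quality:g} not > "
                              f"{thresholds.min_rms_mapping_quality_exclusive:g}")
    return None


def filter_variants(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[ClassifiedVariant], list[Rejection]]:
    """Normalize, classify and filter a record stream.

    Every normalized record lands in exactly one of the two returned lists,
    so kept + dropped counts always sum to the normalized input count.
    """
    thresholds = thresholds or FilterThresholds()
    kept: list[ClassifiedVariant] = []
    dropped: list[Rejection] = []
    for record in normalize_records(records):
        classified = classify_variant(record, thresholds)
        if isinstance(classified, Rejection):
            dropped.append(classified)
            continue
        rejection = apply_snp_filters(classified, thresholds)
        if rejection is not None:
            dropped.append(rejection)
        else:
            kept.append(classified)
    return kept, dropped


def write_filter_report(dropped: Iterable[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("record\treason\n")
        for rej in dropped:
            fh.write(f"{rej.key}\t{rej.reason}\n")
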