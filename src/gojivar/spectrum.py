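"""Genome-wide variant summary statistics.

Implements the strand-collapsed six-class SNP mutation spectrum, the
transition/transversion ratio, per-mille heterozygosity rates, InDel length
distributions and windowed variant-density tracks.  A substitution and its
reverse complement are one event on the double helix, so T>C and A>G fall in
the same class; the six labels pair the pyrimidine-strand change with its
purine-strand mirror (e.g. ``T:A>C:G``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genomic_io import GenomeSequence, Genotype
from .variant_qc import ClassifiedVariant, VariantKind

__all__ = [
    "MUTATION_CLASSES",
    "TRANSITION_CLASSES",
    "COMPLEMENT",
    "collapse_mutation_class",
    "SpectrumSummary",
    "IndelSummary",
    "DensityTrack",
    "spectrum_summary",
    "indel_summary",
    "window_density",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# The six strand-collapsed classes; every ordered (ref, alt) base pair maps
# to exactly one of these labels.
MUTATION_CLASSES = (
    "T:A>C:G",
    "T:A>G:C",
    "C:G>T:A",
    "C:G>A:T",
    "T:A>A:T",
    "C:G>G:C",
)

# Purine<->purine / pyrimidine<->pyrimidine changes.
TRANSITION_CLASSES = frozenset({"T:A>C:G", "C:G>T:A"})

_CLASS_BY_SUBSTITUTION: dict[tuple[str, str], str] = {}
for _pyrimidine, _alt in (("T", "C"), ("T", "G"), ("T", "A"), ("C", "T"), ("C", "A"), ("C", "G")):
    _label = f"{_pyrimidine}:{COMPLEMENT[_pyrimidine]}>{_alt}:{COMPLEMENT[_alt]}"
    _CLASS_BY_SUBSTITUTION[(_pyrimidine, _alt)] = _label
    _CLASS_BY_SUBSTITUTION[(COMPLEMENT[_pyrimidine], COMPLEMENT[_alt])] = _label


def collapse_mutation_class(ref_base: str, alt_base: str) -> str:
    """Map a single-base substitution to its strand-collapsed class label."""
    key = (ref_base.upper(), alt_base.upper())
    if key[0] == key[1]:
        raise ValueError(f"not a substitution: {ref_base}>{alt_base}")
    try:
        return _CLASS_BY_SUBSTITUTION[key]
    except KeyError:
        raise ValueError(f"bases must be A/C/G/T, got {ref_base}>{alt_base}") from None


@dataclass
class SpectrumSummary:
    """Per-sample six-class spectrum with ts/tv and heterozygosity."""

    sample_id: str
    class_counts: dict[str, int]
    het_snp_count: int
    callable_bases: int

    @property
    def snp_total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def transitions(self) -> int:
        return sum(self.class_counts[c] for c in TRANSITION_CLASSES)

    @property
    def transversions(self) -> int:
        return self.snp_total - self.transitions

    @property
    def ts_tv_ratio(self) -> float | None:
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions

    @property
    def het_rate_permille(self) -> float:
        return 1000.0 * self.het_snp_count / self.callable_bases


@dataclass
class IndelSummary:
    sample_id: str
    insertion_count: int
    deletion_count: int
    length_histogram: dict[int, int]
    het_indel_count: int
    callable_bases: int

    @property
    def total(self) -> int:
        return self.insertion_count + self.deletion_count

    @property
    def length_percentages(self) -> dict[int, float]:
        total = self.total
        if total == 0:
            return {}
        return {length: 100.0 * n / total for length, n in sorted(self.length_histogram.items())}

    @property
    def het_indel_rate_permille(self) -> float:
        return 1000.0 * self.het_indel_count / self.callable_bases


@dataclass
class DensityTrack:
    chromosome: str
    chromosome_length: int
    window_size: int
    snp_counts: np.ndarray
    indel_counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.snp_counts)

    @property
    def snp_total(self) -> int:
        return int(self.snp_counts.sum())

    @property
    def indel_total(self) -> int:
        return int(self.indel_counts.sum())

    @property
    def snp_indel_ratio(self) -> float | None:
        if self.indel_total == 0:
            return None
        return self.snp_total / self.indel_total


def _sample_genotype(variant: ClassifiedVariant, sample_id: str) -> Genotype:
    try:
        return variant.record.call_for(sample_id).genotype
    except KeyError:
        return Genotype.MISSING


def spectrum_summary(
    snps: Iterable[ClassifiedVariant],
    sample_id: str,
    callable_bases: int,
) -> SpectrumSummary:
    """Summarize kept SNPs for one sample.

    Only sites at which the sample carries the variant (het or hom-alt)
    contribute to its spectrum; the heterozygosity rate is het calls per
    thousand callable bases, with the caller choosing the denominator
    (typically the N-excluded reference length).
    """
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    counts = Counter({label: 0 for label in MUTATION_CLASSES})
    het = 0
    for variant in snps:
        if variant.kind is not VariantKind.SNP:
            raise ValueError("spectrum_summary expects SNPs only")
        genotype = _sample_genotype(variant, sample_id)
        if genotype in (Genotype.HOM_REF, Genotype.MISSING):
            continue
        counts[collapse_mutation_class(variant.ref, variant.alt)] += 1
        if genotype is Genotype.HET:
            het += 1
    return SpectrumSummary(
        sample_id=sample_id,
        class_counts=dict(counts),
        het_snp_count=het,
        callable_bases=callable_bases,
    )


def indel_summary(
    indels: Iterable[ClassifiedVariant],
    sample_id: str,
    callable_bases: int,
) -> IndelSummary:
    """Length histogram and insertion/deletion totals for one sample."""
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    histogram: Counter[int] = Counter()
    insertions = deletions = het = 0
    for variant in indels:
        if variant.kind is VariantKind.SNP:
            raise ValueError("indel_summary expects InDels only")
        genotype = _sample_genotype(variant, sample_id)
        if genotype in (Genotype.HOM_REF, Genotype.MISSING):
            continue
        histogram[variant.indel_length] += 1
        if variant.kind is VariantKind.INSERTION:
            insertions += 1
        else:
            deletions += 1
        if genotype is Genotype.HET:
            het += 1
    return IndelSummary(
        sample_id=sample_id,
        insertion_count=insertions,
        deletion_count=deletions,
        length_histogram=dict(histogram),
        het_indel_count=het,
        callable_bases=callable_bases,
    )


def window_density(
    variants: Iterable[ClassifiedVariant],
    genome: Sequence[GenomeSequence],
    window_size: int = 1_000_000,
) -> dict[str, DensityTrack]:
    """Bin variant start positions into half-open windows tiling [0, L).

    The last window may be short.  A variant beyond its chromosome length is
    an error naming the record.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lengths = {g.name: g.length for g in genome}
    tracks = {
        name: DensityTrack(
            chromosome=name,
            chromosome_length=length,
            window_size=window_size,
            snp_counts=np.zeros(-(-length // window_size) or 1, dtype=int),
            indel_counts=np.zeros(-(-length // window_size) or 1, dtype=int),
        )
        for name, length in lengths.items()
    }
    for variant in variants:
        record = variant.record
        if record.chromosome not in lengths:
            raise ValueError(f"variant {record.chromosome}:{record.position} on unknown chromosome")
        if not 1 <= record.position <= lengths[record.chromosome]:
            raise ValueError(
                f"variant {record.chromosome}:{record.position} beyond chromosome length "
                f"{lengths[record.chromosome]}"
            )
        window = (record.position - 1) // window_size
        track = tracks[record.chromosome]
        if variant.kind is VariantKind.SNP:
            track.snp_counts[window] += 1
        else:
            track.indel_counts[window] += 1
    return tracks


def write_spectrum_table(summaries: Iterable[SpectrumSummary], path) -> None:
    with open(path, "w") as fh:
        header = ["sample", *MUTATION_CLASSES, "transitions", "transversions",
                  "ts_tv_ratio", "het_snp_count", "het_rate_permille", "snp_total"]
        fh.write("\t".join(header) + "\n")
        for s in summaries:
            ratio = "" if s.ts_tv_ratio is None else f"{s.ts_tv_ratio:.4f}"
            row = [s.sample_id, *(str(s.class_counts[c]) for c in MUTATION_CLASSES),
                   str(s.transitions), str(s.transversions), ratio,
                   str(s.het_snp_count), f"{s.het_rate_permille:.4f}", str(s.snp_total)]
            fh.write("\t".join(row) + "\n")


def write_indel_table(summaries: Iterable[IndelSummary], path, max_length: int = 50) -> None:
    with open(path, "w") as fh:
        header = ["sample", "insertions", "deletions", "het_indel_rate_permille",
                  *(f"len_{i}_pct" for i in range(1, max_length + 1))]
        fh.write("\t".join(header) + "\n")
        for s in summaries:
            pct = s.length_percentages
            row = [s.sample_id, str(s.insertion_count), str(s.deletion_count),
                   f"{s.het_indel_rate_permille:.4f}",
                   *(f"{pct.get(i, 0.0):.4f}" for i in range(1, max_length + 1))]
            fh.write("\t".join(row) + "\n")


def write_density_tracks(tracks: Mapping[str, DensityTrack], path) -> None:
    """BED-like export: 0-based half-open windows with SNP and InDel counts."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsnp_count\tindel_count\n")
        for name in tracks:
            track = tracks[name]
            for i in range(track.n_windows):
                start = i * track.window_size
                end = min(start + track.window_size, track.chromosome_length)
                fh.write(f"{name}\t{start}\t{end}\t{track.snp_counts[i]}\t{track.indel_counts[i]}\n")
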