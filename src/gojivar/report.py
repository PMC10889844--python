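"""Pipeline orchestration and publication-style table rendering.

Chains the stages — IO, post-call QC, spectrum/InDel/density summaries,
coding-consequence annotation and cohort discrimination — and renders the
per-gene tables in the layout of the published coding-SNP tables so the two
can be diffed directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .consequence import (
    NON_CODING,
    CodingPosition,
    build_codon_change,
    classify_effect,
    classify_site_row,
    group_codon_variants,
    project_to_cds,
)
from .discrimination import DiscriminationReport, gene_discrimination_report
from .genomic_io import (
    CdsModel,
    CohortMap,
    GenomeSequence,
    Genotype,
    SampleCall,
    SiteRow,
    SiteStateMatrix,
    load_packaged_site_tables,
    read_cds_annotation,
    read_cohorts,
    read_fasta,
    read_site_table,
    read_vcf,
)
from .spectrum import (
    indel_summary,
    spectrum_summary,
    window_density,
    write_density_tracks,
    write_indel_table,
    write_spectrum_table,
)
from .synthetic_data import SimulationConfig, simulate_run
from .variant_qc import FilterThresholds, VariantKind, filter_variants, write_filter_report

logger = logging.getLogger("gojivar")

__all__ = ["RunConfig", "run_pipeline", "build_site_matrices", "render_gene_table"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class RunConfig:
    """Either explicit input paths or a simulation block — never both."""

    fasta: Path | None = None
    gff: Path | None = None
    vcf: Path | None = None
    cohorts: Path | None = None
    site_tables: tuple[Path, ...] = ()
    simulate: SimulationConfig | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    window_size: int = 1_000_000
    outdir: Path = Path("gojivar_run")

    def __post_init__(self) -> None:
        has_paths = self.vcf is not None or self.site_tables
        if self.simulate is not None and has_paths:
            raise ValueError("provide either input paths or a simulate block, not both")
        if self.simulate is None and not has_paths:
            raise ValueError("no inputs: provide a VCF (with FASTA/GFF/cohorts) or site tables")


class ReferenceMismatchError(ValueError):
    """A variant allele contradicts the reference base it claims to change."""


def _collapse(sample_id: str, states: Sequence[SampleCall]) -> SampleCall:
    if any(s.genotype is Genotype.MISSING for s in states):
        return SampleCall(sample_id, Genotype.MISSING)
    hets = [s for s in states if s.genotype is Genotype.HET]
    if hets:
        return SampleCall(sample_id, Genotype.HET, alt_read_fraction=hets[0].alt_read_fraction)
    if any(s.genotype is Genotype.HOM_ALT for s in states):
        return SampleCall(sample_id, Genotype.HOM_ALT)
    return SampleCall(sample_id, Genotype.HOM_REF)


def build_site_matrices(
    genomes: Sequence[GenomeSequence],
    cds_models: Sequence[CdsModel],
    kept_snps,
    samples: Sequence[str],
    full_enumeration: bool = False,
) -> tuple[dict[str, SiteStateMatrix], int]:
    """Project kept SNPs into each gene's CDS and assemble per-gene matrices.

    Returns the matrices plus the count of SNPs that fell outside every CDS.
    Multi-SNP codons list the alternate codons attested by per-sample
    genotypes (a sample carrying several same-codon alternates attests their
    combination); ``full_enumeration`` forces every non-empty combination
    instead.
    """
    genome_by_name = {g.name: g for g in genomes}
    snps_by_chrom: dict[str, list] = {}
    for v in kept_snps:
        snps_by_chrom.setdefault(v.record.chromosome, []).append(v)

    non_coding = 0
    coding_keys: set[tuple[str, int]] = set()
    matrices: dict[str, SiteStateMatrix] = {}
    for model in cds_models:
        genome = genome_by_name.get(model.chromosome)
        if genome is None:
            raise ValueError(f"gene {model.gene_id}: chromosome {model.chromosome} not in FASTA")
        cds_seq = model.spliced_sequence(genome.sequence)
        sites: list[tuple[CodingPosition, str, object]] = []
        for variant in snps_by_chrom.get(model.chromosome, []):
            projected = project_to_cds(model.chromosome, variant.record.position, model)
            if projected == NON_CODING:
                continue
            coding_keys.add((model.chromosome, variant.record.position))
            ref_o, alt_o = variant.ref, variant.alt
            if model.strand == "-":
                ref_o, alt_o = _COMPLEMENT[ref_o], _COMPLEMENT[alt_o]
            if cds_seq[projected.cds_position - 1] != ref_o:
                raise ReferenceMismatchError(
                    f"gene {model.gene_id} CDS position {projected.cds_position}: VCF reference "
                    f"{ref_o} != CDS base {cds_seq[projected.cds_position - 1]}"
                )
            sites.append((projected, alt_o, variant))

        rows: list[SiteRow] = []
        for group in group_codon_variants([cp for cp, _, _ in sites]):
            members = [next(s for s in sites if s[0] == cp) for cp in group]
            start = (group[0].codon_index - 1) * 3
            ref_codon = cds_seq[start : start + 3]
            single_subs = {}
            for cp, alt_base, _variant in members:
                codon = list(ref_codon)
                codon[cp.offset_in_codon - 1] = alt_base
                single_subs[cp.cds_position] = "".join(codon)

            combos: set[tuple[int, ...]] = set()
            if full_enumeration:
                from itertools import combinations

                for k in range(1, len(members) + 1):
                    combos.update(combinations([cp.cds_position for cp, _, _ in members], k))
            else:
                for sample in samples:
                    carried = tuple(
                        cp.cds_position
                        for cp, _, variant in members
                        if variant.record.call_for(sample).genotype
                        in (Genotype.HET, Genotype.HOM_ALT)
                    )
                    if carried:
                        combos.add(carried)
                if not combos:  # no carrier: still report each single substitution
                    combos = {(cp.cds_position,) for cp, _, _ in members}
            alt_codons = []
            for combo in sorted(combos):
                codon = list(ref_codon)
                for cp, alt_base, _variant in members:
                    if cp.cds_position in combo:
                        codon[cp.offset_in_codon - 1] = alt_base
                alt_codons.append("".join(codon))

            positions = tuple(cp.cds_position for cp, _, _ in members)
            position_states = {
                cp.cds_position: {
                    s: variant.record.call_for(s) for s in samples
                }
                for cp, _, variant in members
            }
            row_states = {
                s: _collapse(s, [position_states[p][s] for p in positions]) for s in samples
            }
            rows.append(
                SiteRow(
                    printed_positions="-".join(str(p) for p in positions),
                    positions=positions,
                    ref_codon=ref_codon,
                    alt_codons=tuple(dict.fromkeys(alt_codons)),
                    changed_offsets=tuple(
                        sorted({cp.offset_in_codon for cp, _, _ in members})
                    ),
                    aa_printed="",
                    ref_token="",
                    cell_tokens={s: "" for s in samples},
                    row_states=row_states,
                    position_states=position_states,
                )
            )
        matrices[model.gene_id] = SiteStateMatrix(
            gene_id=model.gene_id,
            chromosome=model.chromosome,
            samples=tuple(samples),
            rows=rows,
        )
    for chrom, variants in snps_by_chrom.items():
        for variant in variants:
            if (chrom, variant.record.position) not in coding_keys:
                non_coding += 1
    return matrices, non_coding


_STATE_TOKEN = {
    Genotype.HOM_REF: "ref",
    Genotype.HOM_ALT: "alt",
    Genotype.MISSING: ".",
}


def _cell_token(call: SampleCall) -> str:
    if call.genotype is Genotype.HET:
        if call.alt_read_fraction is None:
            return "h?"
        return f"h{call.alt_read_fraction:.0f}"
    return _STATE_TOKEN[call.genotype]


def render_gene_table(
    matrix: SiteStateMatrix,
    report: DiscriminationReport,
    path: str | Path,
) -> None:
    """Write the per-gene consequence/discrimination TSV, table-layout style.

    Column order mirrors the published tables — row number, CDS position(s),
    codons, amino acids — followed by the effect class, the discriminating
    flag and one state column per sample.
    """
    with open(path, "w") as fh:
        header = ["nr", "positions", "codon", "amino_acid", "effect", "discriminating",
                  *matrix.samples]
        fh.write("\t".join(header) + "\n")
        for i, row in enumerate(matrix.rows, start=1):
            change = classify_site_row(row, matrix.gene_id)
            codons = "/".join((row.ref_codon, *row.alt_codons))
            aas = "/".join((change.ref_aa, *change.alt_aas))
            disc = row.printed_positions in report.discriminating_row_labels
            cells = [
                row.cell_tokens.get(s) or _cell_token(row.row_states[s])
                for s in matrix.samples
            ]
            fh.write(
                "\t".join(
                    [str(i), row.printed_positions, codons, aas, change.effect,
                     "yes" if disc else "no", *cells]
                )
                + "\n"
            )


def _report_dict(report: DiscriminationReport) -> dict:
    return {
        "gene_id": report.gene_id,
        "n_rows": report.n_rows,
        "n_positions": report.n_positions,
        "n_discriminating_rows": report.n_discriminating_rows,
        "n_discriminating_positions": report.n_discriminating_positions,
        "percent_discriminating": report.percent_discriminating,
        "discriminating_rows": report.discriminating_row_labels,
        "non_discriminating_rows": report.non_discriminating_row_labels,
        "discriminating_positions": report.discriminating_positions,
        "non_discriminating_positions": report.non_discriminating_positions,
        "cross_tab": report.cross_tab,
        "row_effects": report.row_effects,
        "notes": report.notes,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute io -> qc -> spectrum -> consequence -> discrimination.

    Writes all tabular outputs plus ``summary.json`` into the run directory
    and returns the summary dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    summary: dict = {}
    try:
        if config.simulate is not None:
            logger.info("simulating inputs (seed=%d)", config.simulate.seed)
            paths = simulate_run(config.simulate, outdir / "sim")
            config.fasta, config.gff = paths["fasta"], paths["gff"]
            config.vcf, config.cohorts = paths["vcf"], paths["cohorts"]

        matrices: dict[str, SiteStateMatrix] = {}
        cohorts: CohortMap | None = None
        if config.cohorts is not None:
            cohorts = read_cohorts(config.cohorts)

        if config.site_tables:
            for path in config.site_tables:
                matrix = read_site_table(path)
                matrices[matrix.gene_id] = matrix
                for corr in matrix.corrections_applied:
                    logger.warning("fixture correction: %s", corr)
        elif config.vcf is not None:
            genomes = read_fasta(config.fasta) if config.fasta else []
            cds_models = read_cds_annotation(config.gff) if config.gff else []
            records = list(read_vcf(config.vcf))
            kept, dropped = filter_variants(records, config.thresholds)
            write_filter_report(dropped, outdir / "filter_report.tsv")
            snps = [v for v in kept if v.kind is VariantKind.SNP]
            indels = [v for v in kept if v.kind is not VariantKind.SNP]
            callable_bases = sum(g.length - g.sequence.count("N") for g in genomes) or None
            samples = sorted({c.sample_id for r in records for c in r.calls})
            summary["qc"] = {
                "input_records": len(records),
                "kept_snps": len(snps),
                "kept_indels": len(indels),
                "dropped": len(dropped),
            }
            if callable_bases:
                spectra = [spectrum_summary(snps, s, callable_bases) for s in samples]
                indel_stats = [indel_summary(indels, s, callable_bases) for s in samples]
                write_spectrum_table(spectra, outdir / "spectrum.tsv")
                write_indel_table(indel_stats, outdir / "indel_lengths.tsv")
                tracks = window_density(kept, genomes, config.window_size)
                write_density_tracks(tracks, outdir / "density.tsv")
                summary["spectrum"] = {
                    s.sample_id: {
                        "ts_tv_ratio": s.ts_tv_ratio,
                        "het_rate_permille": s.het_rate_permille,
                        "snp_total": s.snp_total,
                    }
                    for s in spectra
                }
                summary["indels"] = {
                    s.sample_id: {
                        "total": s.total,
                        "pct_1bp": s.length_percentages.get(1, 0.0),
                        "het_rate_permille": s.het_indel_rate_permille,
                    }
                    for s in indel_stats
                }
            if cds_models and genomes:
                matrices, non_coding = build_site_matrices(genomes, cds_models, snps, samples)
                summary["non_coding_snps"] = non_coding

        if matrices and cohorts is not None:
            summary["discrimination"] = {}
            for gene_id, matrix in matrices.items():
                report = gene_discrimination_report(matrix, cohorts)
                logger.info(report.summary_line())
                render_gene_table(matrix, report, outdir / f"gene_{gene_id}.tsv")
                (outdir / f"gene_{gene_id}.json").write_text(
                    json.dumps(_report_dict(report), indent=2) + "\n"
                )
                summary["discrimination"][gene_id] = _report_dict(report)

        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
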