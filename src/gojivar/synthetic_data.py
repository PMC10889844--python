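"""Two-cohort resequencing variant simulator.

Generates a random reference genome with annotated single-exon CDS genes and
a two-cohort (cultivated/wild) variant call set with the statistical
structure the downstream analyses assume:

* SNP substitutions drawn from a configurable six-class strand-collapsed
  spectrum (defaults tuned to a transition/transversion ratio of 1.72 with
  C:G>T:A the most and C:G>G:C the least frequent class);
* per-sample heterozygous-call rates targeting a per-mille rate measured on
  filter-passing calls;
* InDel lengths from a decreasing law (~49.4% 1 bp, ~13% 2 bp, ~7% 3 bp,
  <1% beyond 12 bp, <0.1% beyond 32 bp);
* variant density multiplicatively enriched in the terminal fraction of each
  chromosome;
* a configurable fraction of coding SNP sites planted so the two cohorts are
  uniform in different genotype classes (cultivated het / wild hom-ref, or
  cultivated hom-alt / wild het, with equal probability);
* record-level DP and MQ drawn above or below the post-call filter
  thresholds according to a configured pass rate.

Determinism: every random quantity comes from streams keyed on
``(seed, stream-id[, sample-index])``, so a fixed seed reproduces the output
byte-for-byte and adding samples does not perturb genome or site draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genomic_io import (
    CdsModel,
    CohortMap,
    GenomeSequence,
    Genotype,
    SampleCall,
    VariantRecord,
    write_cds_annotation,
    write_cohorts,
    write_fasta,
    write_vcf,
)

__all__ = ["SimulationConfig", "ConfigError", "simulate_genome", "simulate_cohort_variants", "simulate_run"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Stream ids for keyed random substreams (documented draw order).
_STREAM_GENOME = 0
_STREAM_SITES = 1
_STREAM_EVIDENCE = 2
_STREAM_SAMPLE_BASE = 10


class ConfigError(ValueError):
    """An invalid or internally inconsistent simulation configuration."""


def _default_class_probabilities() -> dict[str, float]:
    # Transition share fixed by the target ts/tv of 1.72; within-share splits
    # follow the observed ordering (C:G>T:A > T:A>C:G; C:G>G:C rarest).
    ts = 1.72 / 2.72
    tv = 1.0 - ts
    return {
        "C:G>T:A": 0.52 * ts,
        "T:A>C:G": 0.48 * ts,
        "T:A>G:C": 0.29 * tv,
        "C:G>A:T": 0.29 * tv,
        "T:A>A:T": 0.26 * tv,
        "C:G>G:C": 0.16 * tv,
    }


def _default_indel_lengths() -> dict[int, float]:
    dist = {1: 0.494, 2: 0.13, 3: 0.07}
    mid = [0.060, 0.048, 0.040, 0.034, 0.029, 0.025, 0.022, 0.020, 0.018]
    for length, p in zip(range(4, 13), mid):
        dist[length] = p
    # Geometric tail, 13..50, mass 0.010 total: <1% beyond 12 bp, <0.1% past 32.
    r = 0.78
    weights = np.array([r ** (l - 13) for l in range(13, 51)])
    weights = 0.010 * weights / weights.sum()
    for length, p in zip(range(13, 51), weights):
        dist[length] = float(p)
    return dist


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the study conditions."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 500_000))
    n_cultivated: int = 5
    n_wild: int = 3
    snp_rate: float = 0.0084            # expected SNP sites per base
    n_snps: int | None = None           # fixed total SNP count (overrides snp_rate)
    class_probabilities: dict[str, float] = field(default_factory=_default_class_probabilities)
    het_rate_permille: float = 5.037    # per-sample het SNPs per 1000 bases, post-filter
    hom_alt_probability: float = 0.25   # per-sample hom-alt probability at a SNP site
    indel_rate: float = 0.00084
    n_indels: int | None = None
    indel_length_distribution: dict[int, float] = field(default_factory=_default_indel_lengths)
    indel_het_rate_permille: float = 0.381
    deletion_probability: float = 0.538
    end_density_gradient: float = 3.0   # rate multiplier in terminal regions
    end_fraction: float = 0.1           # terminal fraction of each chromosome, per end
    n_cds_genes: int = 2
    cds_length: int = 300
    discriminating_site_fraction: float = 0.5
    filter_pass_rate: float = 0.95
    mean_depth: float = 10.0

    def __post_init__(self) -> None:
        probs = np.array(list(self.class_probabilities.values()))
        if not np.isclose(probs.sum(), 1.0, atol=1e-9) or (probs < 0).any():
            raise ConfigError("class_probabilities must be a distribution over six classes")
        if len(self.class_probabilities) != 6:
            raise ConfigError("expected exactly six mutation classes")
        lengths = np.array(list(self.indel_length_distribution.values()))
        if not np.isclose(lengths.sum(), 1.0, atol=1e-6) or (lengths < 0).any():
            raise ConfigError("indel_length_distribution must be a distribution")
        if any(not 1 <= l <= 50 for l in self.indel_length_distribution):
            raise ConfigError("InDel lengths must lie in [1, 50]")
        for rate in (self.snp_rate, self.indel_rate):
            if rate < 0:
                raise ConfigError("rates must be non-negative")
        if not 0 < self.filter_pass_rate <= 1:
            raise ConfigError("filter_pass_rate must lie in (0, 1]")
        if not 0 <= self.discriminating_site_fraction <= 1:
            raise ConfigError("discriminating_site_fraction must lie in [0, 1]")
        if self.het_probability + self.hom_alt_probability > 1:
            raise ConfigError(
                "heterozygosity target too high: het + hom-alt probability exceeds 1 "
                f"({self.het_probability:.3f} + {self.hom_alt_probability:.3f})"
            )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def effective_snp_rate(self) -> float:
        if self.n_snps is not None:
            return self.n_snps / self.total_length
        return self.snp_rate

    @property
    def effective_indel_rate(self) -> float:
        if self.n_indels is not None:
            return self.n_indels / self.total_length
        return self.indel_rate

    @property
    def het_probability(self) -> float:
        """Per-sample het probability at a SNP site.

        The per-mille target is defined on filter-passing calls, so the
        planted probability is inflated by 1/pass_rate.
        """
        if self.effective_snp_rate == 0:
            return 0.0
        return self.het_rate_permille / 1000.0 / (self.effective_snp_rate * self.filter_pass_rate)

    @property
    def indel_het_probability(self) -> float:
        if self.effective_indel_rate == 0:
            return 0.0
        return min(
            1.0,
            self.indel_het_rate_permille / 1000.0 / (self.effective_indel_rate * self.filter_pass_rate),
        )

    @property
    def sample_names(self) -> tuple[str, ...]:
        cultivated = [f"Lb{i}" for i in range(1, self.n_cultivated + 1)]
        wild = [f"Lb{self.n_cultivated + j}w" for j in range(1, self.n_wild + 1)]
        return tuple(cultivated + wild)

    def cohort_map(self) -> CohortMap:
        names = self.sample_names
        return CohortMap(
            {
                **{s: "cultivated" for s in names[: self.n_cultivated]},
                **{s: "wild" for s in names[self.n_cultivated :]},
            }
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple((str(n), int(l)) for n, l in raw["chromosomes"])
        if "indel_length_distribution" in raw:
            raw["indel_length_distribution"] = {
                int(k): float(v) for k, v in raw["indel_length_distribution"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["chromosomes"] = [list(c) for c in self.chromosomes]
        return out


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


# ---------------------------------------------------------------------------
# Genome and annotation

def simulate_genome(config: SimulationConfig) -> tuple[list[GenomeSequence], list[CdsModel]]:
    """Uniform-random chromosomes plus non-overlapping single-exon CDS genes.

    Genes are laid out round-robin across chromosomes in the central region,
    with strand drawn at random; CDS length must be divisible by 3.
    """
    if config.cds_length % 3 != 0:
        raise ConfigError("cds_length must be divisible by 3")
    rng = _rng(config, _STREAM_GENOME)
    genomes = []
    for name, length in config.chromosomes:
        codes = rng.integers(0, 4, size=length)
        genomes.append(GenomeSequence(name=name, sequence=_BASES[codes].tobytes().decode()))

    models: list[CdsModel] = []
    if config.n_cds_genes:
        per_chrom: dict[str, int] = {name: 0 for name, _ in config.chromosomes}
        for i in range(config.n_cds_genes):
            name, length = config.chromosomes[i % len(config.chromosomes)]
            slot = per_chrom[name]
            margin = max(1, int(length * config.end_fraction))
            start = margin + slot * (config.cds_length + 100)
            end = start + config.cds_length - 1
            if end > length - margin:
                raise ConfigError(
                    f"requested CDS genes do not fit on chromosome {name} "
                    f"(gene {i + 1} would end at {end} of {length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                CdsModel(
                    gene_id=f"gene{i + 1:03d}",
                    chromosome=name,
                    strand=strand,
                    segments=((start, end),),
                )
            )
            per_chrom[name] += 1
    return genomes, models


# ---------------------------------------------------------------------------
# Variants

def _allocate(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder allocation of an integer total across weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return [0] * len(weights)
    exact = total * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def _weighted_region_positions(
    rng: np.random.Generator,
    candidate_idx: np.ndarray,
    end_mask: np.ndarray,
    gradient: float,
    n: int,
) -> np.ndarray:
    """Sample n distinct 0-based positions, terminal regions upweighted.

    The gradient takes only two values (1 in the interior, g at the ends), so
    the draw splits into a binomial count per region followed by uniform
    sampling without replacement inside each region.
    """
    if n == 0:
        return np.empty(0, dtype=np.int64)
    in_end = end_mask[candidate_idx]
    idx_end = candidate_idx[in_end]
    idx_mid = candidate_idx[~in_end]
    w_end = gradient * len(idx_end)
    w_mid = float(len(idx_mid))
    if w_end + w_mid == 0:
        raise ConfigError("no candidate positions to place variants on")
    n_end = rng.binomial(n, w_end / (w_end + w_mid))
    n_end = min(n_end, len(idx_end))
    n_mid = min(n - n_end, len(idx_mid))
    n_end = n - n_mid  # spill back if the interior is exhausted
    if n_end > len(idx_end):
        raise ConfigError("more variants requested than candidate positions")
    chosen = np.concatenate(
        [
            rng.choice(idx_end, size=n_end, replace=False) if n_end else np.empty(0, dtype=np.int64),
            rng.choice(idx_mid, size=n_mid, replace=False) if n_mid else np.empty(0, dtype=np.int64),
        ]
    )
    return chosen


_PYRIMIDINE_OF = {
    # class label -> (pyrimidine-strand ref, alt); the purine-strand mirror
    # is the complement of both.
    "T:A>C:G": ("T", "C"),
    "T:A>G:C": ("T", "G"),
    "T:A>A:T": ("T", "A"),
    "C:G>T:A": ("C", "T"),
    "C:G>A:T": ("C", "A"),
    "C:G>G:C": ("C", "G"),
}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _alt_for(ref_base: str, label: str) -> str:
    ref_py, alt_py = _PYRIMIDINE_OF[label]
    if ref_base == ref_py:
        return alt_py
    if ref_base == _COMPLEMENT[ref_py]:
        return _COMPLEMENT[alt_py]
    raise ValueError(f"class {label} incompatible with reference base {ref_base}")


def _coding_mask(length: int, models: Sequence[CdsModel], chromosome: str) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for model in models:
        if model.chromosome != chromosome:
            continue
        for start, end in model.segments:
            mask[start - 1 : end] = True
    return mask


def simulate_cohort_variants(
    config: SimulationConfig,
    genomes: Sequence[GenomeSequence],
    cds_models: Sequence[CdsModel],
) -> list[VariantRecord]:
    """Draw the full two-cohort variant set over a simulated genome.

    Draw order per chromosome: SNP class counts, SNP positions (terminal
    regions upweighted), InDel positions/lengths/types, then per-record
    DP/MQ evidence; per-sample genotype and read-depth draws come from
    sample-keyed streams so the site layout is invariant to cohort size.
    """
    site_rng = _rng(config, _STREAM_SITES)
    evidence_rng = _rng(config, _STREAM_EVIDENCE)
    samples = config.sample_names
    n_cult = config.n_cultivated
    labels = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[l] for l in labels])

    lengths = [g.length for g in genomes]
    n_snps_total = (
        config.n_snps if config.n_snps is not None else int(round(config.snp_rate * sum(lengths)))
    )
    n_indels_total = (
        config.n_indels if config.n_indels is not None else int(round(config.indel_rate * sum(lengths)))
    )
    snps_per_chrom = _allocate(n_snps_total, lengths)
    indels_per_chrom = _allocate(n_indels_total, lengths)

    p_het = config.het_probability
    p_hom = config.hom_alt_probability
    p_het_indel = config.indel_het_probability
    p_hom_indel = min(config.hom_alt_probability, 1.0 - p_het_indel)

    records: list[VariantRecord] = []
    for chrom_i, genome in enumerate(genomes):
        length = genome.length
        seq_codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        end_span = int(length * config.end_fraction)
        end_mask = np.zeros(length, dtype=bool)
        if end_span:
            end_mask[:end_span] = True
            end_mask[-end_span:] = True

        # --- SNP sites -----------------------------------------------------
        n_snps = snps_per_chrom[chrom_i]
        class_counts = site_rng.multinomial(n_snps, probs)
        ta_mask = (seq_codes == ord("T")) | (seq_codes == ord("A"))
        cg_mask = (seq_codes == ord("C")) | (seq_codes == ord("G"))
        pair_of = {l: ("TA" if l.startswith("T") else "CG") for l in labels}
        n_ta = sum(c for l, c in zip(labels, class_counts) if pair_of[l] == "TA")
        n_cg = n_snps - n_ta

        pos_ta = _weighted_region_positions(
            site_rng, np.flatnonzero(ta_mask), end_mask, config.end_density_gradient, n_ta
        )
        pos_cg = _weighted_region_positions(
            site_rng, np.flatnonzero(cg_mask), end_mask, config.end_density_gradient, n_cg
        )
        class_list: list[str] = []
        for label, count in zip(labels, class_counts):
            if pair_of[label] == "TA":
                class_list.extend([label] * count)
        for label, count in zip(labels, class_counts):
            if pair_of[label] == "CG":
                class_list.extend([label] * count)
        positions0 = np.concatenate([pos_ta, pos_cg])
        class_arr = np.array(class_list)

        order = np.argsort(positions0, kind="stable")
        positions0 = positions0[order]
        class_arr = class_arr[order]

        # --- discriminating coding sites ----------------------------------
        coding = _coding_mask(length, cds_models, genome.name)
        is_coding = coding[positions0] if len(positions0) else np.zeros(0, dtype=bool)
        disc_flags = np.zeros(len(positions0), dtype=bool)
        disc_pattern = np.zeros(len(positions0), dtype=np.int8)
        coding_idx = np.flatnonzero(is_coding)
        if len(coding_idx):
            draws = site_rng.random(len(coding_idx))
            chosen = coding_idx[draws < config.discriminating_site_fraction]
            disc_flags[chosen] = True
            disc_pattern[chosen] = site_rng.integers(0, 2, size=len(chosen))

        # --- per-sample genotypes (sample-keyed streams) -------------------
        geno = np.zeros((len(samples), len(positions0)), dtype=np.int8)  # 0=hom_ref,1=het,2=hom_alt
        for s_i, _sample in enumerate(samples):
            srng = _rng(config, _STREAM_SAMPLE_BASE + s_i, chrom_i)
            draws = srng.random(len(positions0))
            geno[s_i] = np.where(draws < p_het, 1, np.where(draws < p_het + p_hom, 2, 0))
        cult_rows = np.arange(len(samples)) < n_cult
        # pattern 0: cultivated het, wild hom-ref; pattern 1: cultivated hom-alt, wild het
        for j in np.flatnonzero(disc_flags):
            if disc_pattern[j] == 0:
                geno[cult_rows, j] = 1
                geno[~cult_rows, j] = 0
            else:
                geno[cult_rows, j] = 2
                geno[~cult_rows, j] = 1

        # --- per-sample read depths ---------------------------------------
        depth = np.zeros_like(geno, dtype=np.int64)
        alt_depth = np.zeros_like(geno, dtype=np.int64)
        for s_i, _sample in enumerate(samples):
            srng = _rng(config, _STREAM_SAMPLE_BASE + s_i, chrom_i, 1)
            d = np.maximum(1, srng.poisson(config.mean_depth, size=geno.shape[1]))
            a = srng.binomial(d, 0.5)
            depth[s_i] = d
            alt_depth[s_i] = np.where(geno[s_i] == 1, np.maximum(1, np.minimum(d - 1, a)), 0)
            alt_depth[s_i][geno[s_i] == 2] = d[geno[s_i] == 2]

        # --- SNP records ---------------------------------------------------
        snp_evidence = _draw_evidence(evidence_rng, len(positions0), config)
        for j, pos0 in enumerate(positions0):
            ref = genome.sequence[pos0]
            alt = _alt_for(ref, str(class_arr[j]))
            records.append(
                _make_record(
                    genome.name, int(pos0) + 1, ref, alt, samples, geno[:, j],
                    depth[:, j], alt_depth[:, j], snp_evidence[j],
                )
            )

        # --- InDels --------------------------------------------------------
        n_indels = indels_per_chrom[chrom_i]
        taken = np.zeros(length, dtype=bool)
        taken[positions0] = True
        candidates = np.flatnonzero(~taken[: length - 51])
        indel_pos = _weighted_region_positions(
            site_rng, candidates, end_mask[: length - 51], config.end_density_gradient, n_indels
        )
        indel_pos.sort()
        ilengths = list(config.indel_length_distribution)
        ilen = site_rng.choice(ilengths, size=n_indels, p=[config.indel_length_distribution[l] for l in ilengths])
        is_del = site_rng.random(n_indels) < config.deletion_probability
        igeno = np.zeros((len(samples), n_indels), dtype=np.int8)
        for s_i, _sample in enumerate(samples):
            srng = _rng(config, _STREAM_SAMPLE_BASE + s_i, chrom_i, 2)
            draws = srng.random(n_indels)
            igeno[s_i] = np.where(draws < p_het_indel, 1, np.where(draws < p_het_indel + p_hom_indel, 2, 0))
        indel_evidence = _draw_evidence(evidence_rng, n_indels, config)
        ins_rng = _rng(config, _STREAM_SITES, chrom_i, 99)
        for j, pos0 in enumerate(indel_pos):
            L = int(ilen[j])
            anchor = genome.sequence[pos0]
            if is_del[j]:
                ref = genome.sequence[pos0 : pos0 + L + 1]
                alt = anchor
            else:
                inserted = _BASES[ins_rng.integers(0, 4, size=L)].tobytes().decode()
                ref = anchor
                alt = anchor + inserted
            records.append(
                _make_record(
                    genome.name, int(pos0) + 1, ref, alt, samples, igeno[:, j],
                    np.full(len(samples), int(config.mean_depth)),
                    None, indel_evidence[j],
                )
            )

    records.sort(key=lambda r: (r.chromosome, r.position))
    return records


def _draw_evidence(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> list[tuple[int, float]]:
    """(DP, MQ) per record: above both thresholds with the configured rate."""
    out = []
    passes = rng.random(n) < config.filter_pass_rate
    which = rng.integers(0, 2, size=n)  # failing records: 0 -> low DP, 1 -> low MQ
    dp_pass = rng.integers(5, 61, size=n)
    dp_fail = rng.integers(1, 5, size=n)
    mq_pass = np.round(rng.uniform(20.5, 60.0, size=n), 1)
    mq_fail = np.round(rng.uniform(2.0, 20.0, size=n), 1)
    for i in range(n):
        if passes[i]:
            out.append((int(dp_pass[i]), float(mq_pass[i])))
        elif which[i] == 0:
            out.append((int(dp_fail[i]), float(mq_pass[i])))
        else:
            out.append((int(dp_pass[i]), float(mq_fail[i])))
    return out


_GENO_CODE = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}
_GT_INDICES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _make_record(
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
    samples: Sequence[str],
    geno_col: np.ndarray,
    depth_col: np.ndarray,
    alt_depth_col: np.ndarray | None,
    evidence: tuple[int, float],
) -> VariantRecord:
    calls = []
    for s_i, sample in enumerate(samples):
        code = int(geno_col[s_i])
        genotype = _GENO_CODE[code]
        d = int(depth_col[s_i])
        if alt_depth_col is not None:
            a = int(alt_depth_col[s_i])
            ad = (d - a, a)
            frac = 100.0 * a / d if genotype is Genotype.HET and d else None
        else:
            ad = None
            frac = None
        calls.append(
            SampleCall(
                sample_id=sample,
                genotype=genotype,
                alt_read_fraction=frac,
                allele_indices=_GT_INDICES[code],
                allele_depths=ad,
            )
        )
    dp, mq = evidence
    return VariantRecord(
        chromosome=chromosome,
        position=position,
        ref_allele=ref,
        alt_alleles=(alt,),
        calls=tuple(calls),
        supporting_reads=dp,
        rms_mapping_quality=mq,
    )


# ---------------------------------------------------------------------------
# Run directory

def simulate_run(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate genome + variants and write FASTA/GFF3/VCF/cohort TSV.

    Returns the paths of all written files; a ``manifest.json`` records the
    configuration and file list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, models = simulate_genome(config)
    records = simulate_cohort_variants(config, genomes, models)

    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "vcf": outdir / "variants.vcf",
        "cohorts": outdir / "cohorts.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(genomes, paths["fasta"])
    write_cds_annotation(models, paths["gff"])
    write_vcf(records, config.sample_names, paths["vcf"], contigs=[(g.name, g.length) for g in genomes])
    write_cohorts(config.cohort_map(), paths["cohorts"])
    manifest = {
        "config": config.to_dict(),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        "n_records": len(records),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
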