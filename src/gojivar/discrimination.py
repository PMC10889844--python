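"""Cohort-separation analysis of coding SNP sites.

A site discriminates the two cohorts when every cultivated sample shares one
genotype state class, every wild sample shares one state class, and the two
classes differ.  The alternate-read percentage of heterozygous calls plays no
role — het is het regardless of the read split.

Counts are reported at two granularities, because a coding-SNP table row is
a codon-change event that may bundle several substituted positions:

* **rows** — one decision per table row, using the collapsed row state
  (het anywhere in the codon makes the sample het for the row);
* **positions** — one decision per individual substituted CDS position.

The two coincide whenever every row carries a single SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .consequence import classify_site_row
from .genomic_io import CohortMap, Genotype, SampleCall, SiteStateMatrix

__all__ = [
    "SiteState",
    "DiscriminationReport",
    "site_state",
    "discriminates",
    "gene_discrimination_report",
]

UNASSESSABLE = "unassessable"


@dataclass(frozen=True)
class SiteState:
    state_class: Genotype
    alt_read_fraction: float | None = None


def site_state(call: SampleCall) -> SiteState | str:
    """Collapse a sample call to its three-way state class.

    Missing genotypes yield the :data:`UNASSESSABLE` marker rather than an
    exception; sites with unassessable samples are excluded from the
    discrimination denominator and listed separately.
    """
    if call.genotype is Genotype.MISSING:
        return UNASSESSABLE
    return SiteState(call.genotype, call.alt_read_fraction)


def discriminates(
    states: Mapping[str, SiteState | str],
    cohorts: CohortMap,
) -> bool | None:
    """Apply the uniform-and-distinct rule to one site.

    True iff each cohort is internally uniform in state class and the two
    cohorts' classes differ.  Returns None (indeterminate) when either cohort
    has no assessable sample; any unassessable sample makes the site
    indeterminate so that partial data can never flip a verdict.
    """
    classes: dict[str, set[Genotype]] = {"cultivated": set(), "wild": set()}
    for sample, cohort in cohorts.assignments.items():
        if sample not in states:
            raise KeyError(f"no state for sample {sample!r}")
        state = states[sample]
        if state == UNASSESSABLE:
            return None
        classes[cohort].add(state.state_class)
    if not classes["cultivated"] or not classes["wild"]:
        return None
    if len(classes["cultivated"]) > 1 or len(classes["wild"]) > 1:
        return False
    return classes["cultivated"] != classes["wild"]


def _percent_half_up(numerator: int, denominator: int) -> int | None:
    if denominator == 0:
        return None
    return math.floor(100.0 * numerator / denominator + 0.5)


@dataclass
class DiscriminationReport:
    gene_id: str
    n_rows: int
    n_positions: int
    n_discriminating_rows: int
    n_discriminating_positions: int
    discriminating_row_labels: list[str]
    non_discriminating_row_labels: list[str]
    discriminating_positions: list[int]
    non_discriminating_positions: list[int]
    indeterminate_row_labels: list[str]
    # rows cross-tabulated as {discriminating, non_discriminating} x {silent, non_silent}
    cross_tab: dict[str, dict[str, int]]
    row_effects: dict[str, str]
    notes: list[str] = field(default_factory=list)

    @property
    def percent_discriminating(self) -> int | None:
        """Row-level percentage, rounded half-up."""
        return _percent_half_up(self.n_discriminating_rows, self.n_rows)

    def summary_line(self) -> str:
        return (
            f"{self.gene_id}: {self.n_discriminating_rows}/{self.n_rows} codon-change rows "
            f"({self.percent_discriminating}%) and {self.n_discriminating_positions}/"
            f"{self.n_positions} substituted positions discriminate cultivated from wild"
        )


def gene_discrimination_report(
    matrix: SiteStateMatrix,
    cohorts: CohortMap,
) -> DiscriminationReport:
    """Apply the discrimination rule to every row and position of one gene.

    Indeterminate rows (any unassessable sample in either cohort) are
    excluded from ``n_rows``/``n_positions`` and listed separately.
    """
    for sample in matrix.samples:
        if sample not in cohorts.assignments:
            raise ValueError(f"cohort map lacks sample {sample!r} of gene {matrix.gene_id}")

    disc_rows: list[str] = []
    non_disc_rows: list[str] = []
    indeterminate: list[str] = []
    disc_positions: list[int] = []
    non_disc_positions: list[int] = []
    cross = {
        "discriminating": {"silent": 0, "non_silent": 0},
        "non_discriminating": {"silent": 0, "non_silent": 0},
    }
    effects: dict[str, str] = {}
    notes: list[str] = []
    n_rows = n_positions = 0

    for row in matrix.rows:
        change = classify_site_row(row, matrix.gene_id)
        effects[row.printed_positions] = change.effect
        silent_key = "silent" if change.effect == "synonymous" else "non_silent"

        row_verdict = discriminates(
            {s: site_state(c) for s, c in row.row_states.items()}, cohorts
        )
        if row_verdict is None:
            indeterminate.append(row.printed_positions)
        else:
            n_rows += 1
            if row_verdict:
                disc_rows.append(row.printed_positions)
                cross["discriminating"][silent_key] += 1
            else:
                non_disc_rows.append(row.printed_positions)
                cross["non_discriminating"][silent_key] += 1

        for pos in row.positions:
            verdict = discriminates(
                {s: site_state(c) for s, c in row.position_states[pos].items()}, cohorts
            )
            if verdict is None:
                continue
            n_positions += 1
            (disc_positions if verdict else non_disc_positions).append(pos)

        notes.extend(f"row {row.printed_positions}: {note}" for note in row.notes)

    return DiscriminationReport(
        gene_id=matrix.gene_id,
        n_rows=n_rows,
        n_positions=n_positions,
        n_discriminating_rows=len(disc_rows),
        n_discriminating_positions=len(disc_positions),
        discriminating_row_labels=disc_rows,
        non_discriminating_row_labels=non_disc_rows,
        discriminating_positions=disc_positions,
        non_discriminating_positions=non_disc_positions,
        indeterminate_row_labels=indeterminate,
        cross_tab=cross,
        row_effects=effects,
        notes=notes,
    )
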