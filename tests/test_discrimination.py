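"""The cohort site-discrimination rule and its per-gene reports."""

import random

import pytest
from hypothesis import given, strategies as st

from gojivar.discrimination import (
    UNASSESSABLE,
    SiteState,
    discriminates,
    gene_discrimination_report,
    site_state,
)
from gojivar.genomic_io import CohortMap, Genotype, SampleCall

CULT = [f"Lb{i}" for i in range(1, 6)]
WILD = ["Lb6w", "Lb7w", "Lb8w"]


def states(cult_classes, wild_classes):
    return {
        **{s: SiteState(c) for s, c in zip(CULT, cult_classes)},
        **{s: SiteState(c) for s, c in zip(WILD, wild_classes)},
    }


def uniform(cls, n):
    return [cls] * n


# ---------------------------------------------------------------------------
# site_state


def test_het_call_maps_to_het_state():
    call = SampleCall("Lb1", Genotype.HET, alt_read_fraction=69.0)
    state = site_state(call)
    assert state.state_class is Genotype.HET
    assert state.alt_read_fraction == 69.0


def test_missing_call_is_unassessable():
    assert site_state(SampleCall("Lb1", Genotype.MISSING)) == UNASSESSABLE


def test_hom_states_from_fixture_tokens(chr4_gene):
    row1312 = next(r for r in chr4_gene.rows if r.positions == (1312,))
    assert site_state(row1312.row_states["Lb1"]).state_class is Genotype.HOM_ALT
    row517 = chr4_gene.rows[0]
    assert site_state(row517.row_states["Lb6w"]).state_class is Genotype.HOM_REF


# ---------------------------------------------------------------------------
# the uniform-and-distinct rule


def test_uniform_het_vs_uniform_ref_discriminates(cohorts8):
    # chromosome-4 gene, position 517: cultivated all het, wild all hom-ref
    s = states(uniform(Genotype.HET, 5), uniform(Genotype.HOM_REF, 3))
    assert discriminates(s, cohorts8) is True


def test_mixed_wild_cohort_does_not_discriminate(cohorts8):
    # chromosome-4 gene, position 590: cultivated all hom-alt, wild het/hom-ref/het
    s = states(uniform(Genotype.HOM_ALT, 5), [Genotype.HET, Genotype.HOM_REF, Genotype.HET])
    assert discriminates(s, cohorts8) is False


def test_identical_classes_do_not_discriminate(cohorts8):
    # chromosome-4 gene, position 749: every sample heterozygous
    s = states(uniform(Genotype.HET, 5), uniform(Genotype.HET, 3))
    assert discriminates(s, cohorts8) is False


def test_unassessable_sample_makes_site_indeterminate(cohorts8):
    s = states(uniform(Genotype.HET, 5), uniform(Genotype.HOM_REF, 3))
    s["Lb3"] = UNASSESSABLE
    assert discriminates(s, cohorts8) is None


def test_missing_sample_is_an_error(cohorts8):
    s = states(uniform(Genotype.HET, 5), uniform(Genotype.HOM_REF, 3))
    del s["Lb1"]
    with pytest.raises(KeyError):
        discriminates(s, cohorts8)


def test_alt_read_fraction_is_ignored(cohorts8):
    base = states(uniform(Genotype.HET, 5), uniform(Genotype.HOM_REF, 3))
    shifted = {
        k: SiteState(v.state_class, 7.0) if v.state_class is Genotype.HET else v
        for k, v in base.items()
    }
    assert discriminates(base, cohorts8) == discriminates(shifted, cohorts8)


# ---------------------------------------------------------------------------
# invariance properties

_class_strategy = st.sampled_from([Genotype.HOM_REF, Genotype.HOM_ALT, Genotype.HET])


@given(st.lists(_class_strategy, min_size=5, max_size=5),
       st.lists(_class_strategy, min_size=3, max_size=3))
def test_label_symmetry(cult, wild):
    cohorts = CohortMap({**{s: "cultivated" for s in CULT}, **{s: "wild" for s in WILD}})
    s = states(cult, wild)
    assert discriminates(s, cohorts) == discriminates(s, cohorts.swapped())


@given(st.lists(_class_strategy, min_size=5, max_size=5),
       st.lists(_class_strategy, min_size=3, max_size=3),
       st.randoms(use_true_random=False))
def test_within_cohort_permutation_invariance(cult, wild, rnd):
    cohorts = CohortMap({**{s: "cultivated" for s in CULT}, **{s: "wild" for s in WILD}})
    baseline = discriminates(states(cult, wild), cohorts)
    cult2, wild2 = cult[:], wild[:]
    rnd.shuffle(cult2)
    rnd.shuffle(wild2)
    assert discriminates(states(cult2, wild2), cohorts) == baseline


@given(st.lists(_class_strategy, min_size=5, max_size=5),
       st.lists(_class_strategy, min_size=3, max_size=3),
       st.integers(0, 7))
def test_monotone_degradation(cult, wild, which):
    """Unassessable data removes a site from the denominator, never flips it."""
    cohorts = CohortMap({**{s: "cultivated" for s in CULT}, **{s: "wild" for s in WILD}})
    s = states(cult, wild)
    s[(CULT + WILD)[which]] = UNASSESSABLE
    assert discriminates(s, cohorts) is None


# ---------------------------------------------------------------------------
# full-table regression against the published tables


def test_chr4_gene_counts(chr4_gene, cohorts8):
    report = gene_discrimination_report(chr4_gene, cohorts8)
    assert report.n_discriminating_rows == 14
    assert report.n_rows == 22
    assert report.percent_discriminating == 64
    assert report.cross_tab["non_discriminating"] == {"silent": 8, "non_silent": 0}


def test_chr8_gene_counts(chr8_gene, cohorts8):
    report = gene_discrimination_report(chr8_gene, cohorts8)
    assert report.n_positions == 28
    assert report.n_discriminating_positions == 17
    # position 392-394 contributes both substituted positions, 287-288 only
    # the second (the first has a het wild sample)
    assert 392 in report.discriminating_positions
    assert 394 in report.discriminating_positions
    assert 288 in report.discriminating_positions
    assert 287 in report.non_discriminating_positions


def test_chr9_gene_counts(chr9_gene, cohorts8):
    report = gene_discrimination_report(chr9_gene, cohorts8)
    assert report.n_discriminating_rows == 15
    assert report.n_rows == 28
    non_disc = report.cross_tab["non_discriminating"]
    assert non_disc["silent"] + non_disc["non_silent"] == 13
    assert non_disc["silent"] == 7


def test_swapping_cohort_labels_preserves_all_reports(packaged_tables, cohorts8):
    for matrix in packaged_tables.values():
        a = gene_discrimination_report(matrix, cohorts8)
        b = gene_discrimination_report(matrix, cohorts8.swapped())
        assert a.discriminating_row_labels == b.discriminating_row_labels
        assert a.discriminating_positions == b.discriminating_positions


def test_report_partitions_rows(packaged_tables, cohorts8):
    for matrix in packaged_tables.values():
        report = gene_discrimination_report(matrix, cohorts8)
        assert (
            report.n_discriminating_rows
            + len(report.non_discriminating_row_labels)
            + len(report.indeterminate_row_labels)
            == matrix.n_rows
        )
        assert sum(v for d in report.cross_tab.values() for v in d.values()) == report.n_rows
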