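"""Consequence engine: classification, enumeration, stop designs, coverage."""

import itertools

import pandas as pd
import pytest
from Bio.Seq import Seq

from aidscan import (
    CodingSequence,
    Consequence,
    OverhangConfig,
    annotate_mutation_table,
    classify_consequence,
    coverage_report,
    design_guide_oligos,
    design_stop_targets,
    enumerate_outcomes,
    find_editable_cytosines,
    in_cds,
    projected_outcome_count,
    scan_pams,
    select_nonsynonymous_targets,
    single_ct_stop_gain_codons,
)
from aidscan.consequence import OutcomeCapExceeded

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def oracle_class(ref_codon, alt_codon, codon_index):
    """Independent translate-and-compare oracle via biopython."""
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return Consequence.SYNONYMOUS
    if alt_aa == "*":
        return Consequence.NONSENSE
    if codon_index == 1 and ref_codon == "ATG":
        return Consequence.START_LOSS
    return Consequence.MISSENSE


class TestClassification:
    def test_stop_gain_examples(self):
        assert classify_consequence("CGA", "TGA") is Consequence.NONSENSE
        assert classify_consequence("CAG", "TAG") is Consequence.NONSENSE
        assert classify_consequence("CAA", "TAA") is Consequence.NONSENSE

    def test_identity_synonymous(self):
        assert classify_consequence("GCT", "GCT") is Consequence.SYNONYMOUS

    def test_start_loss_overrides_missense(self):
        assert classify_consequence("ATG", "ATA", codon_index=1) is Consequence.START_LOSS
        assert classify_consequence("ATG", "ATA", codon_index=5) is Consequence.MISSENSE

    def test_invalid_codon(self):
        with pytest.raises(ValueError):
            classify_consequence("AXG", "ATG")

    def test_exhaustive_c_edit_oracle(self):
        """All 64 codons x all single-base C-edits match the translate oracle."""
        for codon in ALL_CODONS:
            for i, base in enumerate(codon):
                if base != "C":
                    continue
                for alt in "TGA":
                    alt_codon = codon[:i] + alt + codon[i + 1 :]
                    for idx in (1, 2):
                        assert (
                            classify_consequence(codon, alt_codon, codon_index=idx)
                            is oracle_class(codon, alt_codon, idx)
                        ), (codon, alt_codon, idx)


class TestStopDesignRules:
    def test_sense_single_ct_stop_set(self):
        sense, antisense = single_ct_stop_gain_codons()
        assert sense == {"CGA", "CAG", "CAA"}
        assert antisense == {"TGG"}

    def test_rule_matches_independent_brute_force(self):
        """Re-derive both sets with biopython translation only."""
        sense, antisense = set(), set()
        for codon in ALL_CODONS:
            if str(Seq(codon).translate()) == "*":
                continue
            for i, b in enumerate(codon):
                if b == "C" and str(Seq(codon[:i] + "T" + codon[i + 1 :]).translate()) == "*":
                    sense.add(codon)
                if b == "G" and str(Seq(codon[:i] + "A" + codon[i + 1 :]).translate()) == "*":
                    antisense.add(codon)
        assert single_ct_stop_gain_codons() == (sense, antisense)

    def test_no_qualifying_codon_gives_empty(self):
        cs = CodingSequence(id="x", cds="ATGGCTGCTTAA", upstream_flank="A" * 23,
                            downstream_flank="T" * 23)
        assert design_stop_targets(cs, scan_pams(cs)) == []

    def test_designs_report_truncation_and_stop_type(self, spt15):
        designs = design_stop_targets(spt15, scan_pams(spt15))
        assert designs
        n_res = spt15.n_codons
        for d in designs:
            assert 1 <= d.truncation_residue < n_res  # never the terminal stop
            assert d.stop_type in {"opal", "amber", "ochre"}
            (_, _, alt_codon), = d.outcome.codon_changes
            assert alt_codon in {"TAA", "TAG", "TGA"}
            # single C->T on the edited strand
            ((_, alt),) = d.outcome.edited_strand_changes
            assert alt == "T"


# CDS with a planted '+' site whose window holds exactly 3 sense-strand Cs:
# protospacer GCTACTCAATTGCAATTATT + PAM CGG; window = first 8 nt (GCTACTCA)
WINDOW3C = CodingSequence(
    id="w3c",
    cds="ATG" + "GCTACTCAATTGCAATTATT" + "CGG" + "ACTATTAAAG" + "TAA",
)


class TestEnumeration:
    def test_no_window_cytosines_no_outcomes(self):
        assert enumerate_outcomes(WINDOW3C, []) == []

    def test_default_mode_one_outcome_per_cytosine(self, spt15):
        ecs = in_cds(find_editable_cytosines(spt15, scan_pams(spt15)))
        outcomes = enumerate_outcomes(spt15, ecs, alphabet=("T",), max_multiplicity=1)
        assert len(outcomes) == len(ecs)

    def test_three_c_window_count_matches_closed_form_and_brute_force(self):
        sites = scan_pams(WINDOW3C)
        plus = [s for s in sites if s.strand == "+" and s.pam == "CGG"]
        assert plus, "scaffold must contain the planted +CGG site"
        site = plus[0]
        ecs = [e for e in find_editable_cytosines(WINDOW3C, [site])]
        assert len(ecs) == 3
        outcomes = enumerate_outcomes(WINDOW3C, ecs, alphabet=("T", "G", "A"),
                                      max_multiplicity=2)
        assert len(outcomes) == 3 * 3 + 3 * 9 == 36
        assert len(outcomes) == projected_outcome_count(3, 3, 2)
        # brute-force oracle: every subset of <=2 Cs x product assignments, unique
        seen = {(o.changes, o.site_id) for o in outcomes}
        assert len(seen) == 36

    def test_counts_match_closed_form_per_site(self, spt15):
        ecs = in_cds(find_editable_cytosines(spt15, scan_pams(spt15)))
        by_site = {}
        for e in ecs:
            by_site.setdefault(e.site_id, []).append(e)
        outcomes = enumerate_outcomes(spt15, ecs, alphabet=("T", "G"), max_multiplicity=2)
        expected = sum(
            projected_outcome_count(len(v), 2, 2) for v in by_site.values()
        )
        assert len(outcomes) == expected

    def test_cap_guard(self, spt15):
        ecs = in_cds(find_editable_cytosines(spt15, scan_pams(spt15)))
        with pytest.raises(OutcomeCapExceeded):
            enumerate_outcomes(spt15, ecs, alphabet=("T", "G", "A"),
                               max_multiplicity=6, cap=1000)

    def test_antisense_edit_reads_complement_on_sense(self, spt15):
        ecs = [e for e in in_cds(find_editable_cytosines(spt15, scan_pams(spt15)))
               if e.edited_strand == "-"]
        outcomes = enumerate_outcomes(spt15, ecs[:5], alphabet=("T",))
        for o in outcomes:
            (pos, ref, alt), = o.changes
            assert ref == "G" and alt == "A"  # antisense C->T is sense G->A

    def test_mixed_class_for_adjacent_codons(self):
        """One allele touching two codons with differing classes is MIXED."""
        ecs = in_cds(find_editable_cytosines(WINDOW3C, scan_pams(WINDOW3C)))
        outcomes = enumerate_outcomes(WINDOW3C, ecs, alphabet=("T", "G", "A"),
                                      max_multiplicity=2)
        multi = [o for o in outcomes if len(o.codon_changes) > 1]
        for o in multi:
            classes = set(o.per_codon_classes)
            if len(classes) > 1:
                assert o.consequence is Consequence.MIXED
            else:
                assert o.consequence in classes
        assert any(o.consequence is Consequence.MIXED for o in multi)

    def test_protein_annotation_ascending_slash_joined(self):
        ecs = in_cds(find_editable_cytosines(WINDOW3C, scan_pams(WINDOW3C)))
        outcomes = enumerate_outcomes(WINDOW3C, ecs, alphabet=("T",), max_multiplicity=2)
        for o in outcomes:
            if len(o.codon_changes) > 1:
                indices = [c[0] for c in o.codon_changes]
                assert indices == sorted(indices)
                assert o.protein_annotation.count("/") == len(indices) - 1


class TestNonsynonymousSelection:
    def test_no_pam_reference_empty(self):
        cs = CodingSequence(id="x", cds="ATGATTAAAATTTAA")  # no GG/CC anywhere
        assert select_nonsynonymous_targets(cs, scan_pams(cs)) == []

    def test_matches_enumerate_classify_filter_oracle(self, spt15):
        sites = scan_pams(spt15)
        selected = select_nonsynonymous_targets(spt15, sites, alphabet=("T", "G", "A"))
        ecs = in_cds(find_editable_cytosines(spt15, sites))
        oracle = [
            o for o in enumerate_outcomes(spt15, ecs, ("T", "G", "A"), 1)
            if o.consequence is Consequence.MISSENSE
        ]
        assert [o.changes for _, o in selected] == [o.changes for o in oracle]

    def test_alphabet_widening_monotonic(self, spt15):
        from aidscan.consequence import affected_residue_positions

        sites = scan_pams(spt15)
        narrow = affected_residue_positions(
            select_nonsynonymous_targets(spt15, sites, alphabet=("T",))
        )
        wide = affected_residue_positions(
            select_nonsynonymous_targets(spt15, sites, alphabet=("T", "G", "A"))
        )
        assert narrow <= wide


class TestCoverage:
    def test_cytosine_totals_at_poly_at(self):
        cs = CodingSequence(id="x", cds="ATGATTATTAAAATTTAA")
        rep = coverage_report(cs, scan_pams(cs))
        # sense has no C; the single G (ATG) is the only antisense C
        assert rep.total_C_sense == 0
        assert rep.fraction_sense == 0.0
        assert rep.targetable_C_sense == 0

    def test_totals_equal_brute_force_tally(self, spt15):
        rep = coverage_report(spt15, scan_pams(spt15))
        assert rep.total_C_sense == sum(b == "C" for b in spt15.cds)
        assert rep.total_C_antisense == sum(b == "G" for b in spt15.cds)

    def test_strand_totals_sum_to_c_plus_g(self, spt15):
        rep = coverage_report(spt15, scan_pams(spt15))
        assert rep.total_C_sense + rep.total_C_antisense == (
            spt15.cds.count("C") + spt15.cds.count("G")
        )

    def test_fractions_and_dedup(self, spt15):
        rep = coverage_report(spt15, scan_pams(spt15), alphabet=("T", "G", "A"))
        assert 0 <= rep.fraction_sense <= 1 and 0 <= rep.fraction_antisense <= 1
        assert rep.fraction_sense == rep.targetable_C_sense / rep.total_C_sense
        assert rep.targetable_C_sense_per_site >= rep.targetable_C_sense
        assert rep.nonsynonymous_positions <= set(range(1, spt15.n_codons + 1))


class TestGuideOligos:
    def test_empty_overhangs_forward_equals_guide(self, spt15):
        site = scan_pams(spt15)[0]
        d = design_guide_oligos(site)
        assert d.forward_oligo == site.protospacer
        assert d.reverse_oligo == str(Seq(site.protospacer).reverse_complement())

    def test_round_trip_reconstruction(self, spt15):
        site = scan_pams(spt15)[0]
        ov = OverhangConfig(forward_5="GATC", forward_3="GTTT")
        d = design_guide_oligos(site, ov)
        assert d.reconstruct_insert(ov) == "GATC" + site.protospacer + "GTTT"
        assert d.forward_oligo == "GATC" + site.protospacer + "GTTT"

    def test_wrong_guide_length_rejected(self, spt15):
        import dataclasses

        site = scan_pams(spt15)[0]
        short = dataclasses.replace(site, protospacer=site.protospacer[:19])
        with pytest.raises(ValueError):
            design_guide_oligos(short)


class TestMutationTable:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["strain_id", "cds_position", "edited_strand", "ref_base", "alt_base"],
        )

    def test_empty_table_zero_tallies(self, spt15):
        ann, tallies = annotate_mutation_table(spt15, self._table([]))
        assert tallies["n_strains"] == 0 and tallies["n_bases"] == 0
        assert tallies["C>T"] == tallies["C>G"] == tallies["C>A"] == 0

    def test_constructed_truth_exact_tallies(self):
        # cds codons: M  A  T  P  *   (ATG GCA ACT CCA TAA)
        cs = CodingSequence(id="x", cds="ATGGCAACTCCATAA")
        rows = [
            ("m1", 5, "+", "C", "T"),   # GCA->GTA  A2V
            ("m2", 10, "+", "C", "G"),  # CCA->GCA  P4A
            ("m2", 11, "+", "C", "T"),  # with 10: CCA->GTA  P4V (two-base codon change)
            ("m3", 6, "-", "C", "A"),   # sense G? position 6 is A on sense -> error row
        ]
        ann, tallies = annotate_mutation_table(cs, self._table(rows))
        assert tallies["n_strains"] == 2
        assert tallies["n_bases"] == 3
        assert tallies["C>T"] == 2 and tallies["C>G"] == 1 and tallies["C>A"] == 0
        assert len(tallies["row_errors"]) == 1
        by_id = dict(zip(ann.strain_id, ann.protein_annotation))
        assert by_id["m1"] == "A2V"
        assert by_id["m2"] == "P4V"

    def test_non_c_row_reported_not_fatal(self, spt15):
        rows = [("bad", 1, "+", "C", "T")]  # cds position 1 is A (ATG)
        ann, tallies = annotate_mutation_table(spt15, self._table(rows))
        assert tallies["n_strains"] == 0
        assert tallies["row_errors"]

    def test_synthetic_catalogue_annotations_match_reported_labels(self, spt15):
        from aidscan.data import mutant_catalogue

        df = mutant_catalogue()
        ann, tallies = annotate_mutation_table(spt15, df)
        reported = dict(zip(df.strain_id, df.reported_label))
        for _, row in ann.iterrows():
            assert row.protein_annotation == reported[row.strain_id]
        assert not tallies["row_errors"]
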