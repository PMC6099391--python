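"""Genotype parsing, type assignment, census, and cross feasibility."""

from itertools import combinations_with_replacement, product

import pytest

from codonits import genotyping as gt
from codonits import synthetic_data as sd


class TestSiteGenotype:
    def test_parse_plain_and_ambiguous(self):
        g = gt.parse_genotype(122, "C")
        assert (g.composition, g.major, g.iupac) == (frozenset("C"), None, "C")
        g = gt.parse_genotype(122, "Y")
        assert g.composition == frozenset("CT") and g.major is None

    def test_parse_orientation(self):
        g = gt.parse_genotype(122, "Y:T>C")
        assert (g.major, g.minor, str(g)) == ("T", "C", "Y(T>C)")

    def test_orientation_must_match_code(self):
        with pytest.raises(ValueError, match="inconsistent"):
            gt.parse_genotype(122, "Y:A>G")

    def test_major_outside_composition_rejected(self):
        with pytest.raises(ValueError, match="major"):
            gt.SiteGenotype(1, frozenset("CT"), major="G")

    def test_three_base_composition_rejected(self):
        with pytest.raises(ValueError):
            gt.SiteGenotype(1, frozenset("ACG"))


class TestTypeRegistry:
    def test_thirteen_types_split_into_pure_and_cultivar(self):
        assert len(gt.TYPE_DEFS) == 13
        assert set(gt.PURE_LINES) == {"P0", "PM0", "T0", "S0"}
        assert len(gt.CULTIVAR_TYPES) == 9

    def test_pure_lines_are_homozygous_cultivars_are_not(self):
        assert all(t.is_pure_line for t in gt.PURE_LINES.values())
        assert all(t.heterozygous for t in gt.CULTIVAR_TYPES.values())

    def test_specimen_counts_total_46(self):
        assert sum(t.specimen_count or 0
                   for t in gt.CULTIVAR_TYPES.values()) == 46
        assert gt.CULTIVAR_TYPES["P1"].specimen_count == 33


class TestGenotypeVariableSites:
    def test_homozygous_baseline(self, type_sequences):
        genos = gt.genotype_variable_sites(type_sequences["P0"])
        assert [g.position for g in genos] == [122, 135, 226, 500]
        assert all(not g.heterozygous for g in genos)

    def test_hybrid_sequence_reports_ambiguity(self, type_sequences):
        genos = {g.position: g
                 for g in gt.genotype_variable_sites(type_sequences["PM2"])}
        assert genos[226].composition == frozenset("CT")
        assert genos[122].composition == frozenset("T")

    def test_extra_ambiguity_outside_canonical_sites_reported(self, reference):
        seq = reference[:299] + "R" + reference[300:]
        positions = [g.position for g in gt.genotype_variable_sites(seq)]
        assert positions == [122, 135, 226, 300, 500]

    def test_majors_attach_orientation(self, type_sequences):
        genos = {g.position: g for g in gt.genotype_variable_sites(
            type_sequences["P1"], majors={122: "T", 226: "C"})}
        assert genos[122].major == "T" and genos[226].major == "C"

    def test_out_of_range_position(self, reference):
        with pytest.raises(ValueError, match="outside"):
            gt.genotype_variable_sites(reference, positions=(9999,))


class TestAssignType:
    def assign_seq(self, label, type_sequences, majors=None):
        tdef = gt.TYPE_DEFS[label]
        genos = gt.genotype_variable_sites(type_sequences[label],
                                           majors=majors)
        canonical = {g.position: g for g in genos
                     if g.position in gt.VARIABLE_SITES}
        return gt.assign_type(tdef.species_context, canonical)

    @pytest.mark.parametrize("label", ["P0", "PM0", "T0", "S0", "P2", "P5",
                                       "PM1", "PM2", "PM3", "T1"])
    def test_unambiguous_round_trip_without_orientation(self, label,
                                                        type_sequences):
        assert self.assign_seq(label, type_sequences) == label

    @pytest.mark.parametrize("label,majors", [
        ("P1", {122: "T", 226: "C"}),
        ("P3", {122: "T", 226: "T"}),
        ("P4", {122: "C", 226: "C"}),
    ])
    def test_double_het_pilosula_types_need_orientation(self, label, majors,
                                                        type_sequences):
        with pytest.raises(ValueError, match="orientation"):
            self.assign_seq(label, type_sequences)
        assert self.assign_seq(label, type_sequences, majors=majors) == label

    def test_species_context_separates_shared_compositions(self):
        # Y at 122, plain elsewhere: P5 in one taxon, PM3 in its variety
        genos = {122: gt.parse_genotype(122, "Y"),
                 135: gt.parse_genotype(135, "G"),
                 226: gt.parse_genotype(226, "C"),
                 500: gt.parse_genotype(500, "G")}
        assert gt.assign_type(gt.SPECIES_PILOSULA, genos) == "P5"
        assert gt.assign_type(gt.SPECIES_MODESTA, genos) == "PM3"

    def test_unmatched_genotype_is_novel(self):
        genos = {122: gt.parse_genotype(122, "G"),
                 135: gt.parse_genotype(135, "G"),
                 226: gt.parse_genotype(226, "C"),
                 500: gt.parse_genotype(500, "G")}
        assert gt.assign_type(gt.SPECIES_PILOSULA, genos) == "novel"

    def test_incomplete_genotype_rejected(self):
        with pytest.raises(ValueError, match="positions"):
            gt.assign_type(gt.SPECIES_PILOSULA,
                           {122: gt.parse_genotype(122, "C")})


class TestCensus:
    def test_pilosula_and_modesta_fully_heterozygous(self, panel):
        census = gt.census_heterozygosity(panel)
        assert census["total"] == 46
        assert census["heterozygous_by_species"][gt.SPECIES_PILOSULA] == 39
        assert census["heterozygous_by_species"][gt.SPECIES_MODESTA] == 6
        non_tangshen_het = sum(v for k, v in
                               census["heterozygous_by_species"].items()
                               if k != gt.SPECIES_TANGSHEN)
        non_tangshen_total = sum(v for k, v in
                                 census["total_by_species"].items()
                                 if k != gt.SPECIES_TANGSHEN)
        assert (non_tangshen_het, non_tangshen_total) == (45, 45)

    def test_unknown_type_label_raises(self, panel):
        bad = panel.copy()
        bad.loc[0, "its_type"] = "ZZ"
        with pytest.raises(KeyError, match="ZZ"):
            gt.census_heterozygosity(bad)


class TestCrossFeasibility:
    def test_intermediate_by_line_gives_target(self):
        hyp = gt.cross_feasible(gt.TYPE_DEFS["PM2"], gt.TYPE_DEFS["P0"],
                                gt.TYPE_DEFS["P1"])
        assert hyp.feasible
        assert hyp.explanation[122] == ("T", "C")

    def test_pm3_by_s0_gives_p1(self):
        assert gt.cross_feasible(gt.TYPE_DEFS["PM3"], gt.TYPE_DEFS["S0"],
                                 gt.TYPE_DEFS["P1"]).feasible

    def test_selfed_line_cannot_give_hybrid(self):
        hyp = gt.cross_feasible(gt.TYPE_DEFS["S0"], gt.TYPE_DEFS["S0"],
                                gt.TYPE_DEFS["P1"])
        assert not hyp.feasible and hyp.explanation == {}

    def test_agrees_with_gamete_product_oracle(self):
        # brute force: a pair is feasible iff some gamete combination
        # reproduces the target composition at every site simultaneously
        for target in gt.TYPE_DEFS.values():
            for a, b in combinations_with_replacement(sorted(gt.PURE_LINES), 2):
                pa, pb = gt.TYPE_DEFS[a], gt.TYPE_DEFS[b]
                oracle = all(
                    any(frozenset({ga, gb}) == target.genotypes[pos].composition
                        for ga, gb in product(pa.genotypes[pos].composition,
                                              pb.genotypes[pos].composition))
                    for pos in gt.VARIABLE_SITES)
                assert gt.cross_feasible(pa, pb, target).feasible == oracle


class TestLineageInference:
    EXPECTED = {
        "P1": {frozenset({"P0", "S0"})},
        "P3": {frozenset({"P0", "S0"})},
        "P4": {frozenset({"P0", "S0"})},
        "PM1": {frozenset({"P0", "S0"})},
        "P5": {frozenset({"P0", "PM0"})},
        "PM3": {frozenset({"P0", "PM0"})},
        "PM2": {frozenset({"PM0", "S0"})},
        "P2": set(),
        "T1": set(),
    }

    @pytest.mark.parametrize("label", sorted(EXPECTED))
    def test_single_cross_table(self, label):
        assert gt.infer_single_cross(gt.TYPE_DEFS[label]) == self.EXPECTED[label]

    def test_heterozygous_line_input_rejected(self):
        with pytest.raises(ValueError, match="homozygous"):
            gt.infer_single_cross(gt.TYPE_DEFS["P1"],
                                  lines={"P1": gt.TYPE_DEFS["P1"]})

    def test_two_step_contains_both_documented_chains(self):
        chains = gt.enumerate_two_step(gt.TYPE_DEFS["P1"])
        assert (frozenset({"S0", "PM0"}), "PM2", "P0") in chains
        assert (frozenset({"P0", "PM0"}), "PM3", "S0") in chains

    def test_two_step_chains_are_sound(self):
        for first, inter, second in gt.enumerate_two_step(gt.TYPE_DEFS["P1"]):
            assert first in gt.infer_single_cross(gt.TYPE_DEFS[inter])
            assert gt.cross_feasible(gt.TYPE_DEFS[inter],
                                     gt.TYPE_DEFS[second],
                                     gt.TYPE_DEFS["P1"]).feasible

    def test_homozygous_target_needs_no_chain(self):
        assert gt.enumerate_two_step(gt.TYPE_DEFS["P0"]) == []

    def test_orphan_type_gets_hypothetical_parent(self):
        hypos = gt.hypothetical_missing_parent(gt.TYPE_DEFS["P2"])
        assert hypos == [({122: "C", 135: "G", 226: "T", 500: "G"}, "P0")]
        # the implied partner is itself a plausible unsampled pure line:
        # its cross with P0 reproduces P2 exactly
        partner, line = hypos[0]
        for pos in gt.VARIABLE_SITES:
            want = gt.TYPE_DEFS["P2"].genotypes[pos].composition
            (allele,) = gt.TYPE_DEFS[line].genotypes[pos].composition
            assert frozenset({allele, partner[pos]}) == want


class TestGenotypesFromTraces:
    def render_pairs(self, label, reference, params, n=3, fractions=None):
        rng = params.rng()
        return [sd.render_type_traces(label, reference,
                                      site_fractions=fractions or {},
                                      params=params, rng=rng)
                for _ in range(n)]

    def test_hybrid_type_recovered(self, reference, params):
        pairs = self.render_pairs("P1", reference, params,
                                  fractions={122: 0.33, 226: 0.47})
        genos, decisions = gt.genotypes_from_trace_replicates(pairs)
        assert genos[122].composition == frozenset("CT")
        assert genos[122].major == "T"  # published orientation for P1
        assert genos[226].major == "C"
        assert all(d.confirmed for d in decisions.values())
        canonical = {p: g for p, g in genos.items() if p in gt.VARIABLE_SITES}
        assert gt.assign_type(gt.SPECIES_PILOSULA, canonical) == "P1"

    def test_pure_line_yields_no_candidates(self, reference, params):
        pairs = self.render_pairs("P0", reference, params)
        genos, decisions = gt.genotypes_from_trace_replicates(pairs)
        assert decisions == {}
        assert all(not g.heterozygous for g in genos.values())

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            gt.genotypes_from_trace_replicates([])
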