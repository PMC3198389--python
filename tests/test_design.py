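"""Primer and fragment design against synthetic plasmids.

The reference fixture embeds the exact local contexts implied by the
published five-site order sheet, so designed primers can be compared to
the printed sequences character for character.
"""

import math
import re

import pytest

from satmut.io import load_reference_primers
from satmut.seqcore import CircularSeq, DegenerateCodon, NNK, reverse_complement
from satmut.design import (
    DesignConfig,
    DesignError,
    ProximityError,
    TargetSite,
    design_forward_primer,
    design_reverse_primer,
    gc_content,
    locate_target_codons,
    make_junction,
    melting_temperature,
    plan_fragments,
    subset_design,
    validate_design,
)

# ---------------------------------------------------------------------------
# independent nearest-neighbor Tm oracle: unified duplex parameter table,
# monovalent-salt entropy correction, excess-primer two-state model
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def oracle_tm_nn(seq: str, na_mM: float = 50.0, oligo_nM: float = 400.0) -> float:
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(oligo_nM * 1e-9)) - 273.15


class TestMeltingTemperature:
    def test_wallace_rule(self):
        assert melting_temperature("ATGC", method="wallace") == 12.0

    @pytest.mark.parametrize(
        "seq",
        ["CAAAGTGTAACCCGTC", "TTGAGCCGCCATG", "GTGATTATTTCCG", "CATCTGGGCAAATG",
         "ACGCGTTTAAACGGCATCAG"],
    )
    def test_nearest_neighbor_matches_independent_oracle(self, seq):
        assert melting_temperature(seq) == pytest.approx(oracle_tm_nn(seq), abs=0.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("")

    def test_degenerate_rejected_for_nearest_neighbor(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGNNK")


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_concrete(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_degenerate_matches_brute_force_expansion(self):
        exact = sum(sum(b in "GC" for b in c) / 3 for c in NNK.expand()) / NNK.size
        assert gc_content("NNK") == pytest.approx(exact)
        assert gc_content("NNK") == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestLocateTargetCodons:
    def test_synthetic_orf_coordinates(self):
        plasmid = CircularSeq("TTTT" + "ATGGAGAAATGA" + "CCCC")
        [site] = locate_target_codons(plasmid, 4, [2])
        assert site.wt_codon == "GAG"
        assert site.codon_start == 7
        assert site.label == "E2"

    def test_duplicate_indices_rejected(self):
        plasmid = CircularSeq("TTTTATGGAGAAATGACCCC")
        with pytest.raises(DesignError, match="duplicate"):
            locate_target_codons(plasmid, 4, [2, 2])

    def test_index_beyond_orf_rejected(self):
        plasmid = CircularSeq("TTTTATGGAGAAATGACCCC")
        with pytest.raises(DesignError, match="beyond"):
            locate_target_codons(plasmid, 4, [9], orf_len=12)

    def test_minus_strand_orf(self):
        core = "ATGGAGAAA"
        plasmid = CircularSeq("TT" + reverse_complement(core) + "GGGG")
        coding_start = len(plasmid) - 2 - len(core)  # on the reverse-complement view
        [site] = locate_target_codons(plasmid, coding_start, [2], orf_strand="-")
        assert site.wt_codon == "GAG"

    def test_reference_fixture_sites_in_template_order(self, ref):
        labels = [s.label for s in ref.sites]
        assert labels == ["E31", "T77", "K139", "G187", "V298"]
        assert [s.wt_codon for s in ref.sites] == ["GAG", "ACA", "AAA", "GGT", "GTG"]


class TestJunctions:
    def test_reference_linkers(self, ref):
        by_label = {s.label: s for s in ref.sites}
        assert make_junction(ref.plasmid, by_label["E31"], 12).linker == "CGAGTGGTTATC"
        assert make_junction(ref.plasmid, by_label["T77"], 13).linker == "GGCGGCTTCTATG"
        assert make_junction(ref.plasmid, by_label["K139"], 13).linker == "GATCCACTGTTTC"

    def test_invalid_pto_length(self, ref):
        with pytest.raises(DesignError):
            make_junction(ref.plasmid, ref.sites[0], 11)


class TestPrimerDesign:
    def test_reverse_primer_reproduces_printed_row(self, ref):
        site = next(s for s in ref.sites if s.label == "E31")
        junction = make_junction(ref.plasmid, site, 12)
        primer = design_reverse_primer(ref.plasmid, site, junction, anneal_len=16)
        assert primer.render() == "gataaccactcgMNNCAAAGTGTAACCCGTC"
        assert primer.pto_bond_count == 12

    def test_forward_primer_reproduces_printed_row(self, ref):
        site = next(s for s in ref.sites if s.label == "E31")
        junction = make_junction(ref.plasmid, site, 12)
        primer = design_forward_primer(ref.plasmid, junction, anneal_len=13, name="T77_Fw")
        assert primer.render() == "cgagtggttatcTTGAGCCGCCATG"

    def test_offset_spacer_rides_on_reverse_primer(self, ref):
        site = next(s for s in ref.sites if s.label == "T77")
        junction = make_junction(ref.plasmid, site, 13)
        primer = design_reverse_primer(ref.plasmid, site, junction, anneal_len=12)
        assert primer.render() == "catagaagccgccCATCAGMNNCACTAATTGCGC"

    def test_nnn_scheme_segment(self, ref):
        site0 = next(s for s in ref.sites if s.label == "E31")
        site = TargetSite(site0.label, site0.aa_index, site0.codon_start,
                          site0.wt_codon, DegenerateCodon("NNN"), site0.linker_offset)
        junction = make_junction(ref.plasmid, site, 12)
        primer = design_reverse_primer(ref.plasmid, site, junction, anneal_len=16)
        assert primer.degenerate_segment == "NNN"

    def test_anneal_extension_reaches_tm_window(self, small_fixture_factory):
        fx = small_fixture_factory(seed=11)
        cfg = DesignConfig()
        for plan in fx.default_plan(cfg):
            for primer in (plan.fwd_primer, plan.rev_primer):
                assert cfg.min_anneal <= len(primer.anneal3p) <= cfg.max_anneal
                # the extension stops once the window is reached; an AT-rich
                # context may exhaust max_anneal first (reported as a warning)
                assert (primer.tm_c >= cfg.tm_target - cfg.tm_window
                        or len(primer.anneal3p) == cfg.max_anneal)


class TestFragmentPlanning:
    def test_five_sites_five_fragments(self, ref, ref_plans):
        assert len(ref_plans) == 5
        assert [p.fragment_id for p in ref_plans] == ["vector", "B", "C", "D", "E"]
        assert sum(p.wraps_origin for p in ref_plans) == 1

    def test_junction_complementarity_between_consecutive_fragments(self, ref_plans):
        for prev, nxt in zip(ref_plans, ref_plans[1:] + ref_plans[:1]):
            assert reverse_complement(prev.rev_primer.pto_tail) == nxt.fwd_primer.pto_tail

    def test_primer_pattern_invariant(self, ref_plans):
        fwd_pat = re.compile(r"^[acgt]{12,13}[ACGT]{12,}$")
        rev_pat = re.compile(r"^[acgt]{12,13}[ACGT]*MNN[ACGT]{12,}$")
        for p in ref_plans:
            assert fwd_pat.match(p.fwd_primer.render())
            assert rev_pat.match(p.rev_primer.render())

    def test_fragment_lengths_tile_the_plasmid(self, ref, ref_plans):
        overlaps = sum(len(p.fwd_primer.pto_tail) for p in ref_plans)
        assert sum(p.expected_length_bp for p in ref_plans) - overlaps == len(ref.plasmid)

    def test_single_site_whole_plasmid_amplicon(self, ref):
        [site] = [s for s in ref.sites if s.label == "E31"]
        [plan] = plan_fragments(ref.plasmid, [site], DesignConfig(), ref.anneal_lengths)
        assert plan.expected_length_bp == len(ref.plasmid) + 12

    def test_two_sites_two_fragments(self, ref):
        chosen = [s for s in ref.sites if s.label in ("E31", "K139")]
        plans = plan_fragments(ref.plasmid, chosen, DesignConfig(), ref.anneal_lengths)
        assert len(plans) == 2

    def test_adjacent_codons_raise_proximity_error(self):
        # two target codons 6 bp apart: the second's annealing region would
        # run over the first codon
        orf = "ATG" + "GAGAAATTTGGG" * 20
        plasmid = CircularSeq("ACGTACGTCC" * 8 + orf + "TTGGCCAACC" * 8)
        sites = locate_target_codons(plasmid, 80, [5, 7])
        with pytest.raises(ProximityError, match="multi-codon"):
            plan_fragments(plasmid, sites, DesignConfig())


class TestSubsetDesign:
    def test_identity_subset(self, ref, ref_plans):
        out = subset_design(ref.plasmid, ref_plans, list(ref.sites),
                            anneal_lengths=ref.anneal_lengths)
        assert len(out.plans) == 5
        assert not out.new_primers
        assert {p.rev_primer.name for p in out.plans} == {p.rev_primer.name for p in ref_plans}

    def test_four_site_sublibrary(self, ref, ref_plans):
        chosen = [s for s in ref.sites if s.label != "E31"]
        out = subset_design(ref.plasmid, ref_plans, chosen, anneal_lengths=ref.anneal_lengths)
        assert len(out.plans) == 4
        assert not out.new_primers  # the published oligo set suffices

    def test_single_site_subset(self, ref, ref_plans):
        [site] = [s for s in ref.sites if s.label == "E31"]
        out = subset_design(ref.plasmid, ref_plans, [site], anneal_lengths=ref.anneal_lengths)
        assert len(out.plans) == 1

    def test_new_near_neighbour_site_needs_one_new_primer_pair(self, ref, ref_plans):
        t77 = next(s for s in ref.sites if s.label == "T77")
        out = subset_design(ref.plasmid, ref_plans, [ref.sublibrary_site, t77],
                            anneal_lengths=ref.anneal_lengths)
        assert sorted(out.new_primers) == ["D52_Rv", "T77_Fw'"]
        assert sorted(out.reused_primers) == ["K139_Fw", "T77_Rv"]
        rendered = {p.rev_primer.name: p.rev_primer.render() for p in out.plans}
        rendered.update({p.fwd_primer.name: p.fwd_primer.render() for p in out.plans})
        sheet = load_reference_primers().set_index("name")["sequence"]
        assert rendered["D52_Rv"] == sheet["D52_Rv"]
        assert rendered["T77_Fw'"] == sheet["T77_Fw'"]

    def test_empty_subset_rejected(self, ref, ref_plans):
        with pytest.raises(DesignError):
            subset_design(ref.plasmid, ref_plans, [])


class TestValidateDesign:
    def test_reference_design_has_no_errors(self, ref_plans):
        report = validate_design(ref_plans)
        assert report.is_valid

    def test_wildtype_not_encodable_is_reported(self, ref_plans):
        report = validate_design(ref_plans)
        notes = [i for i in report.issues if i.code == "wt-not-encodable"]
        # T77 (ACA) and K139 (AAA) wild types end in A, outside the NNK expansion
        assert {n.message.split(":")[0] for n in notes} == {"T77", "K139"}

    def test_identical_downstream_contexts_collide(self):
        ctx = "GGCCAATTGGCC"
        filler = "CCATTGCCAGCATTACCGCATCAGGCATTACCGGTTACTGCATCAGGCATTACC"[:54]
        orf = ("ATG" + "GAA" + ctx + filler + "GAA" + ctx
               + "TTACCGGTTACTGCATCAGGCAAAACCCGGGTTTAAACCCGGG")
        plasmid = CircularSeq("ACGGTTCAGGTCCAGGAACCTTGGAACTCAGG" * 4 + orf
                              + "TGCCAAGGTTCCAAGGCAGGTTGGCCAATTCC" * 4)
        sites = locate_target_codons(plasmid, 128, [2, 25])
        plans = plan_fragments(plasmid, sites, DesignConfig())
        report = validate_design(plans)
        assert any(i.code == "linker-collision" for i in report.errors)

    def test_palindromic_linker_flagged(self):
        pal = "GGATCCGGATCC"  # reverse complement of itself
        orf = "ATG" + "GAA" + pal + "CCATTGACCGCATTACCGCATCAGG"
        plasmid = CircularSeq("ACGGTTCAGGTCCAGGAACCTTGGAACTCAGG" * 4 + orf
                              + "TGCCAAGGTTCCAAGGCAGGTTGGCCAATTCC" * 4)
        sites = locate_target_codons(plasmid, 128, [2])
        plans = plan_fragments(plasmid, sites, DesignConfig())
        report = validate_design(plans)
        assert any(i.code == "palindromic-linker" for i in report.errors)
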