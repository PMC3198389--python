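"""PCR, iodine cleavage and overhang hybridization simulation."""

import dataclasses

import numpy as np
import pytest

from satmut.seqcore import CircularSeq, reverse_complement
from satmut.design import make_junction
from satmut.assembly import (
    AssemblyError,
    CleavedFragment,
    DsFragment,
    NonSpecificPrimingError,
    amplify,
    amplify_plan,
    detect_self_circularization,
    hybridize,
    iodine_cleave,
    reconstruct_product,
    run_assembly,
    wildtype_assignment,
)
from satmut.clone_qc import QcSite, extract_site_codons, CloneRecord
from satmut.diversity import sample_codons


@pytest.fixture(scope="module")
def cleaved(ref, ref_plans):
    return [iodine_cleave(f) for f in amplify_plan(ref.plasmid, ref_plans)]


class TestAmplify:
    def test_product_lengths_match_plan(self, ref, ref_plans):
        for plan in ref_plans:
            frag = amplify(ref.plasmid, plan.fwd_primer, plan.rev_primer)
            assert len(frag) == plan.expected_length_bp

    def test_total_length_minus_overlaps_is_plasmid_length(self, ref, ref_plans):
        frags = amplify_plan(ref.plasmid, ref_plans)
        overlaps = sum(f.pto_bottom for f in frags)
        assert sum(len(f) for f in frags) - overlaps == len(ref.plasmid)

    def test_degenerate_codon_imprinted(self, ref, ref_plans):
        plan = next(p for p in ref_plans if p.fragment_id == "B")
        frag = amplify(ref.plasmid, plan.fwd_primer, plan.rev_primer,
                       site_label=plan.site.label)
        [d] = frag.degenerate_positions
        assert frag.top_strand[d.offset : d.offset + 3] == "NNK"

    def test_scrambled_anneal_region_is_nonspecific(self, ref, ref_plans):
        plan = ref_plans[1]
        bad = dataclasses.replace(plan.fwd_primer, anneal3p="GCGCGCATATGCGC")
        with pytest.raises(NonSpecificPrimingError):
            amplify(ref.plasmid, bad, plan.rev_primer)


class TestIodineCleave:
    def test_overhangs_equal_designed_linkers(self, ref, ref_plans, cleaved):
        junctions = {s.label: make_junction(ref.plasmid, s, s.pto_len or 12)
                     for s in ref.sites}
        for plan, cf in zip(ref_plans, cleaved):
            # right overhang: this site's linker on the top strand
            assert cf.right_overhang == junctions[plan.site.label].linker
            # left overhang: reverse complement of the previous site's linker
            assert cf.left_overhang == reverse_complement(cf.parent.top_strand[: cf.parent.pto_top])

    def test_overhang_lengths_equal_pto_counts(self, cleaved):
        for cf in cleaved:
            assert len(cf.left_overhang) == cf.parent.pto_top
            assert len(cf.right_overhang) == cf.parent.pto_bottom

    def test_conservation_of_tracked_bases(self, cleaved):
        for cf in cleaved:
            assert (len(cf.core_top) + cf.parent.pto_top + cf.parent.pto_bottom
                    == len(cf.parent))

    def test_idempotent(self, cleaved):
        for cf in cleaved:
            assert iodine_cleave(cf) is cf

    def test_blunt_fragment_warns(self):
        frag = DsFragment("x", "ACGTACGTACGTACGT", 0, 0)
        with pytest.warns(UserWarning, match="blunt"):
            cf = iodine_cleave(frag)
        assert cf.blunt and not cf.left_overhang and not cf.right_overhang


class TestHybridize:
    def test_five_fragments_circularize_with_ten_nicks(self, cleaved):
        result = hybridize(cleaved)
        assert result.is_circular
        assert result.nick_count == 10
        assert result.order == ("B", "C", "D", "E", "vector")

    def test_order_independent(self, cleaved):
        rng = np.random.default_rng(5)
        for _ in range(5):
            perm = list(cleaved)
            rng.shuffle(perm)
            assert hybridize(perm) == hybridize(cleaved)

    def test_two_fragment_sublibrary_has_four_nicks(self, ref, ref_plans):
        from satmut.design import subset_design

        chosen = [s for s in ref.sites if s.label in ("T77", "V298")]
        sub = subset_design(ref.plasmid, ref_plans, chosen, anneal_lengths=ref.anneal_lengths)
        result, _ = run_assembly(ref.plasmid, sub.plans)
        assert result.is_circular and result.nick_count == 4

    def test_mutated_linker_yields_incomplete_assembly(self, cleaved):
        broken = list(cleaved)
        cf = broken[0]
        bad = CleavedFragment(cf.parent, cf.left_overhang,
                              "A" * len(cf.right_overhang), cf.blunt)
        broken[0] = bad
        result = hybridize(broken)
        assert not result.is_circular
        assert len(result.unmatched) == 2

    def test_shared_overhang_text_sets_ambiguity_flag(self, cleaved):
        dup = list(cleaved)
        cf = dup[0]
        # second fragment whose left overhang matches fragment 0's right one
        clone = CleavedFragment(
            dataclasses.replace(dup[1].parent, fragment_id="dup"),
            dup[1].left_overhang, dup[1].right_overhang)
        dup.append(clone)
        result = hybridize(dup)
        assert result.ambiguous and not result.is_circular


class TestSelfCircularization:
    def test_designed_fragments_do_not_self_circularize(self, cleaved):
        assert not any(detect_self_circularization(cf) for cf in cleaved)

    def test_identical_end_linkers_self_circularize(self):
        link = "GGCCAATTCCGG"
        top = link + "ACGTACGTACGTACGTACGTACGT" + link
        frag = DsFragment("x", top, 12, 12)
        assert detect_self_circularization(iodine_cleave(frag))

    def test_blunt_fragment_does_not(self):
        frag = DsFragment("x", "ACGTACGTACGTACGT", 0, 0)
        with pytest.warns(UserWarning):
            assert not detect_self_circularization(iodine_cleave(frag))


class TestReconstruct:
    def test_wildtype_assignment_roundtrips_to_template(self, ref, ref_plans, cleaved):
        result = hybridize(cleaved)
        product = reconstruct_product(result, cleaved, wildtype_assignment(ref_plans))
        assert product.same_circle(ref.plasmid)

    def test_mutant_assignment_differs_only_at_assigned_codons(self, ref, ref_plans, cleaved):
        result = hybridize(cleaved)
        assignment = wildtype_assignment(ref_plans)
        assignment["E31"] = "TAT"
        product = reconstruct_product(result, cleaved, assignment)
        # align rotations and count substitutions
        anchor = ref.plasmid.bases[:40]
        offset = (product.bases + product.bases).index(anchor)
        rotated = product.rotated(offset)
        diffs = [i for i, (a, b) in enumerate(zip(ref.plasmid.bases, rotated.bases)) if a != b]
        e31 = next(s for s in ref.sites if s.label == "E31")
        assert set(diffs) <= {e31.codon_start, e31.codon_start + 1, e31.codon_start + 2}
        assert rotated.slice(e31.codon_start, 3) == "TAT"

    def test_missing_assignment_is_an_error(self, ref_plans, cleaved):
        result = hybridize(cleaved)
        with pytest.raises(AssemblyError, match="no codon assigned"):
            reconstruct_product(result, cleaved, {})

    def test_incomplete_assembly_cannot_be_reconstructed(self, cleaved):
        result = hybridize(cleaved[:3])
        assert not result.is_circular
        with pytest.raises(AssemblyError):
            reconstruct_product(result, cleaved[:3], {})

    def test_random_assignments_feed_clone_qc(self, ref, ref_plans, cleaved):
        """48 random scheme draws -> 48 clones whose site codons read back."""
        result = hybridize(cleaved)
        labels = [p.site.label for p in ref_plans]
        qc_sites = [
            QcSite(s.label, s.aa_index, s.wt_codon, s.scheme) for s in ref.sites
        ]
        gene_len = 3 * ref.spec.orf_codons
        anchor = ref.plasmid.bases[:40]
        draws = sample_codons(ref.sites[0].scheme, len(labels), 48, rng=123)
        for i, draw in enumerate(draws):
            product = reconstruct_product(result, cleaved, dict(zip(labels, draw)))
            offset = (product.bases + product.bases).index(anchor)
            gene = product.rotated(offset).slice(ref.orf_start, gene_len)
            calls = extract_site_codons(CloneRecord(f"c{i}", gene),
                                        ref.plasmid.slice(ref.orf_start, gene_len),
                                        qc_sites)
            assert [c.observed_codon for c in calls] == list(draw)
            assert all(c.in_scheme for c in calls)


class TestFullPipelineProperty:
    def test_roundtrip_identity_on_random_fixtures(self, small_fixture_factory):
        for seed in range(25):
            fx = small_fixture_factory(seed=seed)
            plans = fx.default_plan()
            result, cleaved = run_assembly(fx.plasmid, plans)
            assert result.is_circular
            assert result.nick_count == 2 * len(plans)
            product = reconstruct_product(result, cleaved, wildtype_assignment(plans))
            assert product.same_circle(fx.plasmid)
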