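"""Synthetic plasmid fixtures for design, assembly and QC testing.

Two kinds of fixture are produced:

* a *random* plasmid with an embedded ORF and well-separated target codons,
  designable under the default constraints — for property testing; and
* the *reference* plasmid, which embeds the exact local sequence contexts
  implied by the published ten-oligo order sheet for the five-site phytase
  library (plus the extra near-neighbour site used for the two-site
  sub-library), so that the designer reproduces that primer set verbatim.

Both are deterministic in the seed.  The synthetic plasmids emulate a
small expression vector with one ORF; they do not reproduce real vector
elements, codon usage or the true gene's sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import NNK, CircularSeq, DegenerateCodon, STANDARD_CODE, reverse_complement
from itertools import product as _product

from .design import (
    DesignConfig,
    DesignError,
    FragmentPlan,
    ProximityError,
    TargetSite,
    locate_target_codons,
    plan_fragments,
    validate_design,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "SiteContext",
    "REFERENCE_CONTEXTS",
    "REFERENCE_SUBLIBRARY_CONTEXT",
    "REFERENCE_SPEC",
    "generate_fixture",
    "reference_fixture",
]


@dataclass(frozen=True)
class SiteContext:
    """Exact local template context around one target codon (coding strand):
    [up_anneal][codon][spacer][linker][down_anneal].  up_anneal is the
    region the site's reverse primer anneals to (reverse-complemented on
    the primer); down_anneal is where the next fragment's forward primer
    anneals, immediately 3' of the linker."""

    aa_index: int
    wt_codon: str
    up_anneal: str
    spacer: str
    linker: str
    down_anneal: str

    @property
    def linker_offset(self) -> int:
        return len(self.spacer)

    @property
    def pto_len(self) -> int:
        return len(self.linker)

    def render(self) -> str:
        return self.up_anneal + self.wt_codon + self.spacer + self.linker + self.down_anneal

    @property
    def start_rel_codon(self) -> int:
        return -len(self.up_anneal)


# Local contexts reconstructed from the published five-site order sheet:
# each reverse primer is the reverse complement of
# up_anneal + codon + spacer + linker, and each forward primer reads
# linker + down_anneal of the *previous* site in template order.
REFERENCE_CONTEXTS: tuple[SiteContext, ...] = (
    SiteContext(31, "GAG", "GACGGGTTACACTTTG", "", "CGAGTGGTTATC", "TTGAGCCGCCATG"),
    SiteContext(77, "ACA", "GCGCAATTAGTG", "CTGATG", "GGCGGCTTCTATG", "GTGATTATTTCCG"),
    SiteContext(139, "AAA", "CAGGCTGATTTG", "AAGGTT", "GATCCACTGTTTC", "ACCCCGTCGAAG"),
    SiteContext(187, "GGT", "CATTTGCCCAGATG", "GAGATT", "CTCAATTTCACTG", "CTTCCCCCTATTGC"),
    SiteContext(298, "GTG", "GTTGCAACAGATT", "ACGGCG", "CTAGTGCTTCAG", "CGTAAGGGGCAAG"),
)

# The additional site sitting <100 bp upstream of residue 77, used to build
# the two-site sub-library with a single fresh forward primer.
REFERENCE_SUBLIBRARY_CONTEXT = SiteContext(
    52, "GAT", "CAGAGTTAATGAAT", "GTCACA", "CCGGATAAGTGG", "CCTCAATGGCCGGTAC"
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic circular plasmid with an embedded ORF.

    Defaults mirror the published study layout at desk scale: a ~2.3 kb
    plasmid, a ~0.9 kb ORF and five target residues (31, 77, 139, 187,
    298), one pair of which (52/77, when include_sublibrary_site is set)
    lies under 100 bp apart.
    """

    plasmid_length: int = 2300
    orf_start: int = 650
    orf_codons: int = 300
    aa_indices: tuple[int, ...] = (31, 77, 139, 187, 298)
    scheme: DegenerateCodon = NNK
    gc_fraction: float = 0.5
    contexts: tuple[SiteContext, ...] | None = None  # pin exact local contexts
    include_sublibrary_site: bool = False

    def __post_init__(self) -> None:
        if 3 * max(self.aa_indices) > 3 * self.orf_codons:
            raise ValueError("ORF too short for the requested residue indices")
        if self.orf_start + 3 * self.orf_codons > self.plasmid_length:
            # the ORF itself may not wrap the origin; the vector backbone does
            raise ValueError("ORF must fit without wrapping the origin")


@dataclass(frozen=True)
class Fixture:
    """A generated plasmid plus everything needed to design against it."""

    plasmid: CircularSeq
    orf_start: int
    sites: list[TargetSite]
    spec: FixtureSpec
    anneal_lengths: dict[str, int] = field(default_factory=dict)
    sublibrary_site: TargetSite | None = None

    @property
    def gene_region(self) -> str:
        """The ORF sequence (coding strand)."""
        return self.plasmid.slice(self.orf_start, 3 * self.spec.orf_codons)

    def default_plan(self, config: DesignConfig = DesignConfig()) -> list[FragmentPlan]:
        return plan_fragments(self.plasmid, self.sites, config, self.anneal_lengths)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=probs))


def generate_fixture(spec: FixtureSpec = FixtureSpec(), seed: int = 0) -> Fixture:
    """Deterministically generate a plasmid satisfying `spec`.

    With pinned contexts the exact local sequences are written around each
    target codon; otherwise random local contexts arise and only the target
    codons themselves are forced to encode a sense residue.  The generator
    retries a handful of sub-seeds until the design validates (distinct,
    non-palindromic linkers and unique primer sites) and fails loudly if
    the spec admits no valid design.
    """
    last_err: Exception | None = None
    for attempt in range(8):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        try:
            return _generate_once(spec, rng)
        except ProximityError:
            raise  # geometry problem: no amount of resampling will fix it
        except DesignError as e:
            last_err = e
    raise DesignError(f"fixture spec admits no valid design after 8 attempts: {last_err}")


def _generate_once(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    n = spec.plasmid_length
    seq = _random_bases(rng, n, spec.gc_fraction)

    contexts: dict[int, SiteContext] = {}
    if spec.contexts is not None:
        for ctx in spec.contexts:
            contexts[ctx.aa_index] = ctx
        if spec.include_sublibrary_site:
            contexts[REFERENCE_SUBLIBRARY_CONTEXT.aa_index] = REFERENCE_SUBLIBRARY_CONTEXT

    # force sense (non-stop, non-degenerate) codons at target positions
    sense = [c for c in map("".join, _product("ACGT", repeat=3))
             if not STANDARD_CODE.is_stop(c)]
    targets = list(spec.aa_indices)
    for idx in targets:
        start = spec.orf_start + 3 * (idx - 1)
        seq[start : start + 3] = sense[rng.integers(len(sense))]

    # write pinned contexts last so they win over random fill
    for ctx in contexts.values():
        start = spec.orf_start + 3 * (ctx.aa_index - 1) + ctx.start_rel_codon
        rendered = ctx.render()
        if start < 0 or start + len(rendered) > n:
            raise DesignError("pinned context does not fit on the plasmid")
        seq[start : start + len(rendered)] = list(rendered)

    plasmid = CircularSeq("".join(seq), "circular")
    offsets = {idx: ctx.linker_offset for idx, ctx in contexts.items()}
    sites = locate_target_codons(
        plasmid, spec.orf_start, targets, spec.scheme,
        orf_len=3 * spec.orf_codons, linker_offsets=offsets,
    )
    if contexts:
        sites = [
            TargetSite(
                label=s.label, aa_index=s.aa_index, codon_start=s.codon_start,
                wt_codon=s.wt_codon, scheme=s.scheme,
                linker_offset=s.linker_offset,
                pto_len=contexts[s.aa_index].pto_len if s.aa_index in contexts else None,
            )
            for s in sites
        ]
    anneal_lengths: dict[str, int] = {}
    if contexts:
        anneal_lengths = _reference_anneal_lengths(sites, contexts)
        if spec.include_sublibrary_site and REFERENCE_SUBLIBRARY_CONTEXT.aa_index in contexts:
            ctx = REFERENCE_SUBLIBRARY_CONTEXT
            anneal_lengths[f"D{ctx.aa_index}_Rv"] = len(ctx.up_anneal)
            anneal_lengths["T77_Fw'"] = len(ctx.down_anneal)
    sub_site = None
    if spec.include_sublibrary_site and REFERENCE_SUBLIBRARY_CONTEXT.aa_index in contexts:
        ctx = REFERENCE_SUBLIBRARY_CONTEXT
        [sub_site] = [
            TargetSite(
                label=s.label, aa_index=s.aa_index, codon_start=s.codon_start,
                wt_codon=s.wt_codon, scheme=s.scheme,
                linker_offset=ctx.linker_offset, pto_len=ctx.pto_len,
            )
            for s in locate_target_codons(
                plasmid, spec.orf_start, [ctx.aa_index], spec.scheme,
                linker_offsets={ctx.aa_index: ctx.linker_offset},
            )
        ]

    fixture = Fixture(
        plasmid=plasmid,
        orf_start=spec.orf_start,
        sites=sites,
        spec=spec,
        anneal_lengths=anneal_lengths,
        sublibrary_site=sub_site,
    )
    # a fixture must admit a valid design under default constraints
    plans = fixture.default_plan()
    report = validate_design(plans)
    if not report.is_valid:
        raise DesignError(
            "generated plasmid fails design validation: "
            + "; ".join(i.message for i in report.errors)
        )
    return fixture


def _reference_anneal_lengths(
    sites: list[TargetSite], contexts: dict[int, SiteContext]
) -> dict[str, int]:
    """Pin each primer's annealing length to the pinned context, so the
    designed oligos match the embedded sequences exactly.  The forward
    primer of the fragment carrying site i anneals in the *previous* site's
    down_anneal region."""
    lengths: dict[str, int] = {}
    ordered = sorted((s for s in sites), key=lambda s: s.codon_start)
    for i, s in enumerate(ordered):
        ctx = contexts.get(s.aa_index)
        prev_ctx = contexts.get(ordered[(i - 1) % len(ordered)].aa_index)
        if ctx is not None:
            lengths[f"{s.label}_Rv"] = len(ctx.up_anneal)
        if prev_ctx is not None:
            lengths[f"{s.label}_Fw"] = len(prev_ctx.down_anneal)
    return lengths


#: Spec for the published-context plasmid (verbatim primer reproduction).
REFERENCE_SPEC = FixtureSpec(
    contexts=REFERENCE_CONTEXTS,
    include_sublibrary_site=True,
)


def reference_fixture(seed: int = 0) -> Fixture:
    """The synthetic plasmid carrying the published local contexts; random
    filler elsewhere, deterministic in the seed."""
    return generate_fixture(REFERENCE_SPEC, seed=seed)
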