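"""In-silico chemical-cleavage assembly: PCR, iodine cleavage, hybridization.

Simulates the three in-vitro steps of the ligase-free multi-fragment
protocol: (1) amplification of each fragment with PTO-tailed mutagenic
primers, imprinting the degenerate codon; (2) iodine/ethanol cleavage of
the PTO-bonded 5'-terminal nucleotides of both strands, exposing
single-stranded overhangs; (3) hybridization of all fragments into a
circular construct held together by perfectly complementary 12-13 nt
overhangs, carrying two nicks per junction.  Nick repair (performed by the
host after transformation) is abstracted as seamless, so reconstructing a
wild-type-assigned product returns the template exactly.

Overhangs are modelled as end-labelled single-stranded texts matched by
exact reverse complement; annealing kinetics, partial matches and
polarity bookkeeping beyond the end labels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqcore import (
    CircularSeq,
    DegenerateCodon,
    IUPAC_EXPANSION,
    reverse_complement,
)
from .design import FragmentPlan, MutagenicPrimer

__all__ = [
    "AssemblyError",
    "NonSpecificPrimingError",
    "NoProductError",
    "DsFragment",
    "CleavedFragment",
    "AssemblyResult",
    "amplify",
    "iodine_cleave",
    "hybridize",
    "detect_self_circularization",
    "reconstruct_product",
    "amplify_plan",
    "run_assembly",
    "wildtype_assignment",
]


class AssemblyError(ValueError):
    pass


class NonSpecificPrimingError(AssemblyError):
    """A primer binds the template at zero or multiple positions."""


class NoProductError(AssemblyError):
    """Primer orientation/topology admits no amplicon."""


@dataclass(frozen=True)
class DegeneratePosition:
    """A degenerate codon imprinted in a fragment's top strand."""

    offset: int  # 0-based offset of the codon within the top strand
    scheme: DegenerateCodon
    site_label: str


@dataclass(frozen=True)
class DsFragment:
    """A double-stranded PCR product; bottom strand is implied."""

    fragment_id: str
    top_strand: str
    pto_top: int  # PTO bonds at the top strand 5' end
    pto_bottom: int  # PTO bonds at the bottom strand 5' end
    degenerate_positions: tuple[DegeneratePosition, ...] = ()

    def __post_init__(self) -> None:
        for p in (self.pto_top, self.pto_bottom):
            if p not in (0, 12, 13):
                raise ValueError(f"PTO bond counts must be 0, 12 or 13, got {p}")

    @property
    def bottom_strand(self) -> str:
        return reverse_complement(self.top_strand)

    def __len__(self) -> int:
        return len(self.top_strand)


@dataclass(frozen=True)
class CleavedFragment:
    """A fragment after iodine cleavage of its PTO-bonded 5' ends.

    The removed nucleotides leave the complementary strand single-stranded:
    left_overhang is the bottom strand's newly exposed end (text 5'->3' on
    the bottom strand, equal to revcomp of the removed top prefix);
    right_overhang is the top strand's exposed end (the junction linker).
    Core + overhangs reconstitute the parent duplex — cleavage moves bases
    between strandedness states, it never deletes tracked bases.
    """

    parent: DsFragment
    left_overhang: str
    right_overhang: str
    blunt: bool = False

    @property
    def fragment_id(self) -> str:
        return self.parent.fragment_id

    @property
    def core_top(self) -> str:
        """Double-stranded portion of the top strand."""
        t = self.parent.top_strand
        lo, ro = self.parent.pto_top, self.parent.pto_bottom
        return t[lo : len(t) - ro] if ro else t[lo:]


def amplify(
    template: CircularSeq,
    fwd: MutagenicPrimer,
    rev: MutagenicPrimer,
    fragment_id: str = "",
    site_label: str = "",
    scheme: DegenerateCodon | None = None,
) -> DsFragment:
    """PCR of the template with one mutagenic primer pair.

    Both primers must bind uniquely (degenerate primer letters are treated
    as wildcard positions that tolerate any template base, which is how a
    mutagenic codon anneals over the wild type).  The product runs from the
    forward primer's 5' end to the reverse primer's 5' end and carries the
    primer-borne degenerate codon; PTO annotations come from the tails.
    """
    fwd_hits = _find_unique(template, fwd.full_sequence, "forward primer " + fwd.name)
    rev_pattern = reverse_complement(rev.full_sequence)
    rev_hits = _find_unique(template, rev_pattern, "reverse primer " + rev.name)
    start = fwd_hits
    rev_end = rev_hits + len(rev_pattern)  # exclusive, top-strand coords
    n = len(template)
    if template.is_circular:
        length = (rev_end - start) % n
        # a product must at least contain both primer footprints; a shorter
        # modular distance means the amplicon runs all the way around the
        # circle (the single-fragment whole-plasmid case)
        while length < max(len(fwd.full_sequence), len(rev_pattern)):
            length += n
    else:
        if rev_end <= start:
            raise NoProductError(
                f"primers {fwd.name}/{rev.name} point away from each other on a linear template"
            )
        length = rev_end - start
    top = list(template.slice(start, length))
    degens: list[DegeneratePosition] = []
    if rev.degenerate_segment:
        # position of the degenerate codon within the rev-primer footprint
        idx_in_pattern = rev_pattern.index(_wild_segment(rev))
        offset = (length - len(rev_pattern)) + idx_in_pattern
        pattern = _wild_segment(rev)
        top[offset : offset + len(pattern)] = list(pattern)
        degens.append(
            DegeneratePosition(
                offset=offset,
                scheme=scheme or DegenerateCodon(pattern),
                site_label=site_label,
            )
        )
    return DsFragment(
        fragment_id=fragment_id,
        top_strand="".join(top),
        pto_top=fwd.pto_bond_count,
        pto_bottom=rev.pto_bond_count,
        degenerate_positions=tuple(degens),
    )


def _wild_segment(rev: MutagenicPrimer) -> str:
    """The degenerate codon as it reads on the top strand (MNN -> NNK)."""
    return reverse_complement(rev.degenerate_segment)


def _find_unique(template: CircularSeq, pattern: str, what: str) -> int:
    hits = _find_wildcard(template, pattern)
    if len(hits) != 1:
        raise NonSpecificPrimingError(
            f"{what} binds the template at {len(hits)} positions (need exactly 1)"
        )
    return hits[0]


def _find_wildcard(template: CircularSeq, pattern: str) -> list[int]:
    """Occurrences of pattern on the top strand; degenerate pattern letters
    match any template base (a mutagenic codon anneals over the wild type)."""
    pat = pattern.upper()
    n = len(template)
    hay = template.bases + (template.bases[: len(pat) - 1] if template.is_circular else "")
    limit = n if template.is_circular else n - len(pat) + 1
    hits = []
    for i in range(max(limit, 0)):
        ok = True
        for j, p in enumerate(pat):
            if len(IUPAC_EXPANSION[p]) == 1 and hay[i + j] != p:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


def iodine_cleave(fragment: DsFragment | CleavedFragment) -> CleavedFragment:
    """Remove the PTO-bonded nucleotides from each 5' end, exposing the
    complementary strand as a single-stranded overhang.  Idempotent; a
    fragment without PTO bonds comes back blunt (flagged, no overhangs).
    No other bases are altered — the chemistry is regiospecific."""
    if isinstance(fragment, CleavedFragment):
        return fragment
    t = fragment.top_strand
    left = reverse_complement(t[: fragment.pto_top]) if fragment.pto_top else ""
    right = t[len(t) - fragment.pto_bottom :] if fragment.pto_bottom else ""
    if not (left or right):
        import warnings

        warnings.warn(
            f"fragment {fragment.fragment_id or '?'} has no PTO bonds; "
            "cleavage yields a blunt product with no overhangs",
            stacklevel=2,
        )
    return CleavedFragment(
        parent=fragment,
        left_overhang=left,
        right_overhang=right,
        blunt=not (left or right),
    )


@dataclass(frozen=True)
class Junction:
    upstream_id: str  # fragment contributing its right overhang
    downstream_id: str  # fragment contributing its left overhang
    overhang: str  # top-strand text of the annealed linker


@dataclass(frozen=True)
class AssemblyResult:
    """Outcome of hybridizing a pool of cleaved fragments."""

    order: tuple[str, ...]
    is_circular: bool
    nick_count: int
    junctions: tuple[Junction, ...]
    unmatched: tuple[str, ...] = ()  # "fragment_id:left/right" labels
    ambiguous: bool = False
    candidates: tuple[tuple[str, ...], ...] = ()


def hybridize(fragments: list[CleavedFragment]) -> AssemblyResult:
    """Match overhangs by exact reverse-complement identity and extract the
    fragment cycle.

    Each junction of a successful circular assembly contributes two nicks
    (one per strand), so a k-fragment circle carries 2k nicks.  Unmatched
    overhangs yield an incomplete (non-circular) result rather than an
    exception; if any overhang is complementary to several partners the
    result is flagged ambiguous and no order is chosen.
    """
    if not fragments:
        raise AssemblyError("need at least one fragment")
    frags = {f.fragment_id: f for f in fragments}
    if len(frags) != len(fragments):
        raise AssemblyError("fragment ids must be unique")
    succ: dict[str, list[str]] = {}
    for a in fragments:
        if not a.right_overhang:
            continue
        matches = [
            b.fragment_id
            for b in fragments
            if b.left_overhang and a.right_overhang == reverse_complement(b.left_overhang)
        ]
        succ[a.fragment_id] = matches
    ambiguous = any(len(v) > 1 for v in succ.values())
    # count how many right-ends target each left-end
    indegree: dict[str, int] = {f.fragment_id: 0 for f in fragments}
    for v in succ.values():
        for b in v:
            indegree[b] += 1
    if ambiguous or any(d > 1 for d in indegree.values()):
        candidates = tuple(
            tuple([a] + v) for a, v in succ.items() if len(v) > 1
        )
        return AssemblyResult(
            order=(), is_circular=False, nick_count=0, junctions=(),
            ambiguous=True, candidates=candidates,
        )
    unmatched = []
    for f in fragments:
        if not f.right_overhang or not succ.get(f.fragment_id):
            unmatched.append(f"{f.fragment_id}:right")
        if not f.left_overhang or indegree[f.fragment_id] == 0:
            unmatched.append(f"{f.fragment_id}:left")
    if unmatched:
        return AssemblyResult(
            order=(), is_circular=False, nick_count=0, junctions=(),
            unmatched=tuple(sorted(unmatched)),
        )
    # follow the unique successor map; circular iff one cycle covers all
    start = min(frags)  # canonical start => permutation-invariant output
    order = [start]
    seen = {start}
    junctions = []
    cur = start
    while True:
        nxt = succ[cur][0]
        junctions.append(Junction(cur, nxt, frags[cur].right_overhang))
        if nxt == start:
            break
        if nxt in seen:  # sub-cycle not covering all fragments
            return AssemblyResult(
                order=(), is_circular=False, nick_count=0, junctions=(),
                unmatched=tuple(sorted(set(frags) - seen)),
            )
        order.append(nxt)
        seen.add(nxt)
        cur = nxt
    if len(order) != len(fragments):
        return AssemblyResult(
            order=(), is_circular=False, nick_count=0, junctions=(),
            unmatched=tuple(sorted(set(frags) - seen)),
        )
    return AssemblyResult(
        order=tuple(order),
        is_circular=True,
        nick_count=2 * len(junctions),
        junctions=tuple(junctions),
    )


def detect_self_circularization(fragment: CleavedFragment) -> bool:
    """True iff the fragment's own two overhangs can anneal to each other
    (mutually reverse-complementary), i.e. it can circularize without any
    partner — the empty-vector background failure mode."""
    return bool(
        fragment.left_overhang
        and fragment.right_overhang
        and fragment.left_overhang == reverse_complement(fragment.right_overhang)
    )


def reconstruct_product(
    result: AssemblyResult,
    fragments: list[CleavedFragment],
    codon_assignment: dict[str, str],
) -> CircularSeq:
    """Concrete circular product of a successful assembly.

    Every degenerate position must be assigned a concrete codon (keyed by
    site label).  Nicks are sealed seamlessly, so assigning every site its
    wild-type codon returns the template up to rotation.
    """
    if not result.is_circular:
        raise AssemblyError("cannot reconstruct from an incomplete assembly")
    if result.ambiguous:
        raise AssemblyError("cannot reconstruct from an ambiguous assembly")
    frags = {f.fragment_id: f for f in fragments}
    parts = []
    for fid in result.order:
        parent = frags[fid].parent
        top = parent.top_strand
        seg = list(top[: len(top) - parent.pto_bottom])  # drop right linker: next fragment provides it
        for d in parent.degenerate_positions:
            if d.site_label not in codon_assignment:
                raise AssemblyError(f"no codon assigned for site {d.site_label}")
            codon = codon_assignment[d.site_label].upper()
            if len(codon) != 3:
                raise AssemblyError(f"assigned codon for {d.site_label} must have length 3")
            if d.offset + 3 <= len(seg):
                seg[d.offset : d.offset + 3] = list(codon)
            else:  # codon extends into the dropped linker region (offset 0 edge case)
                raise AssemblyError("degenerate codon overlaps the junction linker")
        parts.append("".join(seg))
    return CircularSeq("".join(parts), "circular")


def amplify_plan(template: CircularSeq, plans: list[FragmentPlan]) -> list[DsFragment]:
    """Amplify every fragment of a design plan."""
    return [
        amplify(
            template,
            p.fwd_primer,
            p.rev_primer,
            fragment_id=p.fragment_id,
            site_label=p.site.label,
            scheme=p.site.scheme,
        )
        for p in plans
    ]


def run_assembly(template: CircularSeq, plans: list[FragmentPlan]):
    """Full pipeline: amplify -> cleave -> hybridize.

    Returns (result, cleaved_fragments)."""
    cleaved = [iodine_cleave(f) for f in amplify_plan(template, plans)]
    return hybridize(cleaved), cleaved


def wildtype_assignment(plans: list[FragmentPlan]) -> dict[str, str]:
    """Site label -> wild-type codon map for round-trip reconstruction."""
    return {p.site.label: p.site.wt_codon for p in plans}
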