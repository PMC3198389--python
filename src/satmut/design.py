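"""Design of phosphorothioate (PTO) mutagenic primer pairs and fragment plans.

For each codon targeted for saturation, a junction is defined: 12-13
template nucleotides downstream of the codon (optionally offset by a few
ordinary bases) that become the single-stranded overhang after iodine
cleavage.  Each fragment of the multi-fragment plan is amplified by

* a forward primer  5'-(PTO tail = previous junction's linker)-(3' anneal)-3'
* a reverse primer  5'-(PTO tail = revcomp of this junction's linker)-
  (revcomp of offset spacer)-(revcomp of the degenerate codon, e.g. MNN for
  NNK)-(3' anneal matching upstream of the codon)-3'

so that consecutive fragments share mutually reverse-complementary PTO
tails and every fragment carries exactly one saturated codon near its
reverse end.  Annealing regions are grown 3'-wards one base at a time until
the melting temperature reaches the target window (63+-3 degC by default,
nearest-neighbor model on the annealing region only, since the 3' end
drives priming).  GC content (>=40% by default) is checked on the full
oligo with fractional counting of degenerate letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqcore import (
    NNK,
    CircularSeq,
    DegenerateCodon,
    GeneticCode,
    IUPAC_EXPANSION,
    STANDARD_CODE,
    reverse_complement,
    slice_circular,
)

__all__ = [
    "DesignError",
    "ProximityError",
    "DesignConfig",
    "TargetSite",
    "JunctionSpec",
    "MutagenicPrimer",
    "FragmentPlan",
    "DesignIssue",
    "DesignReport",
    "SubsetOutcome",
    "melting_temperature",
    "gc_content",
    "coding_view",
    "locate_target_codons",
    "make_junction",
    "design_forward_primer",
    "design_reverse_primer",
    "plan_fragments",
    "subset_design",
    "validate_design",
]


class DesignError(ValueError):
    """A primer/fragment design request cannot be satisfied."""


class ProximityError(DesignError):
    """Two target sites are too close for independent primer footprints.

    The message suggests the standard remedy: place both codons on a single
    multi-codon mutagenic primer (not designed by this module).
    """


@dataclass(frozen=True)
class DesignConfig:
    """Tunable primer-design constraints.

    Defaults follow the published design rules: 12 PTO bonds (13 when a
    12-mer linker collides or is palindromic), >=12 nt annealing region,
    Tm target 63+-3 degC, GC >= 40%.  Salt/oligo concentrations feed the
    nearest-neighbor Tm model (50 mM monovalent salt, 0.4 uM primer).
    """

    pto_len: int = 12
    min_anneal: int = 12
    max_anneal: int = 30
    tm_target: float = 63.0
    tm_window: float = 3.0
    gc_min: float = 0.40
    tm_method: str = "nearest_neighbor"
    na_mM: float = 50.0
    oligo_nM: float = 400.0

    def __post_init__(self) -> None:
        if self.min_anneal > self.max_anneal:
            raise ValueError("min_anneal must be <= max_anneal")
        if self.tm_window < 0:
            raise ValueError("tm_window must be >= 0")


@dataclass(frozen=True)
class TargetSite:
    """One codon selected for saturation.

    aa_index is the 1-based residue number within the ORF (the field's
    labelling convention: 'E31' is the glutamate at residue 31);
    codon_start is the 0-based coordinate of the codon's first base in
    coding orientation.  linker_offset places the overhang linker that many
    ordinary (non-PTO) bases downstream of the codon; the offset bases ride
    along on the reverse primer between the degenerate codon and the PTO
    tail.  pto_len, if set, overrides DesignConfig.pto_len for this site.
    """

    label: str
    aa_index: int
    codon_start: int
    wt_codon: str
    scheme: DegenerateCodon = NNK
    linker_offset: int = 0
    pto_len: int | None = None


@dataclass(frozen=True)
class JunctionSpec:
    """The overhang-forming linker downstream of a target codon."""

    site: TargetSite
    linker: str
    spacer: str  # offset bases between codon and linker ("" when offset 0)

    @property
    def linker_len(self) -> int:
        return len(self.linker)

    @property
    def end(self) -> int:
        """Coding coordinate one past the linker (start of downstream anneal)."""
        return self.site.codon_start + 3 + len(self.spacer) + len(self.linker)


@dataclass(frozen=True)
class MutagenicPrimer:
    """A designed oligo: PTO tail + [spacer + degenerate codon] + 3' anneal."""

    name: str
    role: str  # "forward" | "reverse"
    pto_tail: str
    anneal3p: str
    degenerate_segment: str = ""
    spacer: str = ""  # reverse primers only: revcomp of the linker offset bases
    tm_c: float = float("nan")
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        if self.role == "forward" and self.degenerate_segment:
            raise ValueError("forward primers carry no degenerate segment")

    @property
    def full_sequence(self) -> str:
        return (self.pto_tail + self.spacer + self.degenerate_segment + self.anneal3p).upper()

    @property
    def pto_bond_count(self) -> int:
        return len(self.pto_tail)

    def render(self) -> str:
        """Order-sheet rendering: lowercase = PTO-bonded nucleotides."""
        return self.pto_tail.lower() + (self.spacer + self.degenerate_segment + self.anneal3p).upper()

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class FragmentPlan:
    """One amplicon of the multi-fragment assembly plan.

    The fragment starts at the previous site's junction linker and ends at
    this site's junction, carrying this site's degenerate codon near its
    reverse end.  start/end are coding-orientation plasmid coordinates of
    the two primer 5' ends (end exclusive, possibly wrapping the origin).
    """

    fragment_id: str
    site: TargetSite
    fwd_primer: MutagenicPrimer
    rev_primer: MutagenicPrimer
    start: int
    end: int
    expected_length_bp: int
    wraps_origin: bool = False


@dataclass(frozen=True)
class DesignIssue:
    level: str  # "error" | "warning" | "info"
    code: str
    message: str


@dataclass
class DesignReport:
    issues: list[DesignIssue] = field(default_factory=list)

    def add(self, level: str, code: str, message: str) -> None:
        self.issues.append(DesignIssue(level, code, message))

    @property
    def errors(self) -> list[DesignIssue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def warnings(self) -> list[DesignIssue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def is_valid(self) -> bool:
        return not self.errors


def melting_temperature(
    seq: str,
    method: str = "nearest_neighbor",
    na_mM: float = 50.0,
    oligo_nM: float = 400.0,
) -> float:
    """Melting temperature in degC of a concrete DNA oligo.

    'nearest_neighbor' uses the unified Allawi–SantaLucia parameter set
    (via Biopython) with the configured monovalent salt and an excess-primer
    concentration; 'wallace' is the 2(A+T)+4(G+C) rule.  Degenerate letters
    are rejected for the nearest-neighbor model — callers compute Tm on the
    concrete annealing region only.
    """
    if not seq:
        raise ValueError("cannot compute Tm of an empty sequence")
    s = seq.upper()
    degenerate = any(len(IUPAC_EXPANSION.get(b, "")) != 1 for b in s)
    if method == "wallace":
        if degenerate:
            raise ValueError("Wallace Tm requires a non-degenerate sequence")
        return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (s.count("G") + s.count("C"))
    if method == "nearest_neighbor":
        if degenerate:
            raise ValueError("nearest-neighbor Tm requires a non-degenerate sequence")
        from Bio.SeqUtils import MeltingTemp as mt

        return float(mt.Tm_NN(s, Na=na_mM, dnac1=oligo_nM, dnac2=0))
    raise ValueError(f"unknown Tm method {method!r}")


def gc_content(seq: str) -> float:
    """GC fraction of an IUPAC string; degenerate letters contribute their
    expected GC (N -> 0.5, K -> 0.5, S -> 1.0, W -> 0.0, ...)."""
    if not seq:
        raise ValueError("cannot compute GC content of an empty sequence")
    total = 0.0
    for ch in seq.upper():
        exp = IUPAC_EXPANSION.get(ch)
        if exp is None:
            raise ValueError(f"non-IUPAC character {ch!r}")
        total += sum(b in "GC" for b in exp) / len(exp)
    return total / len(seq)


def coding_view(plasmid: CircularSeq, orf_strand: str = "+") -> CircularSeq:
    """The plasmid in coding orientation: identity for '+', reverse
    complement for '-' ORFs.  All design coordinates refer to this view."""
    if orf_strand == "+":
        return plasmid
    if orf_strand == "-":
        return plasmid.reverse_complement()
    raise ValueError(f"orf_strand must be '+' or '-', got {orf_strand!r}")


def locate_target_codons(
    plasmid: CircularSeq,
    orf_start: int,
    aa_indices: list[int],
    scheme: DegenerateCodon = NNK,
    orf_strand: str = "+",
    orf_len: int | None = None,
    code: GeneticCode = STANDARD_CODE,
    linker_offsets: dict[int, int] | None = None,
) -> list[TargetSite]:
    """Resolve 1-based residue indices to TargetSites on the plasmid.

    For '-' strand ORFs, orf_start is the coding-orientation coordinate of
    the start codon (i.e. on coding_view(plasmid, '-')).  Sites are
    returned sorted by plasmid coordinate; wild-type codons are read from
    the template and labelled residue-letter + index (e.g. E31).
    """
    if len(set(aa_indices)) != len(aa_indices):
        dupes = sorted({i for i in aa_indices if aa_indices.count(i) > 1})
        raise DesignError(f"duplicate target residue indices: {dupes}")
    coding = coding_view(plasmid, orf_strand)
    n = len(coding)
    if orf_len is not None and aa_indices and 3 * max(aa_indices) > orf_len:
        raise DesignError(
            f"residue index {max(aa_indices)} beyond ORF of {orf_len // 3} codons"
        )
    offsets = linker_offsets or {}
    sites = []
    for idx in aa_indices:
        if idx < 1:
            raise DesignError(f"residue indices are 1-based; got {idx}")
        start = (orf_start + 3 * (idx - 1)) % n
        wt = coding.slice(start, 3)
        sites.append(
            TargetSite(
                label=f"{code.translate(wt)}{idx}",
                aa_index=idx,
                codon_start=start,
                wt_codon=wt,
                scheme=scheme,
                linker_offset=offsets.get(idx, 0),
            )
        )
    return sorted(sites, key=lambda s: s.codon_start)


def make_junction(plasmid: CircularSeq, site: TargetSite, pto_len: int = 12) -> JunctionSpec:
    """The linker: pto_len template bases starting linker_offset bases
    downstream of the target codon (coding strand)."""
    if pto_len not in (12, 13):
        raise DesignError(f"pto_len must be 12 or 13, got {pto_len}")
    if site.linker_offset < 0:
        raise DesignError("linker_offset must be >= 0")
    spacer = plasmid.slice(site.codon_start + 3, site.linker_offset)
    linker = plasmid.slice(site.codon_start + 3 + site.linker_offset, pto_len)
    return JunctionSpec(site=site, linker=linker, spacer=spacer)


def _extend_anneal(
    fetch,  # length -> candidate annealing sequence (concrete)
    config: DesignConfig,
    anneal_len: int | None,
) -> tuple[str, float, bool]:
    """Grow the annealing region one base at a time until Tm enters the
    target window; returns (anneal, tm, tm_in_window).  A fixed anneal_len
    bypasses the search (used to reproduce printed primer sets)."""
    lo = config.tm_target - config.tm_window
    hi = config.tm_target + config.tm_window
    if anneal_len is not None:
        seq = fetch(anneal_len)
        tm = melting_temperature(seq, config.tm_method, config.na_mM, config.oligo_nM)
        return seq, tm, lo <= tm <= hi
    seq = fetch(config.min_anneal)
    tm = melting_temperature(seq, config.tm_method, config.na_mM, config.oligo_nM)
    length = config.min_anneal
    while tm < lo and length < config.max_anneal:
        length += 1
        seq = fetch(length)
        tm = melting_temperature(seq, config.tm_method, config.na_mM, config.oligo_nM)
    return seq, tm, lo <= tm <= hi


def _circular_between(n: int, a: int, b: int) -> int:
    """Circular distance walking forward from a to b on a circle of size n."""
    return (b - a) % n


def _span_contains(n: int, start: int, length: int, pos: int) -> bool:
    """Does the (possibly wrapping) window [start, start+length) contain pos?"""
    return _circular_between(n, start, pos) < length


def design_forward_primer(
    plasmid: CircularSeq,
    junction: JunctionSpec,
    config: DesignConfig = DesignConfig(),
    anneal_len: int | None = None,
    name: str | None = None,
    avoid_codons: list[int] | None = None,
) -> MutagenicPrimer:
    """Forward primer for the fragment that begins at `junction`:
    PTO tail = linker, then a template-matching 3' annealing region."""
    start = junction.end

    def fetch(length: int) -> str:
        return plasmid.slice(start, length)

    _check_anneal_clear(plasmid, start, config.min_anneal, avoid_codons, "forward")
    anneal, tm, ok = _extend_anneal(fetch, config, anneal_len)
    full = junction.linker + anneal
    return MutagenicPrimer(
        name=name or f"{junction.site.label}_Fw",
        role="forward",
        pto_tail=junction.linker,
        anneal3p=anneal,
        tm_c=tm,
        gc_fraction=gc_content(full),
    )


def design_reverse_primer(
    plasmid: CircularSeq,
    site: TargetSite,
    junction: JunctionSpec,
    config: DesignConfig = DesignConfig(),
    anneal_len: int | None = None,
    name: str | None = None,
    avoid_codons: list[int] | None = None,
) -> MutagenicPrimer:
    """Reverse primer saturating `site`: PTO tail = revcomp(linker), then
    revcomp of any offset spacer, the degenerate codon as seen on the
    reverse strand (NNK -> MNN), and an annealing region reverse-
    complementary to the template immediately 5' of the codon."""
    if junction.site is not site and junction.site.codon_start != site.codon_start:
        raise DesignError("junction does not belong to this site")
    n = len(plasmid)

    def fetch(length: int) -> str:
        return reverse_complement(plasmid.slice((site.codon_start - length) % n, length))

    _check_anneal_clear(
        plasmid, (site.codon_start - config.min_anneal) % n, config.min_anneal,
        avoid_codons, "reverse",
    )
    anneal, tm, ok = _extend_anneal(fetch, config, anneal_len)
    tail = reverse_complement(junction.linker)
    spacer_rc = reverse_complement(junction.spacer) if junction.spacer else ""
    degen = site.scheme.reverse_complement()
    full = tail + spacer_rc + degen + anneal
    return MutagenicPrimer(
        name=name or f"{site.label}_Rv",
        role="reverse",
        pto_tail=tail,
        spacer=spacer_rc,
        degenerate_segment=degen,
        anneal3p=anneal,
        tm_c=tm,
        gc_fraction=gc_content(full),
    )


def _check_anneal_clear(
    plasmid: CircularSeq,
    start: int,
    length: int,
    avoid_codons: list[int] | None,
    role: str,
) -> None:
    if not avoid_codons:
        return
    n = len(plasmid)
    for cs in avoid_codons:
        for b in (cs, cs + 1, cs + 2):
            if _span_contains(n, start, length, b % n):
                raise ProximityError(
                    f"{role} annealing region would overlap the target codon at {cs}; "
                    "sites this close require a single multi-codon mutagenic primer"
                )


def plan_fragments(
    plasmid: CircularSeq,
    sites: list[TargetSite],
    config: DesignConfig = DesignConfig(),
    anneal_lengths: dict[str, int] | None = None,
) -> list[FragmentPlan]:
    """Fragment plan for k target sites on a circular template: k fragments,
    each running from the previous site's junction to this site's junction
    and carrying this site's degenerate codon.  The fragment spanning the
    plasmid origin is labelled 'vector'; the rest are lettered B, C, ... in
    template order after it.  anneal_lengths optionally pins individual
    primers' annealing lengths by primer name.

    The forward primer of the fragment carrying site i is named after site
    i but its PTO tail is the *previous* junction's linker, matching the
    field's order-sheet convention.
    """
    if not sites:
        raise DesignError("at least one target site is required")
    if not plasmid.is_circular:
        raise DesignError("fragment planning requires a circular template")
    n = len(plasmid)
    sites = sorted(sites, key=lambda s: s.codon_start)
    lengths = anneal_lengths or {}
    k = len(sites)
    junctions = [
        make_junction(plasmid, s, s.pto_len if s.pto_len is not None else config.pto_len)
        for s in sites
    ]
    codon_starts = [s.codon_start for s in sites]
    plans: list[FragmentPlan] = []
    for i, site in enumerate(sites):
        prev_j = junctions[(i - 1) % k]
        this_j = junctions[i]
        others = [c for c in codon_starts if c != site.codon_start]
        fwd = design_forward_primer(
            plasmid, prev_j, config,
            anneal_len=lengths.get(f"{site.label}_Fw"),
            name=f"{site.label}_Fw",
            avoid_codons=others,
        )
        rev = design_reverse_primer(
            plasmid, site, this_j, config,
            anneal_len=lengths.get(f"{site.label}_Rv"),
            name=f"{site.label}_Rv",
            avoid_codons=others,
        )
        start = prev_j.end - prev_j.linker_len  # fwd 5' position (linker start)
        end = this_j.end  # rev 5' end position, exclusive
        length = _circular_between(n, start % n, end % n)
        if length == 0:
            length = n  # single-site plan: the amplicon is the whole circle plus linker
        if k == 1:
            length = n + this_j.linker_len
        plans.append(
            FragmentPlan(
                fragment_id="",  # assigned below
                site=site,
                fwd_primer=fwd,
                rev_primer=rev,
                start=start % n,
                end=end % n,
                expected_length_bp=length,
                wraps_origin=(start % n) + length > n,
            )
        )
    # footprint separation: each fragment must be long enough to hold both primers
    for p in plans:
        if p.expected_length_bp < len(p.fwd_primer) + len(p.rev_primer) - 0:
            raise ProximityError(
                f"fragment for {p.site.label} ({p.expected_length_bp} bp) cannot hold "
                "both primer footprints; merge the neighbouring codons onto one "
                "multi-codon mutagenic primer"
            )
    # label: the origin-spanning fragment is the vector backbone
    vec_idx = next((i for i, p in enumerate(plans) if p.wraps_origin), None)
    letters = iter("BCDEFGHIJKLMNOPQRSTU")
    for i, p in enumerate(plans):
        if i == vec_idx:
            fid = "vector"
        else:
            fid = next(letters)
        plans[i] = replace(p, fragment_id=fid)
    return plans


@dataclass(frozen=True)
class SubsetOutcome:
    """Result of restricting a full plan to a subset of its sites."""

    plans: list[FragmentPlan]
    reused_primers: list[str]
    new_primers: list[str]


def subset_design(
    plasmid: CircularSeq,
    full_plans: list[FragmentPlan],
    chosen: list[TargetSite],
    config: DesignConfig = DesignConfig(),
    anneal_lengths: dict[str, int] | None = None,
) -> SubsetOutcome:
    """Sub-library plan saturating only `chosen` sites, reusing the full
    plan's oligo set wherever possible.

    Fragments between unchosen sites merge.  A chosen site already present
    in the full plan reuses its reverse primer, and the forward primer
    whose tail sits at the junction of the previous chosen site is reused
    when that junction existed in the full plan.  Junctions introduced by
    *new* sites need one fresh primer on each side, which is reported in
    new_primers (the classic one-new-oligo sub-library case).
    """
    if not chosen:
        raise DesignError("chosen site subset must be nonempty")
    n = len(plasmid)
    chosen = sorted(chosen, key=lambda s: s.codon_start)
    by_codon = {p.site.codon_start: p for p in full_plans}
    lengths = anneal_lengths or {}
    reused: list[str] = []
    new: list[str] = []
    plans: list[FragmentPlan] = []
    k = len(chosen)
    junctions = [
        make_junction(plasmid, s, s.pto_len if s.pto_len is not None else config.pto_len)
        for s in chosen
    ]
    all_codons = sorted({p.site.codon_start for p in full_plans} | {s.codon_start for s in chosen})
    for i, site in enumerate(chosen):
        prev_site = chosen[(i - 1) % k]
        prev_j = junctions[(i - 1) % k]
        this_j = junctions[i]
        others = [c for c in (s.codon_start for s in chosen) if c != site.codon_start]
        # reverse primer: reuse if the site was in the full plan
        if site.codon_start in by_codon:
            rev = by_codon[site.codon_start].rev_primer
            reused.append(rev.name)
        else:
            rev = design_reverse_primer(
                plasmid, site, this_j, config,
                anneal_len=lengths.get(f"{site.label}_Rv"),
                avoid_codons=others,
            )
            new.append(rev.name)
        # forward primer: reuse the full plan's primer anchored at prev junction
        fwd = None
        if prev_site.codon_start in by_codon:
            candidate_prev = by_codon[prev_site.codon_start]
            nxt = _next_plan_after(full_plans, prev_site.codon_start, n)
            if nxt is not None and nxt.fwd_primer.pto_tail == prev_j.linker:
                fwd = nxt.fwd_primer
                reused.append(fwd.name)
        if fwd is None:
            fwd = design_forward_primer(
                plasmid, prev_j, config,
                anneal_len=lengths.get(f"{site.label}_Fw'"),
                name=f"{site.label}_Fw'",
                avoid_codons=others,
            )
            new.append(fwd.name)
        start = prev_j.end - prev_j.linker_len
        end = this_j.end
        length = _circular_between(n, start % n, end % n)
        if k == 1:
            length = n + this_j.linker_len
        plans.append(
            FragmentPlan(
                fragment_id="",
                site=site,
                fwd_primer=fwd,
                rev_primer=rev,
                start=start % n,
                end=end % n,
                expected_length_bp=length,
                wraps_origin=(start % n) + length > n,
            )
        )
    vec_idx = next((i for i, p in enumerate(plans) if p.wraps_origin), None)
    letters = iter("BCDEFGHIJKLMNOPQRSTU")
    for i, p in enumerate(plans):
        plans[i] = replace(p, fragment_id="vector" if i == vec_idx else next(letters))
    return SubsetOutcome(plans=plans, reused_primers=reused, new_primers=new)


def _next_plan_after(plans: list[FragmentPlan], codon_start: int, n: int) -> FragmentPlan | None:
    """The fragment whose forward primer starts at the junction of the site
    at `codon_start` — i.e. the next fragment in template order."""
    ordered = sorted(plans, key=lambda p: p.site.codon_start)
    for i, p in enumerate(ordered):
        if p.site.codon_start == codon_start:
            return ordered[(i + 1) % len(ordered)]
    return None


def validate_design(
    plans: list[FragmentPlan],
    config: DesignConfig = DesignConfig(),
) -> DesignReport:
    """Engineering QC of a fragment plan.

    Errors: duplicate linkers or linkers that are mutual reverse
    complements (misassembly risk) and self-reverse-complementary
    (palindromic) linkers (fragment self-hybridization risk).  Warnings:
    Tm outside the target window, GC below the minimum.  Info: wild-type
    codon not encodable by the scheme (the library cannot regenerate the
    wild type at that site).
    """
    report = DesignReport()
    linkers = {p.site.label: p.rev_primer.pto_tail for p in plans}
    # rev tail is revcomp(linker); recover linker text for comparisons
    linkers = {lab: reverse_complement(t) for lab, t in linkers.items()}
    labels = list(linkers)
    for i, a in enumerate(labels):
        la = linkers[a]
        if la == reverse_complement(la):
            report.add("error", "palindromic-linker",
                       f"linker at {a} is its own reverse complement (self-hybridization risk)")
        for b in labels[i + 1:]:
            lb = linkers[b]
            if la == lb:
                report.add("error", "linker-collision",
                           f"identical linkers at {a} and {b} (misassembly risk)")
            elif la == reverse_complement(lb):
                report.add("error", "linker-revcomp-collision",
                           f"linkers at {a} and {b} are mutual reverse complements "
                           "(misassembly risk)")
    lo, hi = config.tm_target - config.tm_window, config.tm_target + config.tm_window
    for p in plans:
        for pr in (p.fwd_primer, p.rev_primer):
            if not (lo <= pr.tm_c <= hi):
                report.add("warning", "tm-out-of-window",
                           f"{pr.name}: anneal Tm {pr.tm_c:.1f} degC outside "
                           f"[{lo:.0f}, {hi:.0f}]")
            if pr.gc_fraction < config.gc_min:
                report.add("warning", "gc-below-min",
                           f"{pr.name}: GC {pr.gc_fraction:.0%} below {config.gc_min:.0%}")
        if p.site.wt_codon.upper() not in p.site.scheme:
            report.add("info", "wt-not-encodable",
                       f"{p.site.label}: wild-type codon {p.site.wt_codon} is not in the "
                       f"{p.site.scheme} expansion; the library cannot regenerate the "
                       "wild type at this site")
    return report
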