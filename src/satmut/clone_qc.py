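"""Quality control of sequenced clone libraries against the template gene.

Given the wild-type gene sequence, the saturated sites and a set of clone
sequences, this module reads the codon at each target site, classifies it
(scheme member / wild type / off-scheme), tallies per-position codon
diversity as a fraction of the scheme's maximum, detects duplicate
genotypes, calls off-target point mutations with their distance to the
nearest target codon, and computes the per-kb mutation frequency.  A
seeded simulator generates synthetic clone sets (uniform scheme draws plus
an optional per-base error rate) that round-trip through the same
analyses.

Coordinates here are relative to the supplied gene region (codon of
residue i starts at 3*(i-1)), not to the full plasmid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .seqcore import NNK, DegenerateCodon, GeneticCode, STANDARD_CODE

__all__ = [
    "QcSite",
    "CloneRecord",
    "SiteCall",
    "Mutation",
    "LibraryReport",
    "extract_site_codons",
    "tally_diversity",
    "call_offtarget_mutations",
    "mutation_frequency",
    "simulate_clone_set",
    "analyze_library",
    "tally_codon_matrix",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (so 81.25 -> 81.3 at one digit), matching
    how tabulated percentages are conventionally printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class QcSite:
    """A saturated codon in gene-relative coordinates."""

    label: str
    aa_index: int
    wt_codon: str
    scheme: DegenerateCodon = NNK

    @property
    def codon_start(self) -> int:
        return 3 * (self.aa_index - 1)


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    sequence: str
    source: str = "sequenced"  # or "simulated"


@dataclass(frozen=True)
class SiteCall:
    site: QcSite
    observed_codon: str
    in_scheme: bool
    is_wildtype: bool
    category: str  # scheme | wildtype-in-scheme | wildtype-off-scheme | off-scheme


@dataclass(frozen=True)
class Mutation:
    clone_id: str
    position: int  # 0-based within the gene region
    ref: str
    alt: str
    distance_to_site: int  # bases to the nearest target codon (0 = adjacent)


def _classify(site: QcSite, codon: str) -> SiteCall:
    codon = codon.upper()
    in_scheme = codon in site.scheme
    is_wt = codon == site.wt_codon.upper()
    if is_wt:
        category = "wildtype-in-scheme" if in_scheme else "wildtype-off-scheme"
    else:
        category = "scheme" if in_scheme else "off-scheme"
    return SiteCall(site, codon, in_scheme, is_wt, category)


def _align_clone(clone_seq: str, template: str) -> str | None:
    """End-gap-free global alignment fallback for length-mismatched clones;
    returns the clone projected onto template coordinates (gaps as '-'), or
    None when the alignment is too poor to trust."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(template.upper(), clone_seq.upper())[0]
    projected = ["-"] * len(template)
    for (tb, te), (qb, qe) in zip(*aln.aligned):
        projected[tb:te] = clone_seq.upper()[qb:qe]
    mapped = sum(1 for c in projected if c != "-")
    if mapped < 0.8 * len(template):
        return None
    return "".join(projected)


def extract_site_codons(
    clone: CloneRecord,
    template: str,
    sites: list[QcSite],
) -> list[SiteCall]:
    """Read and classify the codon at each target site of one clone.

    Clones of template length are read directly; a length mismatch (which
    would indicate an indel) falls back to end-gap-free global alignment
    and raises ValueError if the clone cannot be mapped."""
    seq = clone.sequence.upper()
    if len(seq) != len(template):
        projected = _align_clone(seq, template)
        if projected is None:
            raise ValueError(f"clone {clone.clone_id} cannot be aligned to the template")
        seq = projected
    calls = []
    for site in sites:
        codon = seq[site.codon_start : site.codon_start + 3]
        calls.append(_classify(site, codon))
    return calls


def call_offtarget_mutations(
    clone: CloneRecord,
    template: str,
    sites: list[QcSite],
    exclusion_bp: int = 0,
) -> list[Mutation]:
    """Substitutions outside the target codons, annotated with distance to
    the nearest target codon.

    exclusion_bp additionally masks positions within that many bases of a
    target codon (useful to ignore primer-covered regions); the default 0
    reports everything, treating observed distances as a property of the
    data rather than a filter.
    """
    if exclusion_bp < 0:
        raise ValueError("exclusion_bp must be >= 0")
    seq = clone.sequence.upper()
    tmpl = template.upper()
    if len(seq) != len(tmpl):
        projected = _align_clone(seq, tmpl)
        if projected is None:
            raise ValueError(f"clone {clone.clone_id} cannot be aligned to the template")
        seq = projected
    site_spans = [(s.codon_start, s.codon_start + 3) for s in sites]
    muts = []
    for i, (a, b) in enumerate(zip(tmpl, seq)):
        if b in ("-",) or a == b:
            continue
        if any(lo <= i < hi for lo, hi in site_spans):
            continue
        dist = min(
            (lo - i) if i < lo else (i - hi + 1)
            for lo, hi in site_spans
        ) if site_spans else i
        if dist < exclusion_bp:
            continue
        muts.append(Mutation(clone.clone_id, i, a, b, dist))
    return muts


def mutation_frequency(n_mutations: int, surveyed_bases: int) -> float:
    """Mutations per kb surveyed, half-up rounded to two decimals."""
    if surveyed_bases <= 0:
        raise ValueError("surveyed_bases must be > 0")
    return round_half_up(n_mutations / (surveyed_bases / 1000.0), 2)


@dataclass
class LibraryReport:
    """Per-position diversity tallies plus library-wide mutation QC."""

    sites: list[QcSite]
    n_clones: int
    codon_tables: dict[str, list[str]]  # site label -> observed codons (one per clone)
    distinct_counts: dict[str, int]
    percent_of_max: dict[str, float]
    wildtype_counts: dict[str, int]
    offscheme_counts: dict[str, int]
    duplicate_clones: int
    offtarget_mutations: list[Mutation] = field(default_factory=list)
    surveyed_bases: int = 0

    @property
    def mutation_rate_per_kb(self) -> float:
        return mutation_frequency(len(self.offtarget_mutations), self.surveyed_bases)

    def to_frame(self) -> pd.DataFrame:
        """Codon matrix (clones x sites) with the three summary rows used
        in published per-position diversity tables."""
        labels = [s.label for s in self.sites]
        df = pd.DataFrame(
            {lab: [c.lower() for c in self.codon_tables[lab]] for lab in labels},
            index=[str(i + 1) for i in range(self.n_clones)],
        )
        maxdiv = {lab: s.scheme.size for lab, s in zip(labels, self.sites)}
        df.loc["Different codons"] = [self.distinct_counts[lab] for lab in labels]
        df.loc["Maximal diversity"] = [maxdiv[lab] for lab in labels]
        df.loc["Obtained diversity [%]"] = [self.percent_of_max[lab] for lab in labels]
        return df


def tally_diversity(
    clones: list[CloneRecord],
    template: str,
    sites: list[QcSite],
) -> LibraryReport:
    """Distinct-codon tallies per site, percent of scheme maximum (one
    decimal, half-up), wild-type counts and duplicate-genotype detection."""
    if not clones:
        raise ValueError("need at least one analyzable clone")
    calls_per_clone = [extract_site_codons(c, template, sites) for c in clones]
    return _tally(sites, [[call.observed_codon for call in calls] for calls in calls_per_clone],
                  [[call for call in calls] for calls in calls_per_clone])


def tally_codon_matrix(
    matrix: dict[str, list[str]] | pd.DataFrame,
    sites: list[QcSite] | None = None,
) -> LibraryReport:
    """Tally a pre-extracted codon matrix (site label -> list of observed
    codons), e.g. a transcribed per-position sequencing table.  Without
    explicit sites, every column is treated as an NNK position with
    unknown wild type."""
    if isinstance(matrix, pd.DataFrame):
        matrix = {str(c): [str(v) for v in matrix[c]] for c in matrix.columns}
    labels = list(matrix)
    if sites is None:
        sites = [QcSite(label=lab, aa_index=i + 1, wt_codon="NNN") for i, lab in enumerate(labels)]
    rows = list(zip(*(matrix[lab] for lab in labels)))
    codons = [[c.upper() for c in row] for row in rows]
    calls = [
        [_classify(site, codon) for site, codon in zip(sites, row)]
        for row in codons
    ]
    return _tally(sites, codons, calls)


def _tally(
    sites: list[QcSite],
    codons_per_clone: list[list[str]],
    calls_per_clone: list[list[SiteCall]],
) -> LibraryReport:
    labels = [s.label for s in sites]
    tables: dict[str, list[str]] = {lab: [] for lab in labels}
    wt: dict[str, int] = {lab: 0 for lab in labels}
    offs: dict[str, int] = {lab: 0 for lab in labels}
    for calls in calls_per_clone:
        for lab, call in zip(labels, calls):
            tables[lab].append(call.observed_codon)
            if call.is_wildtype:
                wt[lab] += 1
            if not call.in_scheme:
                offs[lab] += 1
    distinct = {lab: len(set(tables[lab])) for lab in labels}
    percent = {
        lab: round_half_up(100.0 * distinct[lab] / site.scheme.size, 1)
        for lab, site in zip(labels, sites)
    }
    genotypes = [tuple(row) for row in codons_per_clone]
    duplicates = len(genotypes) - len(set(genotypes))
    return LibraryReport(
        sites=list(sites),
        n_clones=len(codons_per_clone),
        codon_tables=tables,
        distinct_counts=distinct,
        percent_of_max=percent,
        wildtype_counts=wt,
        offscheme_counts=offs,
        duplicate_clones=duplicates,
    )


def analyze_library(
    clones: list[CloneRecord],
    template: str,
    sites: list[QcSite],
    exclusion_bp: int = 0,
) -> LibraryReport:
    """Full clone-set analysis: diversity tallies plus off-target mutation
    calling and per-kb frequency over all surveyed bases (gene length x
    analyzable clones, target codons excluded from the mutation calls but
    kept in the denominator as in standard per-kb accounting)."""
    report = tally_diversity(clones, template, sites)
    muts: list[Mutation] = []
    for c in clones:
        muts.extend(call_offtarget_mutations(c, template, sites, exclusion_bp))
    report.offtarget_mutations = muts
    report.surveyed_bases = len(template) * len(clones)
    return report


def simulate_clone_set(
    template: str,
    sites: list[QcSite],
    n_clones: int,
    error_rate_per_base: float = 0.0,
    rng: np.random.Generator | int = 0,
    source: str = "simulated",
) -> list[CloneRecord]:
    """Synthetic clone set: each clone is the template with every target
    codon replaced by a uniform draw from its site's scheme expansion, plus
    i.i.d. substitution errors at error_rate_per_base everywhere outside
    the target codons (emulating polymerase errors; the chemistry itself
    is assumed error-free)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tmpl = template.upper()
    site_spans = {(s.codon_start + j) for s in sites for j in range(3)}
    editable = np.array([i for i in range(len(tmpl)) if i not in site_spans])
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    clones = []
    for ci in range(n_clones):
        seq = list(tmpl)
        for s in sites:
            codons = s.scheme.expand()
            seq[s.codon_start : s.codon_start + 3] = codons[rng.integers(len(codons))]
        if error_rate_per_base > 0 and len(editable):
            hits = editable[rng.random(len(editable)) < error_rate_per_base]
            for i in hits:
                seq[i] = others[seq[i]][rng.integers(3)]
        clones.append(CloneRecord(f"clone_{ci + 1}", "".join(seq), source))
    return clones
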