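"""Degenerate-codon library combinatorics and sampling statistics.

A library saturating k codons with a degenerate scheme such as NNK draws
each position uniformly from the scheme's codon expansion.  Because
amino acids are encoded by 1-3 codons within the scheme, protein variants
are sampled with unequal probabilities p_v = prod(multiplicity_i) / |codons|^k.
This module computes the induced library sizes, expected coverage of the
sequence space after screening L clones, full-coverage probabilities,
oversampling requirements and occupancy expectations — all analytically,
by grouping protein variants into multiplicity-composition classes rather
than enumerating 20^k variants.

Protein-space coverage follows the convention of treating the space as the
20^k amino-acid sequences while draws that contain a stop codon count as
wasted sampling mass (each p_v keeps the full |codons|^k denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqcore import NNK, DegenerateCodon, GeneticCode, STANDARD_CODE

__all__ = [
    "CodonExpansion",
    "LibrarySpace",
    "CoverageStats",
    "expand",
    "library_space",
    "expected_coverage",
    "full_coverage_probability",
    "clones_for_coverage",
    "expected_distinct",
    "sample_codons",
]


@dataclass(frozen=True)
class CodonExpansion:
    """Concrete expansion of a degenerate codon under a genetic code."""

    scheme: DegenerateCodon
    codons: tuple[str, ...]
    aa_multiplicity: dict[str, int]
    stop_multiplicity: int

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_amino_acids(self) -> int:
        return len(self.aa_multiplicity)

    def multiplicity_classes(self) -> dict[int, int]:
        """Map codon-multiplicity m -> number of amino acids encoded by
        exactly m codons of the scheme (NNK: {1: 12, 2: 5, 3: 3})."""
        classes: dict[int, int] = {}
        for m in self.aa_multiplicity.values():
            classes[m] = classes.get(m, 0) + 1
        return dict(sorted(classes.items()))


def expand(scheme: DegenerateCodon, code: GeneticCode = STANDARD_CODE) -> CodonExpansion:
    """Enumerate a degenerate codon and tally per-amino-acid multiplicities."""
    codons = scheme.expand()
    aa_mult: dict[str, int] = {}
    stops = 0
    for c in codons:
        if code.is_stop(c):
            stops += 1
        else:
            aa = code.translate(c)
            aa_mult[aa] = aa_mult.get(aa, 0) + 1
    return CodonExpansion(scheme, codons, aa_mult, stops)


@dataclass(frozen=True)
class LibrarySpace:
    """Size of the combinatorial space of k simultaneously saturated codons."""

    scheme: DegenerateCodon
    k: int
    codon_variants: int
    protein_variants: int
    n_amino_acids: int
    multiplicity_classes: dict[int, int]

    @staticmethod
    def _sci(n: int) -> str:
        """Two-significant-figure scientific rendering, e.g. 3.4x10^7."""
        if n == 0:
            return "0"
        exp = int(math.floor(math.log10(n)))
        mant = n / 10**exp
        mant = round(mant, 1)
        if mant >= 10:
            mant /= 10
            exp += 1
        return f"{mant:g}x10^{exp}"

    @property
    def codon_variants_sci(self) -> str:
        return self._sci(self.codon_variants)

    @property
    def protein_variants_sci(self) -> str:
        return self._sci(self.protein_variants)


def library_space(scheme: DegenerateCodon, k: int, code: GeneticCode = STANDARD_CODE) -> LibrarySpace:
    """Exact codon- and protein-variant counts for k saturated positions.

    For (NNK, 5): 32^5 = 33,554,432 codon variants and 20^5 = 3,200,000
    protein variants.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    exp = expand(scheme, code)
    return LibrarySpace(
        scheme=scheme,
        k=k,
        codon_variants=exp.n_codons**k,
        protein_variants=exp.n_amino_acids**k,
        n_amino_acids=exp.n_amino_acids,
        multiplicity_classes=exp.multiplicity_classes(),
    )


def _class_terms(exp: CodonExpansion, k: int):
    """Iterate (variant_count, p_v) over multiplicity-composition classes.

    Protein variants are grouped by how many of their k positions fall in
    each multiplicity class; for NNK there are C(k+2, 2) classes instead of
    20^k variants.  Yields exact integer counts and per-variant sampling
    probabilities p_v = prod(m_i) / n_codons^k.
    """
    classes = list(exp.multiplicity_classes().items())  # [(m, n_aa), ...]
    n = exp.n_codons

    def compositions(k: int, parts: int):
        if parts == 1:
            yield (k,)
            return
        for first in range(k + 1):
            for rest in compositions(k - first, parts - 1):
                yield (first,) + rest

    for comp in compositions(k, len(classes)):
        count = math.factorial(k)
        p_num = 1
        for c_j, (m, naa) in zip(comp, classes):
            count //= math.factorial(c_j)
            count *= naa**c_j
            p_num *= m**c_j
        yield count, p_num / n**k


def _hit_prob(p: float, L: float, method: str) -> float:
    """P(variant with per-clone probability p is seen at least once in L clones)."""
    if L <= 0 or p <= 0:
        return 0.0
    if method == "binomial":
        return -math.expm1(L * math.log1p(-p))
    if method == "poisson":
        return -math.expm1(-L * p)
    raise ValueError(f"unknown method {method!r}; expected 'binomial' or 'poisson'")


def expected_coverage(
    scheme: DegenerateCodon,
    k: int,
    L: float,
    level: str = "protein",
    method: str = "binomial",
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Expected fraction of the sequence space observed after L clones.

    level='protein' averages 1-(1-p_v)^L over the 20^k amino-acid variants
    (stop-containing draws are wasted mass); level='codon' covers the
    |codons|^k equiprobable codon variants.  Computed exactly by
    multiplicity-class grouping; never enumerates the variant space.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    exp = expand(scheme, code)
    if level == "codon":
        return _hit_prob(exp.n_codons**-k, L, method)
    if level != "protein":
        raise ValueError(f"unknown level {level!r}; expected 'protein' or 'codon'")
    total = exp.n_amino_acids**k
    acc = 0.0
    for count, p in _class_terms(exp, k):
        acc += count * _hit_prob(p, L, method)
    return acc / total


def full_coverage_probability(
    scheme: DegenerateCodon,
    k: int,
    L: float,
    level: str = "protein",
    method: str = "poisson",
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Probability that *every* variant is observed at least once.

    Computed as the product over variants of P(seen), in log space, under
    an independence approximation.  Variant hits in a fixed-L library are
    negatively correlated, so the default Poissonized model (per-variant
    hit probability 1-e^{-Lp}), in which the product is exact, is the
    better approximation; method='binomial' gives the naive fixed-L
    product, which overestimates slightly.
    """
    if L <= 0:
        return 0.0
    if k < 1:
        raise ValueError("k must be >= 1")
    exp = expand(scheme, code)
    if level == "codon":
        q = _hit_prob(exp.n_codons**-k, L, method)
        if q <= 0.0:
            return 0.0
        return math.exp(exp.n_codons**k * math.log(q))
    if level != "protein":
        raise ValueError(f"unknown level {level!r}; expected 'protein' or 'codon'")
    log_acc = 0.0
    for count, p in _class_terms(exp, k):
        q = _hit_prob(p, L, method)
        if q <= 0.0:
            return 0.0
        log_acc += count * math.log(q)
    return math.exp(log_acc)


def clones_for_coverage(
    scheme: DegenerateCodon,
    k: int,
    target_fraction: float,
    level: str = "protein",
    method: str = "binomial",
    code: GeneticCode = STANDARD_CODE,
) -> int:
    """Smallest clone count L with expected_coverage >= target_fraction.

    Bisection on the monotone coverage function; target must lie in (0, 1)
    since full coverage is only reached in the limit.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be strictly between 0 and 1")
    cov = lambda L: expected_coverage(scheme, k, L, level, method, code)
    hi = 1
    while cov(hi) < target_fraction:
        hi *= 2
        if hi > 10**15:
            raise RuntimeError("coverage target not reachable at sensible clone counts")
    lo = hi // 2 if hi > 1 else 0
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if cov(mid) >= target_fraction:
            hi = mid
        else:
            lo = mid
    return hi


def expected_distinct(scheme: DegenerateCodon, n_clones: int, code: GeneticCode = STANDARD_CODE) -> float:
    """Expected number of distinct codons seen at one saturated position
    after n uniform clones: N(1-(1-1/N)^n), the classic occupancy statistic
    (N = 32 for NNK; n = 48 gives 25.03)."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    n_cod = expand(scheme, code).n_codons
    return n_cod * -math.expm1(n_clones * math.log1p(-1.0 / n_cod))


def sample_codons(
    scheme: DegenerateCodon,
    k: int,
    n_clones: int,
    rng: np.random.Generator | int,
    code: GeneticCode = STANDARD_CODE,
) -> list[tuple[str, ...]]:
    """Draw n_clones i.i.d. genotypes, each a k-tuple of concrete codons
    sampled uniformly from the scheme expansion.  `rng` is a numpy
    Generator or an integer seed; all randomness flows through it."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    codons = expand(scheme, code).codons
    idx = rng.integers(0, len(codons), size=(n_clones, k))
    return [tuple(codons[j] for j in row) for row in idx]


@dataclass(frozen=True)
class CoverageStats:
    """Bundle of the two coverage statistics for a (scheme, k, L) query.

    The expected observed fraction and the all-variants probability answer
    different questions; published "confidence level" figures for complete
    coverage typically match the expected fraction.
    """

    scheme: DegenerateCodon
    k: int
    L: float
    level: str
    method: str
    expected_fraction: float
    full_coverage_prob: float

    @classmethod
    def compute(
        cls,
        scheme: DegenerateCodon,
        k: int,
        L: float,
        level: str = "protein",
        method: str = "binomial",
        code: GeneticCode = STANDARD_CODE,
    ) -> "CoverageStats":
        return cls(
            scheme,
            k,
            L,
            level,
            method,
            expected_coverage(scheme, k, L, level, method, code),
            full_coverage_probability(scheme, k, L, level, method, code),
        )
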