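"""Sequence primitives for circular plasmids and degenerate codons.

The toolkit works on double-stranded DNA described by its top (coding)
strand over the IUPAC nucleotide alphabet.  Plasmid templates are circular,
so coordinate arithmetic is modular and slices may span the origin.
Degenerate codons (NNK, NNS, NDT, ...) are first-class objects that expand
to their concrete codon sets under the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "IUPAC_EXPANSION",
    "IUPAC_COMPLEMENT",
    "NNK",
    "AlphabetError",
    "TopologyError",
    "CircularSeq",
    "DegenerateCodon",
    "GeneticCode",
    "STANDARD_CODE",
    "reverse_complement",
    "slice_circular",
    "translate",
]

#: Concrete-base expansion of every IUPAC nucleotide letter.
IUPAC_EXPANSION: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Watson–Crick complement of every IUPAC letter (K<->M, R<->Y, B<->V, D<->H).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class TopologyError(ValueError):
    """A circular operation was requested on a linear sequence."""


def _check_alphabet(seq: str) -> str:
    up = seq.upper()
    bad = set(up) - set(IUPAC_EXPANSION)
    if bad:
        raise AlphabetError(f"non-IUPAC nucleotide characters: {sorted(bad)!r}")
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Degenerate letters map to their complements (K<->M, R<->Y, S<->S, ...).
    Case is preserved per character, so a lowercase phosphorothioate tail
    stays lowercase in the complement.
    """
    _check_alphabet(seq)
    out = []
    for ch in reversed(seq):
        comp = IUPAC_COMPLEMENT[ch.upper()]
        out.append(comp.lower() if ch.islower() else comp)
    return "".join(out)


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if a concrete base is compatible with an IUPAC pattern letter."""
    return base.upper() in IUPAC_EXPANSION[pattern_char.upper()]


@dataclass(frozen=True)
class CircularSeq:
    """A nucleotide sequence with explicit linear/circular topology.

    Bases are canonicalized to upper case.  Indexing is 0-based; on a
    circular sequence all coordinates are taken modulo the length and
    slices wrap across the origin.
    """

    bases: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _check_alphabet(self.bases))
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be 'circular' or 'linear', got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def slice(self, start: int, length: int) -> str:
        return slice_circular(self, start, length)

    def base_at(self, i: int) -> str:
        if self.is_circular:
            return self.bases[i % len(self)]
        return self.bases[i]

    def reverse_complement(self) -> "CircularSeq":
        return CircularSeq(reverse_complement(self.bases), self.topology)

    def rotated(self, n: int) -> "CircularSeq":
        """The same circle read starting n bases further along."""
        if not self.is_circular:
            raise TopologyError("cannot rotate a linear sequence")
        n %= len(self)
        return CircularSeq(self.bases[n:] + self.bases[:n], "circular")

    def same_circle(self, other: "CircularSeq") -> bool:
        """Rotation-invariant equality of two circular sequences."""
        if len(self) != len(other):
            return False
        return self.bases in (other.bases + other.bases)

    def find_all(self, pattern: str) -> list[int]:
        """Start positions (0 <= pos < len) where `pattern` matches the top
        strand, IUPAC-aware on the pattern side; wraps the origin if circular."""
        pat = _check_alphabet(pattern)
        hay = self.bases + (self.bases[: len(pat) - 1] if self.is_circular and len(pat) > 1 else "")
        hits = []
        for i in range(len(self) if self.is_circular else len(self.bases) - len(pat) + 1):
            if all(iupac_match(p, hay[i + j]) for j, p in enumerate(pat)):
                hits.append(i)
        return hits


def slice_circular(seq: CircularSeq, start: int, length: int) -> str:
    """`length` bases starting at `start`, wrapping modulo the sequence
    length when the topology is circular.

    Raises TopologyError when the requested window runs off the end of a
    linear sequence, and ValueError for negative lengths or windows longer
    than the sequence itself.
    """
    if length < 0:
        raise ValueError("slice length must be >= 0")
    n = len(seq)
    if length > n:
        raise ValueError(f"slice length {length} exceeds sequence length {n}")
    if seq.is_circular:
        start %= n
        end = start + length
        if end <= n:
            return seq.bases[start:end]
        return seq.bases[start:] + seq.bases[: end - n]
    if start < 0 or start + length > n:
        raise TopologyError(
            f"slice [{start}, {start + length}) runs outside a linear sequence of length {n}"
        )
    return seq.bases[start : start + length]


class GeneticCode:
    """A codon -> amino acid translation table (64 entries)."""

    def __init__(self, forward_table: dict[str, str], stop_codons: set[str], name: str = "custom"):
        self.forward_table = dict(forward_table)
        self.stop_codons = set(stop_codons)
        self.name = name
        if len(self.forward_table) + len(self.stop_codons) != 64:
            raise ValueError("genetic code must cover all 64 codons")

    def translate(self, codon: str) -> str:
        """One-letter amino acid, or '*' for a stop codon.

        The codon must be concrete (non-degenerate); expand degenerate
        codons first.
        """
        c = _check_alphabet(codon)
        if len(c) != 3:
            raise ValueError(f"codon must have length 3, got {codon!r}")
        if any(len(IUPAC_EXPANSION[b]) > 1 for b in c):
            raise ValueError(f"cannot translate degenerate codon {codon!r}; expand it first")
        if c in self.stop_codons:
            return "*"
        return self.forward_table[c]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


def _standard_code() -> GeneticCode:
    from Bio.Data.CodonTable import standard_dna_table

    return GeneticCode(
        dict(standard_dna_table.forward_table),
        set(standard_dna_table.stop_codons),
        name="standard",
    )


#: The standard genetic code (61 sense codons + TAA/TAG/TGA).
STANDARD_CODE = _standard_code()


def translate(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    return code.translate(codon)


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-letter IUPAC codon pattern, e.g. NNK, NNS or NDT."""

    pattern: str
    name: str | None = None

    def __post_init__(self) -> None:
        pat = _check_alphabet(self.pattern)
        if len(pat) != 3:
            raise ValueError(f"degenerate codon pattern must have length 3, got {self.pattern!r}")
        object.__setattr__(self, "pattern", pat)

    @property
    def size(self) -> int:
        """Number of concrete codons in the expansion."""
        return len(self.expand())

    @lru_cache(maxsize=None)
    def _expansion(self) -> tuple[str, ...]:
        from itertools import product

        return tuple(
            "".join(p) for p in product(*(IUPAC_EXPANSION[b] for b in self.pattern))
        )

    def expand(self) -> tuple[str, ...]:
        """All concrete codons matched by the pattern, in lexicographic order
        of the per-letter expansions."""
        return self._expansion()

    def __contains__(self, codon: str) -> bool:
        return codon.upper() in self._expansion()

    def reverse_complement(self) -> str:
        """The pattern as it appears on the opposite strand (NNK -> MNN)."""
        return reverse_complement(self.pattern)

    def __str__(self) -> str:
        return self.name or self.pattern


#: The workhorse saturation scheme: 32 codons, all 20 amino acids, one stop (TAG).
NNK = DegenerateCodon("NNK", name="NNK")
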