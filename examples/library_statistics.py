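"""Diversity statistics of NNK saturation libraries.

NNK (N = A/C/G/T, K = G/T) spans 32 codons covering all 20 amino acids
with a single stop (amber).  Because amino acids are encoded by 1-3 NNK
codons, protein variants of a k-site library are sampled unevenly; the
expected coverage after screening L clones is the multiplicity-weighted
mean of 1-(1-p_v)^L.  The numbers below show why five simultaneously
saturated codons mark the practical limit for 1e8-clone screening.
"""

from satmut.diversity import (
    clones_for_coverage,
    expand,
    expected_coverage,
    expected_distinct,
    library_space,
)
from satmut.seqcore import NNK

exp = expand(NNK)
print(f"NNK: {exp.n_codons} codons, {exp.n_amino_acids} amino acids, "
      f"{exp.stop_multiplicity} stop; multiplicity classes {exp.multiplicity_classes()}")

for k in (5, 6):
    space = library_space(NNK, k)
    cov = expected_coverage(NNK, k, 1e8, level="protein")
    print(f"\nk={k}: {space.protein_variants_sci} protein / "
          f"{space.codon_variants_sci} codon variants")
    print(f"  expected protein-space coverage at L=1e8: {100 * cov:.1f}%")

L95 = clones_for_coverage(NNK, 5, 0.95)
print(f"\nclones for 95% coverage of the 5-site space: {L95:.3g}")
print(f"expected distinct codons per position after 48 clones: "
      f"{expected_distinct(NNK, 48):.2f} of 32")
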