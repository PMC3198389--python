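# satmut

A toolkit for **simultaneous multi-site saturation mutagenesis** with
phosphorothioate (PTO) chemistry: it designs the mutagenic primer sets,
simulates the ligase-free chemical-cleavage assembly of the resulting
fragments, computes the combinatorial statistics of the generated
degenerate-codon libraries, and QCs sequenced clone sets.

It is written for protein engineers building focused mutant libraries —
typically saturating up to five codons of a gene on a circular expression
plasmid with NNK codons — and for anyone who needs defensible numbers for
library completeness and oversampling.

## The method in brief

To saturate *k* codons at once, the plasmid is amplified as *k* fragments.
Each fragment is primed by oligos of the form

```
forward:  5'-(nt*)12-13 — anneal(>=12 nt)-3'
reverse:  5'-(nt*)12-13 — [spacer] — MNN — anneal(>=12 nt)-3'
```

where `nt*` are PTO-bonded nucleotides (lowercase on order sheets) copying
the 12–13 template bases downstream of a target codon, and `MNN` is the
reverse-strand image of the NNK saturation codon.  Iodine/ethanol cleaves
exactly the PTO-bonded 5′-terminal nucleotides, exposing mutually
reverse-complementary single-stranded overhangs at every junction; the
fragments then hybridize into one circular plasmid carrying **2 nicks per
junction** (10 for five fragments), which the host repairs after
transformation.  No restriction enzymes, ligases or minimal inter-site
distances are involved.

The library statistics rest on the NNK expansion: 32 codons encoding all
20 amino acids (12 by one codon, 5 by two, 3 by three) plus the single
amber stop.  A protein variant *v* of a *k*-site library is drawn with
probability p\_v = Π m\_i / 32^k (m\_i = codon multiplicity), so the expected
fraction of the 20^k protein space seen after screening L clones is

E[coverage] = 20^-k · Σ\_v [ 1 − (1 − p\_v)^L ]

computed exactly by grouping variants into multiplicity-composition
classes (O(k²) classes instead of 20^k terms).  The expected number of
distinct codons at one position after n clones is the occupancy statistic
32·(1 − (31/32)^n).

## Worked example

```pycon
>>> from satmut import NNK, library_space, expected_coverage, expected_distinct
>>> space = library_space(NNK, 5)
>>> space.protein_variants, space.codon_variants
(3200000, 33554432)
>>> round(100 * expected_coverage(NNK, 5, 1e8), 1)
99.6
>>> round(100 * expected_coverage(NNK, 6, 1e8), 1)
52.3
>>> round(expected_distinct(NNK, 48), 2)
25.03
```

Five NNK codons span 3.2×10⁶ protein variants; screening 10⁸ clones is
expected to reveal 99.6% of them, while a sixth site drops that to ~52% —
the quantitative reason five sites are the practical ceiling for current
screening throughput.  Sequencing 48 clones should show ≈25 of 32 codons
per position; a much lower count flags a biased library.

Designing and assembling a five-site library end to end
(`python examples/design_primers.py`, `examples/simulate_assembly.py`):

```
fragment primer    Tm(anneal) GC%   sequence
vector   E31_Fw    46.2       56.0  ctagtgcttcagCGTAAGGGGCAAG
vector   E31_Rv    49.1       50.0  gataaccactcgMNNCAAAGTGTAACCCGTC
B        T77_Fw    49.8       56.0  cgagtggttatcTTGAGCCGCCATG
...
assembled circle: True, order B-C-D-E-vector, 10 nicks
wild-type reconstruction equals template: True
```

The order sheet uses the standard rendering: lowercase = PTO bonds.  The
assembly simulation confirms the plan is self-consistent: the five
cleaved fragments form a single circle with ten nicks, and substituting
the wild-type codon at every site reconstructs the template exactly.

The other example scripts cover library statistics
(`library_statistics.py`) and clone-set QC against the packaged 48×5
codon matrix (`clone_qc_report.py`).  A thin CLI exposes the same
operations: `satmut design|assemble|stats|analyze|simulate --help`.

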