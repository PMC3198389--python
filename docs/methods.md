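# Methods

This note records the models, conventions and numerical choices behind
`satmut`, and what its synthetic fixtures do and do not establish about
real libraries.

## Primer and junction model

A target site is one codon of an ORF on a circular plasmid, addressed by
its 1-based residue index (user-facing) and its 0-based plasmid
coordinate (internal, half-open).  Each site defines a **junction**: the
12 or 13 template nucleotides that will become the single-stranded
overhang after iodine cleavage.  By default the junction linker starts
immediately 3′ of the codon (`linker_offset = 0`).  A per-site
`linker_offset` may shift it a few bases downstream; the offset bases
then ride on the reverse primer as ordinary (non-PTO) nucleotides between
the degenerate codon and the PTO tail.  Reference oligo sets in this
field use offsets of 0–6 nt, presumably to place the overhang on a more
favourable sequence; the toolkit treats the offset as data, not as a rule
to infer.

Primers follow the fixed layout `PTO-tail (12–13 nt, lowercase on order
sheets) + [spacer + MNN, reverse primers only] + 3′ anneal (≥12 nt)`.
The degenerate codon is always carried by the reverse primer; multi-codon
single primers are flagged (proximity error) but not designed.

**Melting temperature** is computed on the 3′ annealing region only,
since the 3′ end drives priming and the PTO tail/degenerate segment do
not anneal to the unmodified template.  The backend is the unified
nearest-neighbor model (Allawi–SantaLucia parameters via Biopython) at
50 mM monovalent salt and 0.4 µM primer, matching a standard PCR setup;
the Wallace 2(A+T)+4(G+C) rule is available as a fallback.  The anneal
region grows one base at a time from 12 nt until Tm reaches the target
window (63 ± 3 °C default) or 30 nt, whichever comes first; failure to
reach the window is a warning, not an error, because published primer
sets were evidently designed with web tools whose settings (and possibly
the region Tm was computed on) differ — the reference ten-oligo set reads
36–50 °C under this model and amplifies fine.  **GC content** (≥40%
default, warning below) is checked on the full oligo with fractional
counting of degenerate letters (N = 0.5, K = 0.5, S = 1, ...).

**PTO tail length** defaults to 12, extendable to 13 per site; reference
sets use both without a stated rule, so the per-site length is again
treated as data.  Design validation errors on duplicate, mutually
reverse-complementary or palindromic linkers (misassembly and
self-hybridization risks) and notes sites whose wild-type codon lies
outside the scheme (NNK cannot regenerate codons ending in A or C).

Sub-library plans restrict a full plan to a subset of sites, merging the
intervening fragments.  All primers of the full set are reused where
their junctions survive; only a junction introduced by a *new* site needs
fresh oligos, which the planner reports explicitly.

## Assembly simulation

The simulator covers amplification, cleavage and hybridization; nick
repair is abstracted as seamless.

* *Amplification* requires each primer to bind the template uniquely;
  degenerate primer positions are wildcards (a mutagenic codon anneals
  over the wild type).  The product carries the NNK imprint and the PTO
  annotations of its primers.
* *Cleavage* removes exactly the PTO-bonded 5′-terminal nucleotides of
  both strands — the chemistry is regiospecific and introduces no other
  changes — leaving the complementary strand single-stranded.  Overhangs
  are modelled as end-labelled texts; matching is by exact reverse
  complement only (12-nt perfect complementarity is the design premise;
  partial annealing is out of scope).  The naming of overhang polarity is
  a documented label, not load-bearing: assembly logic never depends on it.
* *Hybridization* builds the successor graph over overhang matches and
  reports the unique covering cycle (2 nicks per junction).  Unmatched
  overhangs yield an incomplete result; an overhang text shared by two
  junctions sets an ambiguity flag rather than picking an order —
  upstream design validation is expected to prevent this.  The result is
  invariant under permutation of the input pool (the output cycle starts
  at the lexicographically smallest fragment id), consistent with
  treating hybridization as an equilibrium rather than the experimental
  gradual-addition schedule.
* *Self-circularization* of a fragment (empty-backbone background) is
  exactly the condition that its two overhangs are mutually
  reverse-complementary, i.e. its two junction linkers are identical.
* Template removal by DpnI digestion is a pool-membership flag, not
  chemistry.

## Library statistics

`expected_coverage` groups the 20^k protein variants by how many of their
positions use 1-, 2- and 3-codon amino acids (12/5/3 of 20 for NNK) and
evaluates the class-weighted mean of 1 − (1 − p_v)^L with
p_v = Π m_i / 32^k.  Stop-containing draws are wasted sampling mass: the
denominator stays 32 per position while the space is 20^k.  This is the
convention under which the standard published coverage figures for
NNK libraries (99.6% for k = 5 at L = 10⁸; 52% for k = 6) are computed,
and both are reproduced by the acceptance tests.  The binomial hit
probability uses `expm1`/`log1p` throughout; a Poisson variant
(1 − e^{−Lp}) agrees to ≤10⁻³ at screening scales.

`full_coverage_probability` answers a different question — the chance
that *no* variant is missed — as a log-space product of per-variant hit
probabilities.  Hits in a fixed-size library are negatively correlated,
so the default uses the Poissonized per-variant probability, in which the
independence product is exact; at k = 1 it agrees with the
inclusion–exclusion answer to <0.01.  Note that published "confidence
level" figures for *completely covering* a space numerically match the
*expected fraction*, not this all-variants probability; both statistics
are exposed so users can pick deliberately.

`clones_for_coverage` inverts the monotone coverage curve by integer
bisection.  `expected_distinct` is the occupancy statistic
N(1 − (1 − 1/N)^n); for NNK and n = 48 it gives 25.03, matching the
observed mean (25.0) of the packaged 48-clone matrix.

## Clone QC

Clones of template length are compared position-wise; a length mismatch
(indel) falls back to an end-gap-free global alignment and is excluded
with a logged reason if fewer than 80% of template positions map.  Site
codons are classified into four mutually exclusive categories
(scheme / wildtype-in-scheme / wildtype-off-scheme / off-scheme); the
wildtype-off-scheme class exists because sequencing occasionally shows
wild-type codons the scheme cannot produce (synthesis errors or
polymerase proofreading over the mismatch).  Percent diversity is
distinct/32 · 100 rounded half-up to one decimal, matching printed
tables (26/32 → 81.3).  Off-target substitutions are reported with their
distance to the nearest target codon; the distance is an annotation, not
a filter — an optional exclusion window exists for masking
primer-covered regions.  The per-kb mutation frequency is mutations per
surveyed kb, half-up to two decimals (11/62.3 kb → 0.18/kb; a printed
0.17 for the same counts reflects truncation).  Duplicate genotypes are
detected on the full tuple of site codons plus off-target mutations.

## Synthetic fixtures

The fixture generator emulates a small expression plasmid: random
sequence at a set GC fraction, one non-wrapping ORF, target codons forced
to sense codons, and (optionally) pinned local contexts around each site.
The **reference fixture** pins the exact `anneal / codon / spacer /
linker / anneal` contexts implied by the published ten-oligo set of the
five-site phytase study (plus the near-neighbour site used for its
two-site sub-library), so the designer's output can be compared to that
order sheet character for character; everything between contexts is
random filler, and absolute fragment sizes therefore differ from the real
vector except where they are fixed by inter-site distances.  Default
geometry is a 2.3 kb plasmid with a 900-codon-equivalent ORF — desk scale,
chosen so the full design–assembly–QC round trip runs in milliseconds.

What passing tests show: coordinate arithmetic, primer construction,
overhang logic, assembly bookkeeping and the statistics are correct on
sequences with the declared structure.  What they do not show: behaviour
on real vectors with repeats, biased composition or secondary structure
(hairpins/dimers are out of scope), non-uniform codon synthesis, or
annealing kinetics.

## Determinism and degenerate inputs

All randomness flows through an explicit seeded `numpy` Generator; no
global state.  Degenerate letters are rejected where a concrete sequence
is required (translation, nearest-neighbor Tm) and handled fractionally
or as wildcards where the field's practice does so (GC content, primer
binding).  A single-site plan degenerates to one whole-plasmid amplicon
whose two overhangs belong to the same junction; it self-circularizes by
construction and assembles with 2 nicks.
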