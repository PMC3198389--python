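"""Design a five-site PTO primer set on the reference plasmid.

Builds the synthetic plasmid that embeds the published local contexts,
designs one mutagenic primer pair per target codon and prints the order
sheet.  Lowercase nucleotides carry phosphorothioate (PTO) bonds — the
12-13 nt that become single-stranded overhangs after iodine cleavage; MNN
is the NNK saturation codon as it reads on the reverse strand.
"""

from satmut.design import validate_design
from satmut.fixtures import reference_fixture

fx = reference_fixture(seed=0)
plans = fx.default_plan()

print(f"plasmid: {len(fx.plasmid)} bp, ORF at {fx.orf_start}, "
      f"{len(fx.sites)} target codons\n")
print(f"{'fragment':<9}{'primer':<10}{'Tm(anneal)':<11}{'GC%':<6}sequence")
for plan in plans:
    for primer in (plan.fwd_primer, plan.rev_primer):
        print(f"{plan.fragment_id:<9}{primer.name:<10}"
              f"{primer.tm_c:<11.1f}{100 * primer.gc_fraction:<6.1f}{primer.render()}")

report = validate_design(plans)
print(f"\ndesign valid: {report.is_valid}")
for issue in report.issues:
    print(f"  [{issue.level}] {issue.message}")
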