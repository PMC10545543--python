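"""Screen-design arithmetic: coverage, cell numbers and MOI.

Reproduces the back-of-envelope numbers behind a genome-wide in vivo
screen: how many cells a library needs at a target coverage, what coverage
a transduction actually achieves, and why the MOI is kept below 0.3.
"""

from cnscreen import expected_coverage, multi_integration_fraction, plan_coverage

# Validation library: 12,000 guides at 1,000 cells per guide.
cells_needed = plan_coverage(12_000, 1_000)
print(f"validation screen, 12,000 guides at 1,000x: {cells_needed:,} cells")

# Genome-wide transduction: 300e6 T cells at MOI 0.3 over 88,490 guides
# (87,690 targeting + 800 non-targeting controls).
cov = expected_coverage(300e6, 0.3, 88_490)
print(f"genome-wide transduction: {cov:.0f} cells per sgRNA (target was ~1,000x)")

# At MOI 0.3 only a small minority of transduced cells carry two guides,
# which keeps the guide-to-phenotype mapping clean.
for moi in (0.1, 0.3, 1.0):
    frac = multi_integration_fraction(moi)
    print(f"MOI {moi:.1f}: {100 * frac:.1f}% of transduced cells carry >1 integration")
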