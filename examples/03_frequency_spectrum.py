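"""Characterize the CEH frequency spectrum of a phased cohort.

Shows the hallmark skew of the MHC: a handful of very common conserved
haplotypes carrying a fifth of all copies next to a long singleton tail.
"""

from cehkit.phasing import phase_dataset
from cehkit.simulate import DatasetConfig, default_pool, generate_dataset
from cehkit.spectrum import build_spectrum, coverage_curve, spectrum_summary

pool = default_pool(seed=0)
records, _ = generate_dataset(DatasetConfig(pool=pool, n=3000), seed=3)
result = phase_dataset(records)
spectrum = build_spectrum([dip for dip, _ in result.assignments.values()])

summary = spectrum_summary(spectrum, top_k=(10, 25), multiplicity_cutoffs=(1, 2))
print(f"{spectrum.total_copies} haplotype copies, {spectrum.n_unique} unique CEHs")
for k, (copies, pct) in summary.top_k.items():
    print(f"top {k:>3} CEHs: {copies} copies ({pct:.0f}% of total)")
n1, pct_u, copies1, pct_c = summary.multiplicity[1]
print(f"singletons: {n1} ({pct_u:.0f}% of unique CEHs, {pct_c:.0f}% of copies)")

curve = coverage_curve(spectrum)
for n_unique, cum in curve[:3]:
    print(f"first {n_unique} CEH(s) cover {cum:.1f}% of all copies")
# The cumulative curve rises steeply then flattens: most copies belong to a
# small set of highly selected haplotypes, most unique haplotypes are rare.
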