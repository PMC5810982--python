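"""Conditional carrier odds ratios with motif exclusion.

Tests each common CEH for disease association as "1 copy versus 0 copies",
excluding carriers of the dominant Class II risk motif
DRB1*15:01~DQB1*06:02~a1 (except when the tested CEH itself bears it),
then applies Benjamini-Hochberg and Bonferroni corrections.
"""

import numpy as np

from cehkit.association import (
    MultiplicityContext, UndefinedORError, adjust_pvalues, conditional_carrier_or,
)
from cehkit.catalog import RISK_MOTIF
from cehkit.phasing import phase_dataset
from cehkit.simulate import DatasetConfig, default_pool, generate_dataset
from cehkit.spectrum import build_spectrum

pool = default_pool(seed=0)
records, _ = generate_dataset(DatasetConfig(pool=pool, n=4000), seed=4)
result = phase_dataset(records)
dips = [dip for dip, _ in result.assignments.values()]
y = np.array([r.phenotype for r in records if r.sample_id in result.assignments])

spectrum = build_spectrum(dips)
rows = []
for hap, count in spectrum.ranked():
    if count < 50:  # analyze haplotypes with at least 50 copies
        break
    try:
        res = conditional_carrier_or(dips, y, hap, copies=1, exclusion=RISK_MOTIF)
    except UndefinedORError:
        continue
    rows.append((hap.key, count, res))

ctx = MultiplicityContext(m=len(rows), method="benjamini-hochberg")
adjusted = adjust_pvalues([r.p_value for _, _, r in rows], ctx)
print(f"{len(rows)} CEHs tested; Bonferroni threshold 0.05/{len(rows)} = "
      f"{0.05 / len(rows):.1e}")
for (key, count, res), p_bh in zip(rows[:8], adjusted.adjusted[:8]):
    print(f"  {key[:58]:<58} n={count:<5} OR={res.odds_ratio:4.1f} "
          f"({res.ci_low:.1f}-{res.ci_high:.1f}) p_BH={p_bh:.2g}")
# Risk-motif CEHs show OR near their programmed per-copy effects (~2-4);
# protective haplotypes fall below 1; the exclusion rule keeps the dominant
# motif from contaminating the reference group.
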