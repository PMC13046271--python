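"""Differential CUT&Tag enrichment over categorized genomic regions.

Simulates negative-binomial counts for shared / condition-unique peaks
and no-peak 500-bp bins with a +1 log2 fold change confined to shared
peaks, normalizes by spike-in x H3 size factors, runs the NB Wald test
(~ replicate + condition) with the basemean > 25 filter and BH
adjustment, and summarizes significant changes per category.
"""

import pandas as pd

from phasequant.cuttag import (
    compute_size_factors, nb_differential, summarize_categories,
)
from phasequant.synthetic import CountSimSpec, generate_counts

spec = CountSimSpec(seed=4, true_lfc={"shared": 1.0})
table, sheet, h3 = generate_counts(spec)
print(f"simulated {len(table)} regions x {len(sheet)} samples "
      f"(true +1 log2FC in shared peaks only)")

factors = compute_size_factors(
    pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
    h3,
    h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
)
print("combined size factors:",
      [f"{v:.3f}" for v in factors.combined])

result = nb_differential(table.drop(columns="true_lfc"), sheet, factors)
shared = result.table[result.table["category"] == "shared"]
print(f"mean raw log2FC in shared peaks: {shared['log2fc_raw'].mean():.3f}")

print(summarize_categories(result).to_string(index=False,
      float_format=lambda v: f"{v:.1f}"))
print("-> only the shared category shows a large significant-up percentage;")
print("   no-peak bins behave as nulls, showing the test's error control.")
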