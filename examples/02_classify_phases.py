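"""Classify nuclear pixels into cell cycle phases with FUCCI reporters.

Derives the GFP/RFP thresholds from five reference early S-phase nuclei
(the published rule), classifies every nuclear pixel, and compares the
per-phase area fractions with the generator's phase proportions.
"""

import dataclasses

import numpy as np

import phasequant as pq
from phasequant.fucci import PHASES
from phasequant.synthetic import DiscSpec, generate_disc

spec = dataclasses.replace(DiscSpec(seed=2), noise_sd=0.0)
disc = generate_disc(spec)

early_s = disc.truth_nuclei.query("phase == 2")["nucleus_id"].to_numpy()[:5]
thresholds = pq.derive_thresholds(
    disc.channels["GFP"], disc.channels["RFP"], disc.truth_labels,
    nucleus_ids=early_s,
)
print(f"thresholds from 5 early-S nuclei: GFP={thresholds.gfp_threshold:.1f}, "
      f"RFP={thresholds.rfp_threshold:.1f} a.u.")

labels = pq.classify_pixels(
    disc.channels["GFP"], disc.channels["RFP"], thresholds,
    disc.nuclear_truth_mask(),
)
fractions = pq.phase_fractions(labels)
for phase, frac, true in zip(PHASES, fractions, spec.phase_proportions):
    print(f"  {phase.name:8s} area fraction {frac:.3f}  (generator {true:.2f})")
print("-> each nuclear pixel is assigned by the two-threshold rule; area")
print("   fractions recover the simulated phase mix (small deviations come")
print("   from nucleus-size variation and the finite nucleus count).")
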