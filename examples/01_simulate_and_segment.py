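"""Generate a synthetic wing disc and segment its nuclei.

Builds a 500-nucleus two-compartment disc image, runs the DAPI
segmentation chain (rolling-ball background subtraction, CLAHE, Otsu
threshold) and compares the mask against the generator's ground truth.
"""

import numpy as np

import phasequant as pq
from phasequant.synthetic import DiscSpec, generate_disc

spec = DiscSpec(seed=1)
disc = generate_disc(spec)
print(f"disc: {spec.image_shape[0]}x{spec.image_shape[1]} px, "
      f"{len(disc.truth_nuclei)} nuclei, channels {list(disc.channels)}")

mask = pq.make_nuclear_mask([disc.channels["DAPI"]], workflow="dapi_otsu")
truth = disc.nuclear_truth_mask()
jaccard = (mask.mask & truth).sum() / (mask.mask | truth).sum()

print(f"nuclear mask: {mask.area()} px (truth {truth.sum()} px)")
print(f"Jaccard vs ground truth: {jaccard:.4f}")
print("-> at the default 5 a.u. noise the ImageJ-style chain recovers the")
print("   nuclear area almost pixel-perfectly; values > 0.95 mean the")
print("   downstream per-pixel statistics see essentially the true nuclei.")
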