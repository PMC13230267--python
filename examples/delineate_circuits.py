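"""Delineate monoaminergic circuits from receptor/transporter densities.

Simulates normalised per-region density maps — two with a sharp elbow in
their sorted density curve, one linear (no elbow), and one duplicating
another map's top regions — applies coverage-based region QC, and cuts each
map at its elbow (or at the top 5% for the linear map).  Maps selecting
identical member sets are reported jointly, the way overlapping D2 and DAT
circuits are.
"""

import numpy as np
import pandas as pd

from netswitch.parcellation import build_circuits, detect_elbow, exclude_regions
from netswitch.synthetic import generate_density, make_region_table

regions = make_region_table(224, 8)
ids = list(regions["region_id"])

# coverage QC: every region fine except 22 with poor coverage in 15% of subjects
coverage = pd.DataFrame(1.0, index=[f"s{i}" for i in range(20)], columns=ids)
rng = np.random.default_rng(0)
for col in rng.choice(224, size=22, replace=False):
    coverage.iloc[:3, col] = 0.2
retained, log = exclude_regions(coverage)
print(f"region QC: {len(retained)} of {len(ids)} regions retained "
      f"({len(log)} excluded for <30% coverage in >10% of participants)")

d2 = generate_density(224, 12, elbow_sharpness=5, seed=1, region_ids=ids,
                      map_name="D2")
dat = generate_density(224, 12, elbow_sharpness=5, seed=1, region_ids=ids,
                       map_name="DAT")        # same seed: same top regions
ht1a = generate_density(224, 9, elbow_sharpness=4, seed=2, region_ids=ids,
                        map_name="5-HT1a")
nat = generate_density(len(retained), 11, elbow_sharpness=1, seed=3,
                       region_ids=retained,
                       map_name="NAT")        # linear: top-5% fallback

for dv in (d2, ht1a, nat):
    e = detect_elbow(dv.restrict(retained))
    kind = "linear (top-5% fallback)" if e.is_linear else f"elbow at rank {e.cutoff_rank}"
    print(f"  {dv.map_name:>7}: sorted density curve is {kind}")

circuits = build_circuits([d2, dat, ht1a, nat], retained)
print("\ncircuits (name: number of member regions):")
for name, members in circuits.circuits.items():
    merged = " [merged: identical member sets]" if name in circuits.merged_from else ""
    print(f"  {name:>7}: {len(members)} regions{merged}")
print("\nEach circuit is the set of highest-density regions for one "
      "receptor/transporter map, restricted to QC-passing regions.")
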