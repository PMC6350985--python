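"""Human-mouse conserved binding-region classification.

Generates mouse Gli1/Gli3-like interval sets (in human coordinates, with
intensities drawn from the published Normal parameters), applies the strict
>3.0 Gli3 intensity filter, and bins every mouse region by its membership
vector over (human GLI1, human GLI2, mouse Gli1, mouse Gli3) occupancy.
"""

from glibind import conservation_bins, filter_mouse_intensity, percentage
from glibind.simulate import MOUSE_GLI1_INTENSITY, MOUSE_GLI3_INTENSITY, generate_region_sets

lengths = {"chr1": 10_000_000}
hg1, _ = generate_region_sets([], 300, 0.0, lengths, seed=8, width=250, label="hG1")
hg2, _ = generate_region_sets(hg1, 300, 0.4, lengths, seed=9, width=250, label="hG2")
mg1, _ = generate_region_sets(hg1, 150, 0.4, lengths, seed=10, width=200, label="mG1",
                              intensity=MOUSE_GLI1_INTENSITY)
mg3, _ = generate_region_sets(hg1, 400, 0.4, lengths, seed=11, width=200, label="mG3",
                              intensity=MOUSE_GLI3_INTENSITY)

kept = filter_mouse_intensity(mg3, cutoff=3.0)
print(f"Gli3 intensity filter (>3.0): kept {len(kept)}/{len(mg3)}"
      f" = {percentage(len(kept), len(mg3))}% (expected > 75%)")

bins = conservation_bins(hg1, hg2, mg1, kept, d=250)
print("conservation bins (p/q/pq = mouse-only; r..z = human-overlapping):")
for letter, count in sorted(bins.counts.items()):
    print(f"  {letter}: {count}")
print("total =", sum(bins.counts.values()), "=", len(mg1), "+", len(kept))
# Bins are disjoint and exhaustive: counts sum to the mouse-region universe.
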