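"""Chromosome-territory adjacency in a synthetic bead-chain nucleus.

A modelled nucleus (spherical envelope, diameter 7.3 um) holds 24
bead-chain chromosome territories plus a nucleolus; each chain's middle
bead is its centromere.  Re-centering on the centromere of one chromosome
and conifying ranks every other territory by how close its nearest bead
comes, and in which direction it lies.
"""

from dpc12 import (
    compute_profile,
    farthest_object,
    full_conify,
    make_bead_chain_nucleus,
    nearest_object,
    render_dpc12,
    render_guides,
)
from dpc12.chart import save_chart

scene = make_bead_chain_nucleus()  # seed 0 defaults
central = "5'"
conified = full_conify(scene, central, anchor_mode="object_anchor")
profile = compute_profile(conified)

print(f"central object: chromosome {central} (anchor = its centromere bead)")
print(f"profile entries: {len(profile.entries)} (cone, object) pairs\n")

print("five nearest territories (min bead distance from the centromere, um):")
for obj, d, cone in nearest_object(profile)[:5]:
    print(f"  {obj:>10}: {d:5.2f} in {cone}")
obj, d, cone = farthest_object(profile)[0]
print(f"farthest territory: {obj} (its nearest bead is {d:.2f} um away, in {cone})")

fig = render_dpc12(profile, out=None)
render_guides(fig, [1.0, 2.0, 4.0])  # ruler-guide baselines
save_chart(fig, "nucleus_5p.png")
print(
    "\nchart written to nucleus_5p.png; the y-axis tops out at the envelope\n"
    "diameter (7.3 um), the largest possible separation inside the nucleus."
)
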