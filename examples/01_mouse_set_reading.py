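"""Reading a DPC12 chart on the instructional Mouse 3D Set.

Three balls — a head (H) and two ears (LE, RE) placed asymmetrically above
it — are conified with the head as the central object.  The printed
profile rows give, per cone and object, the min/max distance from the
head's centroid and the fraction of the object inside the cone; the
rankings at the end recover the construction (the left ear was placed
closer) from the chart data alone.
"""

from dpc12 import (
    compute_profile,
    farthest_object,
    full_conify,
    make_m3ds,
    nearest_object,
    profile_to_table,
    render_dpc12,
)

scene = make_m3ds()  # objects LE, H, RE; left ear closer by construction
conified = full_conify(scene, central_object_id="H", anchor_mode="centroid")
profile = compute_profile(conified)

table = profile_to_table(profile)
print(table[table.obj_id != "H"].to_string(index=False, float_format="%.3f"))

near = nearest_object(profile)
far = farthest_object(profile)
print(f"\nnearest object:  {near[0][0]} (min distance {near[0][1]:.3f} in {near[0][2]})")
print(f"farthest object: {far[0][0]} (min distance {far[0][1]:.3f} in {far[0][2]})")
print(
    "\nBoth ears sit in TOP cones on opposite sides; the ranking recovers the\n"
    "15% placement asymmetry (LE nearer than RE) from anchor distances alone."
)

render_dpc12(profile, out="m3ds_head.png")
print("chart written to m3ds_head.png")
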