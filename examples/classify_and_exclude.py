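"""Pixel classification and epithelial-nucleus exclusion on a tiny fixture.

Builds the deterministic 64x64x6 demonstration stack (which contains one
bright compact epithelial nucleus on slice 4), classifies every pixel as
viable / non-viable / background, and shows how excluding the nucleus
changes the slice's bacterial viability.
"""

from bvquant import (
    classify_stack,
    exclude_epithelial,
    find_red_components_stack,
    flag_epithelial,
    fixture_small,
)

stack, _ = fixture_small()
classmap = classify_stack(stack)

components = find_red_components_stack(classmap, stack.red)
flagged = flag_epithelial(components)
classmap_clean, report = exclude_epithelial(classmap, flagged)

print("red-dominant components per slice:")
for c, is_nucleus in flagged:
    tag = "  <- flagged as epithelial nucleus" if is_nucleus else ""
    print(
        f"  slice {c.slice_index}: area {c.area_px:4d} px, "
        f"solidity {c.solidity:.2f}, mean red {c.mean_red:5.1f}{tag}"
    )

print("\nslice 4 viability (the nucleus slice):")
row = report.per_slice.iloc[4]
print(f"  BV before exclusion: {row['bv_before']:.1f} %")
print(f"  BV after  exclusion: {row['bv_after']:.1f} %")
print(f"  excluded pixels:     {int(row['excluded_px'])}")
print(
    "\nThe nucleus satisfied all three criteria (area > 200 px, solidity"
    " > 0.70, mean red >= 180), so its pixels left the non-viable count and"
    " the slice's bacterial viability rose accordingly."
)
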