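"""Porosity of a segmented membrane panel: holes, passability, binning.

Generates a cortical-side panel (~7.85% open, lognormal hole areas,
100/11 nm/px calibration), detects every hole, applies the 490 nm^2
microtubule passability cutoff, and prints the binned distribution.
"""

from centmorph import (PanelSpec, as_printed, bin_distribution, extract_holes,
                       make_panel, min_passable_area, passable_holes)

panel, truth = make_panel(PanelSpec(seed=5))
holes = extract_holes(panel)
cutoff = min_passable_area(25.0)
passable = passable_holes(holes, cutoff)
dist = bin_distribution(holes)

print(f"panel: {panel.mask.shape[1]}x{panel.mask.shape[0]} px at "
      f"{panel.pixel_size:.2f} nm/px ({panel.side}, {panel.phase})")
print(f"holes detected        : {holes.n} (truth {truth.n})")
print(f"open fraction         : {holes.open_fraction:.2f}%")
print(f"passability cutoff    : {as_printed(cutoff)} nm^2 (25-nm microtubule)")
print(f"passable holes        : {passable.n} "
      f"({100 * passable.n / holes.n:.0f}% of holes, "
      f"{passable.open_fraction:.2f}% of panel area)")
print("bin            % holes   % open area")
for label, cp, ap in zip(dist.labels, dist.counts_percent, dist.area_percent):
    print(f"{label:>12}   {cp:7.1f}   {ap:10.1f}")
print("Most holes are below the passability cutoff: the membrane admits "
      "only a minority of microtubules.")
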