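"""Classify microtubule traces crossing the centriculum and compare angles.

Generates a slab of 106 stopped and 21 continuing microtubules (the
cortical-side mixture) with angular spreads of 25 deg and 8 deg about
the radial vector, classifies each trace against the interior/exterior
boundary lines, and compares the angle distributions.
"""

from centmorph import SlabSpec, angle_summary, classify_trace, make_slab

traces, interior, exterior, truth = make_slab(SlabSpec(seed=1))
classifications = [classify_trace(t, interior, exterior) for t in traces]
summary = angle_summary(classifications)

for cat in ("stopped", "continuing"):
    s = summary[cat]
    print(f"{cat:>10}: n={s['n']:3d}  angle {s['mean']:5.1f} +/- {s['sd']:4.1f} deg")
cmp = summary["comparison"]
print(f"comparison: {cmp.test}, p = {cmp.p:.2e}")
print("Continuing microtubules hug the radial vector (the shortest path "
      "through the membrane); stopped ones are broadly distributed — the "
      "signature of a passive geometric filter.")
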