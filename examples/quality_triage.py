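"""Triage image quality into good / usable / reject.

Renders one clean, one blurred, and one dark synthetic fundus image and
prints the gate's label with the three metrics it is based on. Only good
and usable images enter training datasets.
"""

import numpy as np

import fundusdr as f

spec = f.SyntheticSpec(seed=5)
samples = {
    qc: f.generate_fundus(spec, 0, quality_class=qc, rng=np.random.default_rng(5))
    for qc in ("good", "usable", "reject")
}

print(f"{'rendered as':<12}{'gate label':<12}{'foreground':<12}{'sharpness':<12}mean value")
for qc, s in samples.items():
    label, m = f.assess_quality(s.image)
    print(f"{qc:<12}{label:<12}{m.foreground_fraction:<12.3f}"
          f"{m.sharpness:<12.1f}{m.mean_value:.1f}")

kept = f.filter_usable(list(samples.values()), image_of=lambda s: s.image)
print(f"\nfilter_usable keeps {len(kept)} of {len(samples)} images "
      "(the dark, blurry one is excluded from any dataset).")
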