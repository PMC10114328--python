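"""Run the preprocessing SOP on one synthetic bordered fundus photograph.

Shows each step of the pipeline (border auto-crop, circular crop, quality
gate, HSV equalization, resize) and how the geometry changes.
"""

import fundusdr as f

sample = f.generate_fundus(f.SyntheticSpec(seed=42, border_width=16), label=1)
print(f"input image:    {sample.image.shape[0]}x{sample.image.shape[1]}, "
      f"{len(sample.lesion_centers)} lesions")

cropped = f.autocrop(sample.image, tolerance=7)
print(f"after autocrop: {cropped.shape[0]}x{cropped.shape[1]} "
      "(the 16-pixel black frame is gone)")

result = f.run_sop(sample.image, f.SOPConfig(output_side=224))
print(f"full SOP:       {result.image.shape[0]}x{result.image.shape[1]}, "
      f"quality={result.quality_label}, rejected={result.rejected}")
print("steps applied: ", " -> ".join(result.steps))
print(f"corner pixel {tuple(int(v) for v in result.image[0, 0])} is black: the retina sits as a "
      "centered disc, so resizing cannot deform it.")
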