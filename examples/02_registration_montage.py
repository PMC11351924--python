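"""Register the five fields of a synthetic eye back into a panorama.

The capture plan's transforms are known ground truth, so the recovered
field-to-panorama transforms can be scored directly: the printed errors are
how far each estimated transform places the field from where the generator
actually put it (sub-pixel is expected).
"""

import math

from ropmap import GeneratorConfig, compose_montage, default_field_plan, generate_eye, render_fields

config = GeneratorConfig()
eye = generate_eye(config, seed=42)
rendered = render_fields(eye, default_field_plan(eye, config))

montage = compose_montage(rendered.rasters, anchor="f0")
print(f"montage over {len(montage.transforms)} fields (excluded: {montage.excluded or 'none'})")
for spec in rendered.plan:
    true = spec.transform_to_panorama
    got = montage.transforms[spec.field_id]
    terr = math.hypot(got.translation[0] - true.translation[0], got.translation[1] - true.translation[1])
    rerr = abs(math.degrees(got.rotation - true.rotation))
    print(f"  {spec.field_id} ({spec.orientation_label}): translation error {terr:.3f} px, "
          f"rotation error {rerr:.4f} deg")
print("pairwise alignment scores (correlation of band-passed overlap):")
for pair, score in sorted(montage.scores.items()):
    print(f"  {pair}: {score:.3f}")
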