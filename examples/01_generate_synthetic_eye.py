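"""Generate one synthetic eye and render its five-field capture.

Prints the ground truth (landmarks, lesions with their zones, plus status)
and saves the disc-centered field as a PNG.  The lesion list is what a
perfect detector would report; `true_zone` is the zone of each lesion center
under the eye's ICROP geometry.
"""

from ropmap import GeneratorConfig, default_field_plan, generate_eye, render_fields
from ropmap.io import save_raster

config = GeneratorConfig()
eye = generate_eye(config, seed=42)
rendered = render_fields(eye, default_field_plan(eye, config))

print(f"eye {eye.eye_id}: {eye.laterality}, plus={eye.plus_present}")
print(f"  disc ({eye.disc_center[0]:.1f}, {eye.disc_center[1]:.1f}), "
      f"fovea ({eye.fovea_center[0]:.1f}, {eye.fovea_center[1]:.1f}), "
      f"nasal ora radius {eye.ora_radius_nasal:.1f} px")
print(f"  vessels: tortuosity amplitude {eye.tortuosity_amp:.2f} px, width {eye.vessel_width:.2f} px")
for i, lesion in enumerate(eye.lesions):
    print(f"  lesion {i}: type {lesion.lesion_type} at "
          f"{tuple(round(v, 1) for v in lesion.center)} -> zone {lesion.true_zone}, "
          f"seen in fields {rendered.visibility[i]}")

save_raster("disc_centered_field.png", rendered.rasters["f0"])
print("wrote disc_centered_field.png (640x480, the montage anchor)")
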