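"""Vessel tortuosity and the plus-disease scorer.

First the arc/chord tortuosity index on shapes with known answers (straight
line -> 1, semicircle -> pi/2), then the full scorer on two rendered eyes:
one with the normal vessel regime and one with the elevated plus regime
(higher sinusoid amplitude and caliber).  The logistic score uses the
standardized mean tortuosity and mean width within zone I.
"""

import math

import numpy as np

from ropmap import GeneratorConfig, classify_plus, extract_centerlines, generate_eye, tortuosity_index
from ropmap.synthetic import FieldSpec, render_fields
from ropmap.transforms import SimilarityTransform

print(f"straight segment: {tortuosity_index(np.array([[0., 0.], [100., 0.]])):.4f}")
theta = np.linspace(0, math.pi, 2000)
print(f"semicircle:       {tortuosity_index(np.c_[np.cos(theta), np.sin(theta)]):.4f} (pi/2 = {math.pi/2:.4f})")

for label, prevalence, seed in (("normal vessels", 0.0, 10), ("plus regime", 1.0, 11)):
    eye = generate_eye(GeneratorConfig(plus_prevalence=prevalence), seed)
    rendered = render_fields(eye, [FieldSpec("f0", "disc-centered", SimilarityTransform.identity())])
    centerlines = extract_centerlines(rendered.rasters["f0"], disc_center=eye.disc_center)
    result = classify_plus(centerlines, eye.frame)
    f = result.features
    print(f"{label}: {len(centerlines)} vessels traced; "
          f"mean tortuosity {f['mean_tortuosity']:.4f}, mean width {f['mean_width']:.2f} px "
          f"-> score {result.score:.3f}, plus={result.plus} (truth: {eye.plus_present})")
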