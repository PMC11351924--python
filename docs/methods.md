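# Methods

## Scope and model

`ropmap` reproduces the clinical ROP grading chain as deterministic,
auditable computation. The unit of analysis is the eye. Inputs are per-field
lesion detections (axis-aligned boxes with a type 1–4 and a confidence),
per-field rasters or field→panorama transforms, and disc/fovea landmarks;
outputs are a per-eye `(stage, zone, plus, severity)` assessment with an
evidence trail, and cohort-level agreement metrics.

The pipeline assumes: (i) fields of one eye are related to the disc-centered
anchor field by 2-D similarity transforms (scale, rotation, translation) —
adequate at the overlap and field-of-view of wide-field captures, though a
real camera adds lens distortion this model ignores; (ii) lesion identity
across fields can be recovered geometrically (same type, overlapping or
nearby re-projections); (iii) landmarks are given (by the generator or the
annotation file) — automatic disc/fovea detection is out of scope.

## Zone geometry

Zones are concentric disc-centered regions. With `d` the disc–fovea distance
and `R` the radius of the disc-centered circle through the nasal ora
serrata: zone I is `r ≤ 2d`, zone II is `2d < r ≤ R`, zone III is `r > R`.
Two deliberate simplifications: zone III is modeled as everything beyond the
zone II circle (anatomically it is only the temporal crescent; the synthetic
generator only places zone III lesions temporally, so the simplification is
unobservable in generated data), and boundary radii resolve inward, i.e.
toward the more posterior and therefore more severe zone — the tie-break a
screening system should prefer. The eye-level zone follows the most severe
lesion; when several lesions tie on type, the most posterior zone among them
wins. A config switch (`most_posterior_overall`, default off) instead takes
the most posterior lesion regardless of type, which is closer to some
clinical practice; the default follows the stage-linked reading. The lesion
reference point is the mapped box center, which a similarity transform
preserves exactly.

## Severity rules

Severe (treatment-requiring) iff any staged lesion in zone I, stage 2 in
zone II with plus, stage 3 in zone II, or stage 4 anywhere; everything else
is not severe. The rules are evaluated in that order and the first match is
reported as `rule_fired`, so every severe call is traceable. Stage 5 is
outside the rule set (such eyes go straight to treatment, not screening) and
is rejected loudly. Plus disease with stage 0 has no rule; the eye is called
not severe but flagged (`plus_without_staged_lesions`) so the finding stays
visible. The exhaustive 26-row table (`rule_table()`) exports as CSV for
clinician review.

For ROC analysis a continuous severity score accompanies the binary call:
1.0 when a rule fires, otherwise `0.99 × (0.6·plus_score + 0.4·c)` where `c`
is the highest detection confidence among zone I/II lesions. The 0.99 factor
keeps rule-positive eyes strictly above every graded-tail eye; without it an
eye with a saturated plus score and a confident (but rule-negative) lesion
could tie the rule-positive eyes at 1.0 and the zero-noise AUC of 1 would be
unattainable on ties alone. Weights live in `RunConfig`.

## Registration

Pairwise similarity estimation is classical and deterministic: ORB keypoints
matched across the two rasters with a RANSAC similarity fit (seeded, hence
reproducible) provide the initial model; if feature matching fails, a
log-polar resampling of the Fourier magnitudes gives rotation/scale and
phase correlation the translation. Either initialization is polished by a
coarse-to-fine Nelder–Mead maximization of the Pearson correlation of the
band-passed overlap (band-passing strips the smooth vignette, which would
otherwise dominate and let grossly wrong alignments score well). The final
correlation is the alignment score in [0, 1]; below threshold (default
0.25) the pair raises an alignment failure carrying the score.

Global transforms chain pairwise estimates along a maximum-score spanning
tree rooted at the disc-centered anchor (identity transform, so panorama
coordinates are the anchor field's). No bundle adjustment — at five fields
the tree is one or two hops deep and measured recovery is ~0.1 px; per-edge
scores are reported so weak links stay visible. Fields unreachable in the
overlap graph are excluded and named; an assessment that lost all non-anchor
fields is flagged degraded rather than failed. Externally supplied
transforms (e.g. a learned registration model) plug in wherever estimated
ones are used.

Detections re-project by mapping box corners and taking the axis-aligned
hull. Under rotation the hull is larger than the tight rotated box —
unavoidable for axis-aligned output — but the center maps exactly, and
zoning consumes only centers. Duplicates from overlapping fields merge when
they share a type and either their centers are within `merge_radius`
(default 15 px, a quarter disc diameter) or their boxes overlap by at least
half the smaller area; the second clause exists because a box clipped at a
field edge has a displaced center that can escape any fixed radius. The
representative is the highest-confidence detection, ties going to the
larger (least clipped) box, then to the detection most central in its
source field. The merge is idempotent.

## Plus disease

The scorer uses the two features the clinical definition names: tortuosity
and dilation. Centerlines come either from pixels — Otsu threshold in the
R−G channel (where rendered vessels separate from background, disc and
glyphs), disc neighbourhood cleared, skeletonization, per-point caliber from
the Euclidean distance transform, branches traced by double-BFS over the
skeleton graph (spurs fall off the longest path), segments under 20 px
discarded — or as serialized analytic polylines. Features are computed on
the portions inside zone I: mean arc/chord tortuosity index across
centerlines and mean caliber in px. The score is a logistic function of the
standardized features; `plus = score ≥ 0.5`. No traceable vessels yields an
*indeterminate* result, distinct from negative and flagged downstream.

Coefficients are fit once on a balanced, seeded calibration set of 200
synthetic disc-centered fields and frozen in `plus_calibration.json`; they
are never refit at run time and `calibrate()` regenerates the file exactly.
Raster-extracted features carry a small positive bias (skeleton jaggedness
inflates tortuosity; stroke rasterization inflates caliber), so the file
holds one calibration per feature provenance (`raster`, `centerline`) and
the caller selects the matching one. Both slopes must come out non-negative
— asserted after fitting — which guarantees the score is monotone in each
feature. This scorer is a transparent, desk-scale stand-in for trained
plus-disease classifiers and makes no claim of equivalence to them.

## Synthetic generator

The generator is the study's data source, not a fixture: seeded,
self-consistent, and exact. Geometry is fixed at disc diameter 60 px,
disc–fovea distance ~140–160 px, nasal ora radius 3.0–3.2× the disc–fovea
distance, fields 640×480. Laterality mirrors the nasal direction (+x for
OD, −x for OS; the fovea is temporal). Per-type lesion counts are Poisson
with means (0.6, 0.5, 0.25, 0.08) for types 1–4 and plus prevalence is
0.15 — chosen once to echo a screening cohort in which most eyes are mild,
stage 4 is rare, and roughly a fifth to a quarter of eyes meet severity
criteria. Lesion centers are placed with an outward-biased radial law (zone
I disease rare), except a 12% fraction placed in the temporal crescent just
beyond the zone II circle (starting at 1.02×R so that even an edge-clipped
box center cannot drift across the boundary). Every generated lesion's
`true_zone` is recomputed through the zoning module before the eye is
returned.

Vessels are eight centerlines leaving the disc with uneven angular spacing
(evenly spaced rays plus per-vessel jitter of ±12°), each a ray with a
sinusoidal normal displacement of amplitude `tortuosity_amp` (wavelength
80 px) stroked at width `vessel_width`. Plus eyes draw amplitude from
4–8 px and width 5–7 px; normal eyes 0–1.5 px and 3–4 px. The uneven
spacing matters beyond realism: perfectly even rays make the rendered eye
nearly invariant under a 180° rotation about the disc, which plants a
genuine second optimum in pairwise registration.

Rendering draws the panorama-space scene once per eye — textured background
(smooth mottle plus fine grain, which is what registration locks onto), a
peripheral vignette, disc with cup, fovea, vessels, and type-coded lesion
glyphs (line / arc / arc with texture dots / filled wedge) — then samples
each field through its known transform. Glyphs are deliberately
non-photorealistic: the pipeline consumes detections, and rasters only need
to support registration and vessel extraction. The default capture plan is
five fields (disc-centered anchor plus nasal/temporal/superior/inferior at
±220/±185 px with rotation ±5° and scale 0.97–1.03), overlapping the anchor
by well over 25%.

The oracle detector applies noise per lesion — miss, type confusion
(row-stochastic 4×4), center jitter — with draws keyed on (seed, eye seed,
lesion index), so every field that sees a lesion reports it consistently
and sweeps over noise levels share common random numbers (a lesion missed
at rate 0.2 is also missed at 0.4). False positives are Poisson per field.
With all noise zero the detections equal ground truth exactly, which is
what makes the zero-noise identifiability check meaningful: any error it
finds was introduced by the pipeline itself.

What the generator does **not** emulate: photometric artifacts (blur,
illumination falloff, specularities), lens distortion, vessel branching
and crossing, anatomical lesion appearance, or inter-grader disagreement in
the reference standard. Passing tests therefore show the *logic* of the
chain is exact and its degradation under detector noise behaves as derived
— not that any component meets clinical performance on real images.

## Evaluation suite

Cohen's kappa is unweighted, `(p0 − pe)/(1 − pe)`; a degenerate table
(`pe = 1`) raises rather than returning a number. Binary rates follow the
textbook formulas; any rate with a zero denominator is NaN with a warning
while the rest of the report is kept. ROC curves sweep all thresholds with
ties grouped; AUC is the trapezoid area and equals the Mann–Whitney rank
statistic (asserted exactly in tests against a quadratic-time oracle). The
AUC confidence interval is a stratified percentile bootstrap (resampling
within class, 2000 reps default, seeded); stratification means no replicate
can lose a class. `specificity_at_full_recall` sets the threshold to the
minimum score among true positives — the operating point a screening
program would choose if missing a severe case is unacceptable — and reports
the fraction of negatives still rejected.

Cohort accounting: per-eye throughout. Stage matrices use labels 0–4; zone
matrices use I–III over eyes whose truth **and** prediction carry a zone
(eyes with no true lesions have no zone; eyes whose lesions were all missed
are counted separately rather than forced into a 3×3 cell). Indeterminate
plus calls are excluded from the plus 2×2 and counted in the report.

## Problem sizes and numerics

Default experiment sizes were chosen to keep any single check under a few
minutes on one core while leaving the statistical assertions
well-powered: 150–200 eyes for zero-noise identifiability, 400–500 eyes for
the closed-form degradation comparison (3-standard-error band), 50 pairs
for registration recovery (median statistics), 10 paired seeds × 3 miss
rates for the monotone-AUC check. Registration refinement runs Nelder–Mead
at 1/2 resolution (after a 1/4-resolution pass in the Fourier fallback
path) with `xatol 5e-4`; measured recovery on in-range pairs is ~0.1 px and
~0.001°, comfortably inside the 1 px / 0.5° design tolerance. Tortuosity of
a straight polyline is exactly 1 by construction (arc equals chord);
closed curves raise on the vanishing chord. All CSV/JSON writers are
deterministic (sorted keys, plain floats), so identical configs and seeds
reproduce outputs byte for byte.

## Known limitations

- Similarity-only registration; no lens distortion or local deformation.
- Zone III ignores its nasal absence (mitigated by temporal-only placement
  in the generator, but a real nasal-peripheral lesion would be
  over-staged III instead of II's edge).
- The plus scorer is calibrated to the synthetic vessel model; its
  coefficients are meaningless for real fundus photographs.
- The severity score's graded tail (plus score + detection confidence) is a
  design choice for ranking, not a calibrated probability.
- Stage 5, pre-plus, and aggressive-posterior ROP are out of scope.
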