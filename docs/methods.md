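# Methods

## Geometry and conventions

All computation happens in image (raster) coordinates: x grows rightward
along columns, y grows downward along rows, so "superior" means smaller y.
On a correctly displayed AP radiograph the patient's left hip occupies the
image-right half. Because display conventions vary, laterality is never
inferred from pixel position: every hip carries an explicit `lateral_sign`,
the sign of the image-x direction pointing away from the body midline
(+1 for the left hip, −1 for the right under the standard convention).

Every index is defined relative to the *Hilgenreiner frame*: the rotated
coordinate system in which the line through both tri-radiate cartilage
centers (Y points) is horizontal. Points are projected into that frame with
dot products against the line's unit direction (canonicalized so frame-x
follows image-x); angles come from `atan2` in the frame and are returned in
degrees, the unit in which these indices are reported clinically. Because
everything is frame-relative, all measurements are invariant under global
rigid motions (pelvic rotation/translation on the plate) and uniform
scaling; this is asserted by property tests at 1e−9.

Sign conventions (the clinical literature rarely states them): the
acetabular index is positive when the lateral rim E lies superior to the
roof's medial end Y — the normal configuration; the CE angle is positive
when E is lateral to the superior perpendicular through the head center C.
Normal hips therefore produce positive values of both. For a dislocated
hip with C superior to the rim level the CE angle can leave (−90°, 90°);
such values are reported as computed (they are clinically meaningless but
numerically well-defined, and the grades carry the diagnosis there).

The acetabular head index is `100·A/B` with B the head width `2r` along
the Hilgenreiner direction and A the distance from the medial head edge
(C shifted medially by the head radius r) to E's projection, measured
toward lateral. The medial edge is the *circle* edge of the fitted head,
not a bony edge; values below 0 or above 100 are not clipped, so a fully
uncovered head reports a negative AHI.

The head radius is not a landmark: it is derived from the femoral-head
segmentation ROI as the equivalent-circle radius `sqrt(mask_area/π)`, with
a quarter of the mean bounding-box side as fallback when no mask area is
available. Without any ROI the AHI and Tönnis grade are reported absent.

## Grading rules

**IHDI.** In the Hilgenreiner frame, with the Hilgenreiner–Perkin junction
(the projection of E onto the Hilgenreiner line) as origin, the metaphysis
midpoint H is classified: grade IV if strictly superior to the Hilgenreiner
line; otherwise I if at-or-medial to Perkin's line; II if lateral to Perkin
but at-or-medial to the 45° inferolateral D-line; III otherwise. Checking
"superior" first makes the (anatomically near-impossible) superior-medial
corner grade IV, consistent with superior migration being the severe
pattern, and keeps the partition exhaustive and monotone.

**Tönnis.** The ossific-nucleus center C is grade 1 if at-or-medial to
Perkin's line; otherwise graded by its superior-inferior level against a
*rim band*, the horizontal strip of half-width equal to the head radius
centered on E's level: inferior to the band → 2, within → 3, superior → 4.
The classical wording compares a finite-sized ossific nucleus to the rim
"level"; the head radius is the only size scale available, hence the band's
half-width. Whether published automatic systems use this ossific-nucleus
band or a pure head-center rule is generally unstated; the variant here is
documented, not asserted as anyone else's.

**Tie-breaks.** A point exactly on a boundary line always resolves to the
lower grade, and each activation is recorded in `boundary_flags`
(`on_perkin`, `on_dline`, `on_hline`) so borderline calls are auditable in
reports.

Both graders are verified against brute-force region classifiers that
re-derive the frame with an explicit rotation matrix and re-state the
inequalities independently, on dense grids (10⁴ points per hip) and under
monotone lateral/superior displacement along 10³ random rays.

**Shenton's line.** Clinically this is a perceptual judgment of arc
continuity. Here it is an explicit geometric rule: a circle is fitted to
the inferior border of the superior pubic ramus by algebraic (Kåsa) least
squares, and the line is *intact* iff the maximum absolute radial residual
of the medial femoral-neck points from that circle is ≤ `tol` (default
5 px, configurable — roughly the detector landmark error scale). A
collinear pubic arc makes the fit singular and yields *indeterminate*.
Reports should treat this as a geometric proxy, not a learned perceptual
judgment; the other qualitative calls of a full reading (rim sharpness,
sourcil integrity) are pass-through annotation fields that this package
never computes.

## Detection gate

The learned detector stages are out of scope by design; a provider
protocol (`provide() -> DetectionBundle`) preserves the pipeline topology.
The one coupling rule implemented is femoral-head gating: an ossific
nucleus may be invisible in young infants, so a detected C point is trusted
only when a femoral-head segmentation ROI exists for that hip (confidence ≥
0.5, configurable). Suppression is per-side by default with a global-mode
switch (suppress both C's only when no ROI at all was found), never touches
E/Y/H, and is idempotent. Downstream, an absent C cleanly removes the CE
angle, AHI and Tönnis grade while the acetabular index and IHDI grade
survive — which is the point of the IHDI scheme.

## Preprocessing

Radiographs (DICOM via pydicom, PNG via Pillow; multi-frame DICOM
rejected) are placed on a fixed 1333×800 canvas: isotropic scale
`min(1333/w, 800/h)` with bilinear interpolation, then zero padding of the
short dimension split centered (floor/ceil on odd remainders — centered
rather than one-sided, recorded in `CanvasTransform` so either convention
is recoverable). The transform is exactly invertible on the content region
(round-trip < 1e−9 px) and maps landmark files between original and canvas
space; points in the padded margin are rejected on the way back. CLAHE
uses `skimage.exposure.equalize_adapthist` behind a wrapper that accepts
the common histogram-multiple clip convention (default clip 2.0, 8×8
tiles); a constant image passes through unchanged and integer dtype range
is preserved.

## Synthetic pelvis generator

The generator is the study substrate, so its construction is exactly the
inverse of the measurement definitions: Y points symmetric about the
midline at half-width 100 px; E placed along a 30 px roof span at the
requested acetabular-index angle; C placed on the ray from E at the
requested CE angle at distance 2r (r = head radius, default 20 px); H at
C + (0, 25) px. A per-hip (lateral, superior) displacement of C and H
drives the grade; the whole scene rotates by the pelvic-tilt angle; and
the emitted detection bundle gets independent isotropic Gaussian jitter
per landmark (truth stays clean). Noise-free, undisplaced cases therefore
reproduce their generating parameters to 1e−6 degrees — the master
identity the engine is tested against.

Jitter is calibrated to clinical detector error: per-landmark mean
Euclidean distance error of published detectors is ~4–5 px at this canvas
size, and isotropic Gaussian jitter of σ per axis has mean radial error
σ·√(π/2) (Rayleigh mean), so σ = 3.7 px reproduces an MDE ≈ 4.64 px; a
500-case check asserts every per-landmark MDE within 3 standard errors of
the closed form. Independence across landmarks is the simplest
calibratable choice — real detector errors are likely correlated within a
hip, which synthetic cohorts do not emulate, so passing tests demonstrate
correctness of the *measurement* engine, not detector realism.

Cohort sampling (`sample_cohort`) varies the acetabular index
(≈ N(25, 3.5°)) and CE angle (≈ N(19, 5°)) around typical pediatric
values, draws a small pelvic tilt (≈ N(0, 2°), clipped at ±10°), and hits
a requested per-hip IHDI grade mix by rejection-sampling the femoral
displacement against the grading module itself — rejection rather than
inverse geometry keeps the grader the single source of truth for region
boundaries, and cohort labels are re-asserted against it at build time.
Shenton arcs are sampled from one 60 px circle per hip (12 points per
arc), the femoral arc translated with the displacement.

## Statistics

Cronbach's alpha is computed from the rater covariance matrix,
`α = k/(k−1)·(1 − tr(S)/ΣΣS)` with sample (n−1) covariances — algebraically
identical to the item-variance form but exact in floating point when two
raters are bit-identical, so a deterministic engine's test–retest alpha is
1.0 with no rounding residue. Alpha ≥ 0.75 is flagged satisfactory. An
ICC(2,1) is provided for comparison but alpha is the default reliability
coefficient. Cohen's kappa and linear weighted kappa
(`w_ij = 1 − |i−j|/(k−1)`) operate on confusion matrices; interpretation
bands are ≤ 0.40 poor-to-slight, 0.41–0.75 moderate, > 0.75 perfect. All
three are cross-checked in tests against independent routes (pingouin,
scikit-learn, and a brute-force double sum). MDE excludes missing
predictions from the mean and reports them as a separate miss count, since
there is no single accepted convention for scoring misses into a distance.

## Problem sizes and determinism

The bundled checks use cohorts of 133 cases (test–retest reliability,
matching a typical external-validation cohort size), 200 cases (parameter
recovery), and 500 cases (MDE calibration); grading oracles run on 10⁴
grid points per hip. All randomness flows through `numpy` Generators with
explicit seeds; the acceptance script takes a single `--seed` and derives
everything from it. The whole suite runs in a few seconds on one CPU.

## Known limitations

- The synthetic pelvis is a geometric stick-figure: no soft tissue, no
  exposure physics, no detector blur, no correlated landmark errors, no
  asymmetric pathology beyond what the per-hip parameters express.
- The Shenton rule and the rim-band Tönnis operationalisation are
  documented proxies for judgments that are perceptual or
  under-specified in the clinical literature.
- CE angle and AHI are reported even in configurations where clinicians
  would not measure them (dislocated hips); consumers should gate on the
  grades.
- No learned landmark detection ships with the package; the provider
  interface is the integration point for one.
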