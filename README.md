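# hipmorph

Radiographic morphometry and dysplasia grading for pediatric AP pelvis
images.

Developmental dysplasia of the hip (DDH) is assessed on anteroposterior
pelvic radiographs from a small set of named landmarks per hip: the lateral
acetabular margin **E**, the tri-radiate cartilage center **Y**, the
femoral-head ossific-nucleus center **C** (absent in young infants), and the
midpoint of the superior ossified femoral metaphysis **H**. From those
points `hipmorph` constructs the classical reference lines and derives the
standard measurements and classifications used in screening and surgical
planning:

- **Hilgenreiner's line** through both Y points, **Perkin's line**
  perpendicular to it through E, and the 45° inferolateral **D-line** of the
  IHDI scheme;
- **acetabular index** — the angle between the acetabular roof Y→E and
  Hilgenreiner's line (larger = shallower socket);
- **center-edge (CE) angle of Wiberg** — at C, between the superior
  perpendicular and the ray C→E (smaller/negative = less femoral-head
  coverage);
- **acetabular head index (AHI)** — the percentage of the femoral-head
  width lying medial to Perkin's line;
- **Shenton-line continuity** — a geometric circle-continuity proxy for the
  perceptual judgment (a step-off between the superior pubic ramus arc and
  the medial femoral neck suggests subluxation);
- **Tönnis (1–4)** and **IHDI (I–IV)** dislocation grades from the position
  of C and H relative to the reference lines.

The package is aimed at people building or validating automatic hip
measurement pipelines: it supplies the deterministic measurement engine
(stage 3 of a detect → segment → measure pipeline), a pluggable
landmark-provider interface with a segmentation-gated suppression rule for
spurious C detections, DICOM/PNG preprocessing onto a fixed 1333×800
detector canvas, a **synthetic pelvis generator** with known ground truth,
and the evaluation statistics used to validate such systems (landmark mean
distance error, Cronbach's alpha, Cohen's and linear weighted kappa,
confusion-matrix metrics). No clinical data ship with the package; every
test runs on synthetic geometry.

## Worked example

```python
from hipmorph import PelvisParams, PerHip, generate_case, measure_bundle

# a pelvis with a healthy left hip and a laterally displaced right femur
params = PelvisParams(
    acetabular_index_deg=PerHip(25.0, 32.0),
    ce_angle_deg=PerHip(20.0, 12.0),
    displacement=PerHip((0.0, 0.0), (55.0, 10.0)),
    noise_sigma_px=0.0,
)
case = generate_case(params)
result = measure_bundle(case.bundle)
for side in ("left", "right"):
    m, g = result.measurements[side], result.grades[side]
    print(f"{side:>5}: AI={m.acetabular_index_deg:5.1f}°  CE={m.ce_angle_deg:6.1f}°"
          f"  AHI={m.ahi_percent:6.1f}%  shenton={m.shenton:9s}"
          f"  Tönnis={g.tonnis}  IHDI={g.ihdi_roman}")
```

prints

```
 left: AI= 25.0°  CE=  20.0°  AHI=  84.2%  shenton=intact     Tönnis=1  IHDI=I
right: AI= 32.0°  CE= -58.0°  AHI= -66.7%  shenton=disrupted  Tönnis=2  IHDI=III
```

The left hip reproduces its generating parameters exactly (the engine is
deterministic and noise was zero). On the right, the 55 px lateral femoral
displacement drags C and H across Perkin's line and the D-line: the CE
angle turns strongly negative and the AHI drops below zero (the head has
left the bony roof entirely), Shenton's line breaks, and the hip grades
Tönnis 2 / IHDI III — lateral displacement without much superior
migration, the pattern of a laterally subluxated/dislocated hip still at
rim level.

There is also a CLI: `hipmorph synth` (generate a cohort of landmark JSON
files), `hipmorph measure` (landmark files → per-hip report CSV),
`hipmorph eval` (landmark mean distance error vs truth), and
`hipmorph reliability` (Cronbach's alpha across repeated runs).

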