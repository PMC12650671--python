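# spinefem

Parameterized, patient-specific scoliotic-spine finite-element modelling:
biplanar-radiograph landmarks → per-vertebra placement parameters (Y-X-Z
Euler chain) → full L5–C7 hex/truss/beam model with optional posterior
instrumentation → linear-static flexion analysis → segmental range of
motion, Cobb/TLK angles, per-axis MAE validation, endplate/annulus stress
maxima, and pre/post comparison reports.

Because no imaging data ship with the method, a first-class synthetic
fixture module generates scoliotic landmark sets with known ground truth
(single thoracolumbar coronal curve, calibrated to a requested Cobb angle),
so the entire pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `spinefem.fixtures` | synthetic biplanar landmark sets + CT-like reference coordinates with ground truth |
| `spinefem.parameterization` | landmark calibration/IO, Euler transform, per-vertebra parameter extraction, Nash–Moe mapping |
| `spinefem.mesher` | template vertebra, morph/placement, discs (nucleus/annulus/fibers/endplates), seven ligament sets, pedicle-screw/rod/connector construct, VTU/INP export |
| `spinefem.fe_solver` | hex8 (selective reduced integration), tension-only trusses with active-set iteration, Timoshenko beams, flexion load cases, angle matching |
| `spinefem.measure` | Cobb/TLK angles, MAE vs reference coordinates, segmental ROM, grouped stress maxima |
| `spinefem.report` | pre/post ratio tables, mobility shares, angle-validation summaries |

Axis convention: X mediolateral, Y anterior–posterior (+Y anterior),
Z vertical; flexion positive. Units: N / mm / MPa internally, stresses
reported in kPa.

## CLI

```sh
spinefem fixtures --out fx/ --seed 1 --cobb 52        # synthetic landmarks + truth
spinefem params --landmarks fx/landmarks.json --out params.csv
spinefem mesh --params params.csv --out spine.vtu --manifest counts.json
spinefem solve --params params.csv --out pre.json --moment-nm 10
spinefem solve --params params.csv --out post.json --instrumented
spinefem compare --pre pre.json --post post.json --out report.json
spinefem full-run --out run/ --seed 1 --cobb 52       # whole pipeline incl. angle matching
```

Exit codes: 0 ok, 2 validation failure, 3 solver failure.

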