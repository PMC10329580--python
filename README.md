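# hybridnav

Hybrid **EMT + X-ray navigation** toolkit for image-guided endovascular
procedures — and for quantifying how much radiation such a hybrid setup
saves.

Continuous fluoroscopy gives the surgeon visual guidance but exposes
everyone in the room to ionizing radiation. Electromagnetic tracking (EMT)
is radiation-free but suffers metal-induced position distortion near the
C-arm, strongest along the beam axis (tens of mm). The hybrid idea:
navigate continuously on EMT and take sparse fluoro *snapshot triplets*
(gantry angles 75°/90°/105°) only when X-ray truth is needed. This package
implements the complete computational pipeline:

* **C-arm geometry** (`hybridnav.carm`) — gantry poses, beam directions,
  forward projection and pixel-to-ray back-projection (parallel-beam by
  default, pinhole optional);
* **calibration** (`hybridnav.calibration`) — metallic-orb blob detection
  on board radiographs, per-image pivot centers, a per-angle polynomial
  pivot model over gantry height, and the caliper-based pixel↔mm scale;
* **registration** (`hybridnav.registration`) — least-squares three-view
  ray-intersection triangulation, rigid (Kabsch) EMT-to-image alignment,
  and per-axis RMSE error reports;
* **distortion compensation** (`hybridnav.compensation`) — per-axis
  ordinary-least-squares polynomials over the full trivariate basis of
  total degree ≤ d (4 terms linear, 20 cubic) mapping EMT positions to
  X-ray-derived references;
* **synthetic studies** (`hybridnav.synthetic`) — a seeded simulator for
  everything the hardware would produce: a calibrated distortion field,
  the 25×25 Lego-board training grid (100 train / 32 validation points), a
  60-step × 2 mm guidewire retraction, rendered radiographs with ground
  truth, frame averaging, and the acquisition timing model
  (t_setup = 1.0 s, ω = 4 °/s, 100 ms exposures);
* **trade-off study** (`hybridnav.tradeoff`) — the leave-out Monte Carlo
  that trades accuracy against fluoroscopy time (FT) and dose area product
  (DAP), the 1 mm threshold crossing, percent radiation savings, and the
  training-point-reduction experiment.

## The statistics at the core

Tracking error is reported per axis as RMSE with the combined value

```
RMSE = sqrt((E_X² + E_Y² + E_Z²) / 3),
```

so per-axis errors (2.04, 1.68, 23.10) mm combine to 13.42 mm.

The leave-out Monte Carlo replaces `M ∈ {0…60}` of the 60 navigation steps
by their EMT position (error = actual EMT-vs-reference distance) and
models the remaining X-ray-navigated steps with per-axis Gaussian noise
σ = 0.32 mm (pixel quantization). Over N = 200 iterations it records, per
M, the mean error and a conservative CI-95 accuracy bound — the 95th
percentile of the per-iteration RMSE. Radiation totals are
`FT = n_exposures × 0.95 s` and `DAP = n_exposures × 0.28 cGy·cm²`; the
operating point is the smallest FT whose CI-95 bound meets the 1 mm
high-precision requirement.

## Worked example

```python
from hybridnav import (
    CompensationModel, MCConfig, RadiationModel, error_report,
    ft_at_threshold, leaveout_mc, percent_reduction, simulate_study,
)

study = simulate_study(seed=0)          # field, board, retraction, triplets
cubic = CompensationModel.fit(study.training_set, degree=3)
print(cubic.summary())

radiation = RadiationModel()
curve = leaveout_mc(cubic.apply(study.emt_raw_mm), study.references_mm,
                    MCConfig(seed=101), radiation, label="cubic")
ft = ft_at_threshold(curve)
print(f"cubic: FT at 1 mm = {ft:.2f} s, "
      f"saving = {percent_reduction(60.0, min(ft, 60.0)):.1f}%")
```

prints

```
Polynomial compensation (degree 3, 20 basis terms per axis)
  training    n=100  E_X=0.30 mm  E_Y=0.28 mm  E_Z=1.09 mm  RMSE=0.67 mm
  validation  n=32  E_X=0.37 mm  E_Y=0.38 mm  E_Z=1.37 mm  RMSE=0.85 mm
cubic: FT at 1 mm = 0.00 s, saving = 100.0%
```

Reading: on held-out board points the cubic polynomial cuts the raw EMT
error (12.01 mm RMSE, Z-dominant) to 0.85 mm — more than tenfold. On this
simulated retraction its residual is small enough that every snapshot can
be replaced while the CI-95 error bound stays under 1 mm, so the full
fluoroscopy budget is saved. The same run with `degree=1` leaves a larger
curved residual: linear compensation reaches the 1 mm requirement only
near full imaging (FT ≈ 55 s, ~8% saving), and the uncompensated stream
never meets it once any EMT step is used (CI-95 ≥ 1.67 mm).

## Command line

```sh
hybridnav simulate --out study/ --seed 0        # synthetic study files
hybridnav calibrate --images boards/ --out pivot.yaml
hybridnav px2mm --csv caliper.csv
hybridnav register --triplets t.csv --emt e.csv --model carm.yaml \
    --out transform.yaml --report errors.csv
hybridnav compensate fit --train train.csv --degree 3 --out comp.yaml
hybridnav tradeoff --dataset eval.csv --comp cubic --out results/
```

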