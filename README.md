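# cineflow

Prediction of in-plane intra-cardiac blood-flow velocity from long-axis cine
MRI, trained against 4D-flow-derived displacement fields, with flow-metric
evaluation and automated E/A-ratio assessment of diastolic function.

Standard SSFP cine imaging shows the blood pool as a bright, speckled
region whose intensity fluctuations are advected with the flow. `cineflow`
treats dense velocity estimation from these fluctuations as a supervised
regression problem: a deeply supervised residual U-Net maps a temporal
window of cine frames to the per-pixel in-plane displacement from the
central frame to the next, with the in-plane projection of a 4D-flow
velocity field (converted to pixel displacements) as ground truth. Because
no patient cohort can ship with the package, a phantom generator produces
cine sequences with *exactly known* velocity fields — a systolic vortex plus
a biphasic diastolic inflow jet — so every stage is testable at desk scale.

## Model

**Preprocessing.** Cine intensities are normalized by the 5th/95th
percentiles of the pooled blood-pool histogram over all phases,
`P_norm = (P − P₅) / (P₉₅ − P₅)` (tails kept, not clipped). Reference
velocities **V** = (vₓ, v_y) in cm/s become pixel displacements

    D = (Δt·vₓ/psₓ, Δt·v_y/ps_y)

with frame interval Δt (s) and pixel spacing ps (mm). Cine/flow pairs whose
heart rates differ by more than 6 bpm are excluded as temporally
inconsistent.

**Network.** A residual U-Net over a 9-frame cyclic window (central phase ±
4 neighbours, concatenated as channels): four downsamplings (one 2×2 max
pool, then three stride-2 1×1 convolutions), residual blocks in the
contracting path, concatenation skips in the expanding path. Three auxiliary
2-channel heads at decoder scales 1/8, 1/4 and 1/2 (each nearest-neighbour
upsampled to full size) plus the final head give the deep-supervision loss

    Loss = EPE(G, O) + Σ_c w_c · EPE(G, P_c),

where the end-point error over the M blood-pool pixels is

    EPE = (1/M) Σᵢ ‖D_i,p − D_i,g‖.

The network and its training loop are implemented in NumPy with a compact
tape-based reverse-mode autodiff (`cineflow.nn`), gradient-checked against
finite differences; convolutions are lowered to BLAS matrix products.

**Evaluation.** EPE on velocities and mean angular error
`θ = (1/M) Σ arccos(V_p·V_g / ‖V_p‖‖V_g‖)` over blood-pool pixels with
reference speed > 5 cm/s, signed relative error of mean speeds, Pearson
correlation of the per-phase mean-speed curves, speed histograms, and
configurable threshold sweeps — per chamber (LV, LA, RV, RA) and pooled.

**Clinical module.** A transmitral region of interest is bounded by the
quadratic b-spline through the two valve hinge points (first/last LV-contour
vertices) and the LV cavity center. The E and A velocities are the two
prominent diastolic peaks of the per-phase maximum in-plane speed inside the
ROI (parabolically refined); 0.75 < E/A < 1.5 counts as normal diastolic
function. Agreement is quantified by Bland-Altman bias and limits of
agreement (1.96 × SD), PCC, paired t-tests and confusion-matrix metrics.

## Worked example

E/A extraction from a phantom's exact flow field:

```python
import numpy as np
from cineflow.phantom import PhantomConfig, make_flow_field
from cineflow.clinical import ea_from_flow, mitral_roi_from_contour

cfg = PhantomConfig(e_peak_speed=60.0, a_peak_speed=40.0, seed=0)
truth, mask, contours = make_flow_field(cfg)
T, H, W = truth.shape
rois = np.zeros((T, H, W), bool)
for t in range(T):
    rois[t], _ = mitral_roi_from_contour(contours.get(t, 1), (H, W), mask.labels[t] == 1)
res = ea_from_flow(truth, rois)
print(f"E = {res.e_velocity:.1f} cm/s at phase {res.e_phase:.1f}")
print(f"A = {res.a_velocity:.1f} cm/s at phase {res.a_phase:.1f}")
print(f"E/A = {res.ratio:.2f} -> diastolic class {res.diastolic_class}")
```

prints

```
E = 59.4 cm/s at phase 19.5
A = 40.1 cm/s at phase 27.0
E/A = 1.48 -> diastolic class 0
```

The configured jet peaks (60 and 40 cm/s at 65 % and 90 % of the cycle) are
recovered from the 30-phase sampling to within ~1 %; the ratio 1.48 falls in
the normal band, so the phantom is classified as normal diastolic function
(class 0).

## Command line

```bash
cineflow simulate  --config phantom.yaml --out data/ --n-cases 8
cineflow preprocess --data data/ --out prep/ [--hr-flow 72]
cineflow train     --data data/ --config train.yaml --out runs/
cineflow evaluate  --pred runs/predictions --ref data/ --out metrics.csv
cineflow ea        --flow data/ --out ea.csv
cineflow visualize --case data/case_000 --out frames/   # vector overlay, > 4 cm/s shown
```

Every run writes a JSON manifest (configs, seeds, versions) and a log.

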