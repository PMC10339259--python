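# mucoflow

Quantification of ciliary beating and mucociliary clearance (MCC) from
microscopy of airway epithelium cultured on chips and membrane inserts.

Differentiated airway epithelium transports mucus through the coordinated
beating of motile cilia. On-chip models of this tissue are characterized
with four imaging readouts, all implemented here as a tested Python
library with a thin CLI:

* **Ciliary beat frequency (CBF)** from high-speed phase-contrast video
  (nominally 200 frames/s): the temporal standard deviation of each pixel
  reveals motion; Otsu thresholding segments beating regions; *beat
  density* is the motion-positive pixel fraction; the dominant beat
  frequency per pixel is the argmax of the FFT magnitude spectrum within a
  physiological band.
* **Bead-transport statistics** from fluorescence movies of 1-μm tracer
  beads (nominally 30 frames/s): Laplacian-of-Gaussian spot detection and
  mutual-nearest-neighbour linking produce trajectories; nine kinematic
  features feed a background-flow classifier (a cross-validated decision
  tree, or an equivalent three-feature threshold rule on Euclidean
  distance, median speed and directness).
* **MCC summary statistics** on the filtered trajectories. Each
  trajectory's direction is the angle θᵢ between the channel axis and its
  start→end line. The **polar order parameter** is

      PO = û · n̂,   û = ⟨[sin θᵢ, cos θᵢ]⟩,

  with n̂ the unit vector toward the channel inlet, so PO ∈ [−1, 1]: +1 for
  flow toward the inlet, −1 toward the outlet, ≈0 for isotropic or
  wall-bound flow. Per-step velocities are time-averaged on a grid into an
  Eulerian field U(x, y); MCC **coverage** is C_mcc = A_mcc / A_total with
  A_mcc the alpha-shape area over active grid cells, and the
  **area-averaged speed** is M̄ = C_mcc·⟨|U|⟩.
* **Immunofluorescence quantification**: marker-positive area fractions
  (median filter → CLAHE → auto-threshold) and the density of VANGL1
  planar-cell-polarity crescents, D_C = ΣLᵢ/A, from Hessian multiscale
  ridge detection and skeletonization.

Every stage is validated against synthetic scenes with exact ground truth
(`mucoflow.synthetic`): sinusoidally beating patches at known frequencies,
directed-plus-Brownian bead motion with known labels, arcs of known
analytic length, and marker images of known positive fraction.

## Worked example

```python
import numpy as np
from mucoflow import synthetic, classify
from mucoflow.core import ChannelGeometry
from mucoflow.mcc import compute_stats

# a movie's worth of labeled trajectories: directed transport + background
tracks, truth = synthetic.gen_bead_tracks(
    synthetic.FlowSceneSpec(n_mcc=200, n_background=200, seed=2)
)
kept = classify.filter_background(tracks, classify.ThresholdClassifier())
geometry = ChannelGeometry(inlet_direction=(-1, 0), field_area_um2=1200**2)
stats = compute_stats(kept, geometry)
print(f"PO {stats.po:.3f}  coverage {stats.coverage:.3f}  "
      f"M_bar {stats.area_avg_speed_um_s:.2f} um/s  "
      f"n {stats.n_trajectories}")
```

prints

```
PO 0.999  coverage 0.546  M_bar 11.46 um/s  n 200
```

meaning: the 200 surviving trajectories (the background was filtered out)
move almost perfectly toward the channel inlet (PO ≈ 1), measurable flow
covers about 55% of the 1200 × 1200 μm field, and the coverage-weighted
mean transport speed is ≈ 11 μm/s.

The same chain from the shell:

```sh
mucoflow simulate-beads --tracks-out tracks.csv --manifest truth.json --seed 2
mucoflow classify --tracks tracks.csv --frame-rate 30 --out kept.csv
mucoflow mcc --tracks kept.csv --frame-rate 30 --field-um 1200 1200 \
    --inlet -x --out stats.csv --hist-out angles.csv
mucoflow benchmark --seed 0 --out report.json   # full end-to-end check
```

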