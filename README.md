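# dynconn

Time-varying neuronal network connectivity from wide-field calcium-imaging
video.

Cultured neurons expressing a genetically encoded calcium indicator
(GCaMP6s) report their firing as slow fluorescence transients. A single
correlation coefficient per cell pair hides the fact that neural coupling
changes over the course of an experiment — most visibly when an excitatory
stimulus such as bath-applied glutamate synchronises the whole network.
`dynconn` implements a model-free dynamic connectivity pipeline for such
recordings, together with a synthetic-video generator so that every stage
can be validated against known ground truth:

- **ΔF/F₀ extraction** — memory-bounded segmented video loading, 5-pixel
  (plus-shaped) ROI averaging around manually chosen soma seeds, shared
  background subtraction, baseline F₀ as the mean of the lowest 10% of
  samples, ΔF/F₀ = (F − F₀)/F₀.
- **Composite connectivity weight** — for each cell pair and each 1-minute
  interval, the unweighted mean of four Pearson-type coefficients:
  r of the traces, r of their power spectra, the mean r over six 10-second
  sub-windows, and r of the derivatives of rloess-smoothed traces
  (2nd-order local regression, 2.5% span). Averaging the interval series
  gives the final n×n connectivity matrix; percent change against a
  baseline window tracks connectivity dynamics.
- **Event statistics** — 3 Hz 3rd-order zero-phase Butterworth filtering,
  peak detection at a µ + kσ threshold with 0.5 s width and separation
  floors, inter-event intervals (IEIs) and an exponential goodness-of-fit
  summary for Poisson-like firing.
- **Wavelet coherence** — analytic Morlet (ω₀ = 6) continuous wavelet
  transform, magnitude-squared coherence
  |S(W_x W_y*)|² / (S(|W_x|²)·S(|W_y|²)) with the standard
  scale-proportional smoothing, cone-of-influence masking, and phase-based
  lead/lag estimation (positive phase ⇒ first cell leads; the phase of a
  common oscillation at frequency f delayed by τ is 2πfτ).
- **Spatial statistics** — intercellular distance vs connectivity
  regression, two-tailed Welch's t-tests, Z-scoring.
- **Synthetic ground truth** — correlated Poisson spike trains (a shared
  "mother" train sets pairwise synchrony), a difference-of-exponentials
  GCaMP6s-like kernel, Gaussian noise, and rendered 16-bit video with a
  guaranteed fluorescence-free background seed. A piecewise rate/synchrony
  switch emulates glutamate-like stimulation versus a media-perfusion
  control.

## Worked example

Simulate a glutamate-like experiment (4 cells, 10 minutes at 22.7 Hz,
stimulus at t = 300 s switching the shared event fraction from 0.3 to 0.9
and tripling the firing rate) and track the pairwise connectivity:

```python
import numpy as np
from dynconn.synth import glutamate_condition, render_traces
from dynconn.trace_io import DffTrace
from dynconn.connectivity import timevarying_weights, final_weights, classify_strength
from dynconn.events import detect_events, inter_event_intervals

cfg = glutamate_condition(seed=1, n_cells=4)
traces, gt = render_traces(cfg)
dff = [DffTrace(values=(traces[c] - cfg.f0) / cfg.f0, fs=cfg.fs, f0=cfg.f0,
                cell_id=f"cell{c}") for c in range(cfg.n_cells)]

series = timevarying_weights(dff)
matrix = final_weights(series)
ws = series[("cell0", "cell1")]
print(np.round(ws.weights, 3))
print("final weight:", round(matrix.pair("cell0", "cell1"), 3),
      "->", classify_strength(matrix.pair("cell0", "cell1")))

det = detect_events(dff[0].values, cfg.fs)
iei = inter_event_intervals(det)
print(f"cell0: {iei.n_events} events, mean IEI {iei.mean_iei:.2f} s")
```

Output:

```
[0.337 0.336 0.578 0.318 0.385 0.881 0.809 0.923 0.925 0.943]
final weight: 0.643 -> moderate
cell0: 112 events, mean IEI 5.24 s
```

The ten numbers are the composite weight of the pair on each 1-minute
interval: moderate, fluctuating coupling before the stimulus (intervals
0–4, weights ≈ 0.3–0.6) and near-saturated synchrony afterwards
(intervals 5–9, weights ≈ 0.8–0.94). The final weight averages the series;
the event train of cell 0 recovers the configured ~0.2 Hz baseline rate
(the post-stimulus rate gain shortens the overall mean IEI to 5.2 s).

## Command line

```bash
dynconn simulate --config synth.yaml --out data/run1     # TIFF + ROI CSV + truth JSON
dynconn analyze  --config run.yaml                       # full pipeline -> CSVs + manifest
dynconn report   --inputs control=out/ctrl --inputs glutamate=out/glut
```

`analyze` writes ΔF/F traces, the per-interval weight series with all four
components, the connectivity matrix, percent-change tables, event/IEI
tables, per-pair time-averaged coherence and distance–weight pairs, plus a
`manifest.json` with a checksum for every output.

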