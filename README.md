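# optonotch

Quantitative image analysis for optogenetic Delta/Notch experiments in the
early *Drosophila* embryo and pupal notum — and a synthetic-data generator
that emulates every input, so the whole pipeline runs and is tested without
any external data.

The package is aimed at quantitative developmental biologists who need the
standard measurements of this experimental system as tested, scriptable
building blocks rather than one-off GUI pipelines:

* **Nascent-transcription spot calling** (`optonotch.spotcall`) — MS2/MCP
  reporter spots are detected per movie frame by a fixed filter cascade
  (3×3 median → 100×100 mean-background subtraction → maximum z-projection
  → 30×30 median flattening → Gaussian σ = 3 px) followed by segmentation
  of the regions bounded by **zero crossings of the Laplacian** of the
  filtered image, with configurable blob area/intensity rejection.
* **Activation kinetics** (`optonotch.kinetics`) — per-frame spot counts
  become a spot-density curve n(t) (spots per µm of mesectoderm), fitted
  with the saturating exponential

      N(t) = N_max · (1 − e^(−k (t − t₀))),   N(t) = 0 for t < t₀

  with N_max (the nucleus census) held constant and only the activation
  rate k (min⁻¹) and onset delay t₀ (min) free.  Condition comparisons use
  Welch two-sample t-tests on per-embryo (k, t₀).
* **Membrane cluster kinetics** (`optonotch.clusterquant`) — light-induced
  clustering is summarized per frame by the clustering index
  (Σ intensity inside segmented clusters) / (total image intensity) ∈ [0, 1],
  whose rise is fitted with index(t) = P·(1 − 2^(−t/t½)).
* **Membrane and interface quantification** (`optonotch.memquant`) —
  7-pixel-wide line profiles across cell interfaces integrated over a
  0.78 µm window centred at the profile peak (normalized per embryo to the
  ectoderm median); per-cell membrane-band (0.3 µm) vs cytoplasm means;
  two-channel vesicle colocalization by ≥ 1-pixel mask overlap.
* **Clone-border scoring** (`optonotch.clonescore`) — sensory organ
  precursors (SOPs) at mosaic clone borders are tallied by clone side and
  tested against the 50 % null with an exact binomial test; plus the exact
  binomial genotype-ratio worked example.
* **Synthetic data** (`optonotch.synthgen`) — seeded generators for spot
  movies (irreversible exponential onsets after a delay, stable per-spot
  intensity), mass-conserving cluster movies, two-region membrane lattices,
  two-channel vesicle fields with a set overlap fraction, and mosaic clone
  tissues with logistic SOP bias — each returning full ground truth.

The model-fitting steps follow the statsmodels convention: build a model
object from data, call `fit()`, read estimates off the results object
(`ActivationKinetics(curve, n_max).fit().summary()`).

## Worked example

Simulate a reporter movie (30 nuclei, SNR 5), detect spots, and fit the
activation kinetics:

```bash
optonotch kinetics --config demo.yaml --out demo_out
```

with `demo.yaml`:

```yaml
seed: 1
spot_movie:
  n_nuclei_per_row: 15
  movie_start: 25.0
  movie_end: 45.0
  frame_interval: 0.5
  noise_model: gaussian
  noise_scale: 100.0
  cv_between_spots: 0.0
spotcall:
  min_intensity: 12000.0
alignment_time_min: 45.0
```

This writes `spots.csv`, `curves.csv`, `fits.csv`, an activation plot and a
`summary.json` containing

```json
"kinetics": {
  "converged": true,
  "k_per_min": 0.35198655649012844,
  "t0_min": -15.050024406156146,
  "true_k": 0.3,
  "true_t0": -15.0
}
```

Reading: 746 spot detections across 41 frames give a spot-density curve
whose fit estimates a per-nucleus activation rate k ≈ 0.35 min⁻¹ (true
value 0.3; a single 30-nucleus embryo carries that much sampling noise) and
an onset delay of 15.05 min **before** ventral-furrow formation (times are
aligned so the ventral furrow is t = 0; with the furrow at 45 min this is
29.95 min after the start of the interphase, vs the generating 30 min).

The same library calls are available in Python:

```python
from optonotch import synthgen, spotcall, kinetics

stack, truth = synthgen.gen_spot_movie(synthgen.SpotMovieParams(seed=1))
spots = spotcall.detect_spots(stack, spotcall.SpotCallConfig(min_intensity=12000))
curve = kinetics.build_activation_curve(spots, region_length_um=90.0)
print(kinetics.ActivationKinetics(curve, n_max=60).fit().summary())
```

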