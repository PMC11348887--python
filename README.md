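# neuromat

Analytics for a multi-phenotypic, image-based assay of neuronal maturation,
together with the synthetic data needed to exercise every stage of it without
access to raw microscopy or recordings.

Human PSC-derived cortical neurons mature slowly and asynchronously, so no
single readout captures their maturation state. The assay quantified here
monitors six maturity parameters per well in 384-well high-content screens:

* **nucleus area** (μm²) and **nucleus roundness** (4πA/P², 1 for a circle)
  from DAPI;
* **total neurite length per nucleus** (μm) and **number of neurite
  segments** from automated MAP2 tracing;
* fractions of **FOS⁺** and **EGR-1⁺** nuclei — immediate-early-gene (IEG)
  products induced by 2 h of 50 mM KCl depolarization, scored as nuclear
  mean intensity strictly above 800 AFU (FOS) / 1,000 AFU (EGR-1), with the
  unstimulated plate's fraction subtracted as baseline.

Mature primary rat cortical neurons at day 14 benchmark the assay: large
round nuclei (~130 μm², roundness ~0.93), >2,500 μm of neurite per neuron
and near-complete KCl-induced IEG responses.

For compound screens (2,688 compounds in duplicate), per-well features are
normalized sequentially: per-plate **b-scores** (two-way Tukey median
polish; residuals divided by 1.4826 × MAD), then library-wide robust
**z-scores** per replicate, then replicate averaging. Compounds with
viability z < −2 (intact-nuclei count) are excluded; **PCA** on the
compound × 6 z-matrix calls maturation-enhancing hits at **PC1 > 4**, and
the top-5 scorers for total neurite length and double FOS⁺/EGR-1⁺ induction
are added as single-parameter hits. Downstream activity readouts: MEA spike
detection at 9 robust s.d. on the negative phase, network bursts as
population rate ≥ 1 spike s⁻¹ per channel across the 4,096-electrode array,
firing-rate summaries over the 1/64 most active electrodes, and calcium
transients per ROI from ΔF/F on the 5-s / 20-min (240-frame) schedule.

The package is aimed at people building or auditing high-content maturation
screens: every stage (synthetic ground truth → image features → plate
normalization → hit calls → activity metrics) is a plain function over
numpy/pandas containers with a thin CLI on top.

## Worked example

Score a synthetic duplicate screen (2,688 compounds, 325 planted strongly
toxic compounds, 30 planted maturation hits, row/column plate artifacts):

```sh
neuromat score --seed 7 --out screen_out
```

```
Screen summary
==============
compounds analyzed (post-viability): 2363
toxic compounds excluded (z < -2):   325
PCA hits (PC1 > threshold):          30
single-parameter hits added:         10

six-parameter z-score medians:
  nucleus_area           -0.009
  nucleus_roundness       0.004
  neurite_length         -0.006
  n_segments              0.003
  induced_frac_fos       -0.027
  induced_frac_egr1      -0.018

explained variance fractions: 0.746, 0.055, 0.052, 0.051, 0.050, 0.047
clusters: other=2333, maturation-enhancing=30
```

All 325 planted toxic compounds — and nothing else — fall below the
viability threshold; the 30 planted hits dominate the first principal
component (74.6% of variance, the all-parameters-elevated direction) and are
all recovered at PC1 > 4, with 10 further single-parameter hits added from
the neurite-length and double-IEG rankings. Per-stage outputs
(`zscores.csv`, `pca_scores.csv`, `screen_result.json`, `manifest.json`)
land in `screen_out/`.

The same works from Python:

```python
from neuromat import LibrarySpec, simulate_screen_features, score_screen

plates = simulate_screen_features(LibrarySpec(seed=7))
result = score_screen(plates)
print(len(result.excluded_toxic), len(result.hits_pca))  # 325 30
```

Image-level measurement of a rendered mature-reference field:

```sh
neuromat simulate-field --preset rat_day14 --seed 2 --out field.tiff
neuromat measure field.tiff --out feats.csv
```

yields 12 nuclei with mean area 140.2 μm², roundness 0.932 and 3,246 μm of
traced neurite per nucleus for that seed — the generator's calibrated
morphometry recovered by the measurement pipeline.

Activity metrics:

```sh
neuromat simulate-mea --seed 1 --channels 512 --burst-rate 0.7 --out spikes.csv
neuromat mea spikes.csv --channels 512       # → network bursts: 42 (0.700 Hz)
neuromat simulate-calcium --seed 1 --out traces.csv
neuromat calcium traces.csv                  # → events per ROI: [5, 5, ...]
```

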