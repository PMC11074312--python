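# switchquant

Quantitative single-cell analyses of a bistable transcription-factor switch,
built around the exit of mouse embryonic stem cells from naïve pluripotency.
When the formative-state factor OCT6 (Pou3f1) is induced, it represses the
naïve-state factor NANOG in a dose-dependent, switch-like fashion: per-cell
NANOG levels are bimodal ("ON–OFF"), and the fraction of NANOG-negative
cells rises steeply with the OCT6 reporter's fold-over-background.
`switchquant` re-implements the measurement chain behind such a claim as a
tested, reusable library:

* **imaging** — background subtraction, classical watershed segmentation of
  DAPI-stained nuclei (external masks importable), and per-nucleus mean
  intensities per channel (the *cell table*).
* **singlecell** — fold-over-background normalisation `F = I / I_bg`;
  ON/OFF classification by a two-component Gaussian mixture on log
  intensities with the separation statistic
  `D = |μ₁ − μ₂| / √((σ₁² + σ₂²)/2)`; the dose–response curve of
  response-negative fractions over fold bins (edges 1.5×, 2×, 4×) with
  Wilson intervals; channel correlation; equal-count Low/Med/High gating.
* **spatial** — nearest-neighbour distance distributions of nuclear
  centroids and a two-sample Kolmogorov–Smirnov comparison of colony
  packing between conditions.
* **smfish** — single-molecule RNA-FISH quantification: Laplacian-of-
  Gaussian filtering, maximum-intensity projection, local-maximum spot
  calling with a robust median + k·MAD threshold, per-cell transcript
  counts.
* **enrichment** — basal-plus-extension regulatory domains (5 kb up / 1 kb
  down of each TSS, extended to neighbours up to 1 Mb), peak-to-gene
  assignment, and a bootstrap null for DE-gene/peak overlap: draw gene sets
  of the DE-list size, count peak-bearing genes, report fold enrichment and
  the add-one empirical p-value.
* **qpcr** — normalisation of N0 starting quantities to the geometric mean
  of housekeeping genes (GAPDH, PGK1), log₂ transform relative to the
  control condition, and randomized-block ANOVA with Tukey contrasts and a
  compact letter display.
* **synth** — a generator for colony images, cell tables, gene universes
  and smFISH stacks with known ground truth, so every stage is testable
  without any external data.  The per-cell expression model couples the
  response state to the driver fold through a repressive Hill link
  `P(ON | F) = 1 / (1 + (F/F₁⁄₂)^h)`.

## Worked example

Simulate a tightly packed five-colony field (100 nuclei) whose mCherry
driver represses the NANOG channel, quantify it, and build the
dose–response curve:

```python
from switchquant import imaging, singlecell, synth

colony = synth.ColonyParams(n_colonies=5, nuclei_per_colony=(20, 0),
                            packing_mode="tight", seed=7)
stack, truth = synth.generate_colony_image(colony, synth.ExpressionParams(seed=7))

labels = imaging.segment_nuclei(stack["DAPI"])
cells = imaging.measure_nuclei(labels, stack)
print(f"segmented {labels.max()} nuclei (simulated: {len(truth)})")

_, bg_d = imaging.subtract_background(stack["mCherry"], method="percentile")
_, bg_r = imaging.subtract_background(stack["NANOG"], method="percentile")
fold_d = singlecell.fold_over_background(cells, "mCherry", bg_d)
fold_r = singlecell.fold_over_background(cells, "NANOG", bg_r)
on, fit = singlecell.classify_on_off(fold_r.to_numpy(), method="gmm2_log", seed=0)
print(f"NANOG bimodality D = {fit['D']:.1f}; {on.mean():.0%} of cells NANOG-ON")
print(singlecell.dose_response(fold_d.to_numpy(), on).to_string(index=False))
```

Output:

```
segmented 100 nuclei (simulated: 100)
NANOG bimodality D = 6.9; 47% of cells NANOG-ON
     bin  n_cells  fraction_response_negative  ci_low  ci_high
negative       40                       0.050   0.014    0.165
     low        6                       0.333   0.097    0.700
    2-4x       30                       0.833   0.664    0.927
    >=4x       24                       1.000   0.862    1.000
```

Reading: segmentation recovered all 100 simulated nuclei; NANOG is strongly
bimodal (separation D ≈ 7); cells with a driver at background level are
95 % NANOG-positive, while cells above four-fold background are uniformly
NANOG-negative — the dose-dependent switch the pipeline is designed to
measure.

A command-line interface mirrors the library (`switchquant simulate`,
`quantify`, `doseresponse`, `gate`, `correlate`, `spatial`, `smfish`,
`enrich`, `qpcr`, `run`); `switchquant run --config cfg.yaml` executes the
full synthetic pipeline and writes a manifest of SHA-256 output hashes so a
config + seed reproduces identical bytes.

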