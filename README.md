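# calquant

Population-scale quantification of global single-cell calcium responses in
fluorescence time-lapse movies.

T cells (and other non-excitable cells) signal through transient rises in
global intracellular calcium, reported by dyes such as Fluo-4 whose
fluorescence increases strongly on Ca²⁺ binding. In a typical assay,
dye-loaded cells are pipetted onto an antigen-functionalized coverslip and
imaged for ~14 minutes (1000 frames, 0.82 s/frame) while they land and
respond; ionomycin added over the final 100 frames forces every viable
cell to maximal fluorescence. The scientific questions are population
level: what fraction of cells triggered, did they release a single Ca²⁺
flux, oscillate, or sustain a plateau, and how long after landing did the
first flux occur?

`calquant` answers these from the raw movie (or from per-cell trace
tables) with one user-set classification parameter:

1. **Segment** — locate each cell by Laplacian-of-Gaussian blob detection
   on a temporal maximum projection, refine its boundary by
   distance-regularized level-set (DRLSE) evolution, and integrate its
   intensity over time.
2. **Normalize** — divide all traces by the population's ionomycin-window
   maximum *M*, so the brightest ionomycin response is exactly 1.0.
3. **Classify triggering in Fourier space** — for each cell, take the DFT
   (1/N-scaled, DC removed) of the baseline-subtracted normalized trace
   x[n] over [landing, ionomycin start). A cell is *triggering* when
   strictly more than 10% of its complex components X_k lie outside the
   *triggering radius* r:

       X_k = (1/N) Σ_n x[n] e^{-2πikn/N},   k = 1 … N−1
       triggering  ⇔  #{k : |X_k| > r} / (N−1) > 0.10

   Noise-only cells cluster near the origin of the complex plane; fluxes
   push a band of components outward. The radius is the only tunable
   parameter and can be resolved automatically from the population's noise
   floor (`--radius auto`, recommended — see `docs/methods.md` for why the
   radius scale is tied to the spectrum convention).
4. **Sort patterns** — count peaks in the derivative of the trace: ≥ 2
   peaks above the minimum threshold → *oscillatory*; 1 peak with shallow
   or no post-peak decay → *sustained*; 1 peak otherwise → *single*; no
   triggering → *none*.
5. **Summarize** — triggering fraction, single/oscillatory/sustained
   fractions of triggered cells, median triggering time (the lag from
   landing to the first derivative peak), with mean ± sd aggregation
   across replicates and a Welch test utility for condition comparisons.

A full synthetic-data module generates ground-truth-labeled traces and
movies (landing cells, four response archetypes, ionomycin surge, additive
noise), so every stage is testable without real microscopy data.

## Worked example

Simulate 60 cells (30% single, 20% oscillatory, 10% sustained, 40% none)
at extraction-quality trace noise, classify with the automatic radius, and
summarize:

```sh
calquant simulate-traces --seed 7 --n-cells 60 --frames 1000 \
    --noise-sd 0.01 --ionomycin-frame 900 --out sim
calquant classify sim/traces.csv --radius auto --ionomycin-frame 900 --out results
calquant summarize results/classifications.csv
```

which prints

```
 n_cells  n_triggered  triggering_fraction  single_peak_fraction  oscillatory_fraction  sustained_fraction  median_triggering_time_s
      60           36                  0.6                   0.5              0.333333            0.166667                    116.85
```

36 of 60 cells triggered (exactly the 36 simulated responders; the
recovered archetype counts 18/12/6/24 match the generator's labels), half
of the triggered cells showed a single flux, a third oscillated, and the
median lag from landing to the first flux was 117 s. The resolved
automatic radius is recorded in `results/manifest.json`
(`triggering_radius_resolved: 0.000613` for this run) together with the
config, seed and software version. Per-cell output lives in
`results/classifications.csv`:

```
 cell_id  triggering archetype  n_peaks  fraction_outside  radius_used  peak_threshold_used  triggering_time_s
       0        True    single        1          0.179402     0.000613                 0.01             127.92
       1        True    single        1          0.168331     0.000613                 0.01             245.18
```

The same pipeline runs end-to-end from a movie: `calquant run --stack
movie.tif --frame-interval 0.82 --ionomycin-frame 900 --radius auto --out
results/`, or on a freshly simulated stack with `calquant run --simulate
--seed 7 --out results/`. Each stage is also exposed separately
(`simulate-stack`, `segment`, `normalize`, `classify`, `summarize`).

## Layout

```
src/calquant/
  synthetic.py     ground-truth-labeled trace & movie generator
  io.py            TIFF/OME-TIFF stacks, YAML config, CSV/JSON results
  segmentation.py  LoG detection, DRLSE evolution, trace extraction
  traces.py        normalization, baselines, derivatives, peak finding
  classify.py      Fourier triggering, pattern sorting, triggering time
  population.py    per-acquisition summaries, replicate aggregation
  pipeline.py      stage orchestration with run manifest
  cli.py           `calquant` command-line entry point
docs/methods.md    model, parameters, numerical choices, limitations
```
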