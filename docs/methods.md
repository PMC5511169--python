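# Methods

`calquant` quantifies global intracellular calcium responses of single
cells at population scale from fluorescence time-lapse movies of a
calcium-sensitive indicator (e.g. Fluo-4 AM). Cells settle onto a
functionalized coverslip during the acquisition; a responding cell releases
calcium and its whole-cell fluorescence rises transiently (single flux),
repeatedly (oscillatory), or to a plateau (sustained). At the end of the
acquisition an ionophore (ionomycin) is added so every viable cell reaches
its maximal indicator fluorescence, which anchors the normalization.

## Pipeline model and assumptions

1. **Detection.** Cells are located once per acquisition by
   Laplacian-of-Gaussian blob detection on a temporal maximum-intensity
   projection of the analysis window. The stack is smoothed along time with
   a 5-frame moving average before projecting: the projection is a maximum
   over hundreds of frames, so unsmoothed read noise sets an inflated
   ceiling, while a cell present for more than a few frames is unaffected.
   Detected blobs must additionally stand 10 robust standard deviations
   above the projection's background (spatially smoothed, median/MAD
   statistics), so a blank movie yields zero detections even though the LoG
   threshold is relative to the projection's own dynamic range. Cells are
   assumed static after landing — the assay images adhering cells — so no
   tracking is performed, and two cells closer than the blob scale merge
   into one detection (documented behavior, not an error).

2. **Landing frames.** A cell's landing frame is the first of two
   consecutive frames in which the mean intensity in a small disk around
   its centroid exceeds the frame background mean by three standard errors
   of that local mean. The two-frame persistence requirement keeps the
   per-frame 3-sigma false-positive rate from accumulating over ~900
   tested frames. "Landing" has no unique operational definition in this
   assay; this rule is the package's choice and is exact to ±2 frames on
   synthetic movies at peak SNR 10.

3. **Segmentation (DRLSE).** Each detection seeds a distance-regularized
   level-set evolution on a crop of four times the detection scale,
   initialized with a concentric disk. The level-set function phi (negative
   inside) evolves under the canonical three forces — double-well distance
   regularization (weight mu = 0.2), an edge-stopping length term (lambda =
   5), and a balloon term (alpha = -3, expansion) — with Dirac width
   epsilon = 1.5, edge-map smoothing sigma = 1.5, time step 1.0 (satisfying
   the stability bound mu * dt < 0.25) and 300 iterations. The
   edge-stopping function is g = 1/(1 + (|grad G_sigma * I| / k)^2) with
   k = 0.25 x the crop's maximum smoothed gradient: a contrast-adaptive k
   makes the forces scale-free in image intensity, stalling the front at
   the strongest local edge (a fixed intensity scale either never stops the
   front or freezes it before the edge crest, depending on contrast). On a
   sharp disk phantom the final region reaches IoU 0.92 with the true disk
   from seeds between 50% and 100% of the true radius. Because the balloon
   force expands, initializations strictly *outside* the object boundary
   diverge — the balloon sign must match the initialization side, and the
   pipeline always seeds inside. A front that reaches the crop border, or a
   region larger than a disk of three detection scales, is rejected and
   replaced by the detection-scale disk, flagged on the cell record.

4. **Trace extraction.** Per cell and frame, the trace is the mean pixel
   intensity inside the mask minus the frame background (median over
   non-cell pixels), making traces invariant to global additive offsets and
   linear in pixel intensity. The mean (not the sum) is used so traces are
   comparable across cell sizes. Frames before landing are missing values.
   Averaging over a ~50-pixel mask shrinks pixel noise by ~sqrt(50): at
   peak SNR 10 the extracted traces carry noise of roughly 0.01 of the
   normalized intensity scale, which is the regime the Fourier classifier
   is designed for (below).

5. **Normalization.** All traces of an acquisition are divided by one
   constant M: the maximum raw intensity any cell reaches during the
   terminal ionomycin window. The maximizing sample becomes exactly 1.0.
   This compensates inhomogeneous dye loading while preserving relative
   amplitudes; it is idempotent and invariant to global rescaling. Each
   cell's baseline is the median of its first 25 post-landing normalized
   frames (median for outlier robustness; the estimator's spread is
   1.25 sd/sqrt(25)).

6. **Fourier triggering classification.** For each cell the
   baseline-subtracted normalized trace over its analysis window
   [landing, ionomycin start) is Fourier transformed (FFT, scaled by 1/N),
   the DC term is discarded, and the remaining N-1 complex components are
   compared against a single modulus threshold, the *triggering radius*.
   A cell is triggering when strictly more than 10% of its components lie
   outside the radius. Noise-only traces scatter isotropically near the
   origin (per-axis spread sd/sqrt(2N) under the 1/N scaling); fluxes push
   a band of low-to-mid frequencies outward. The analysis window excludes
   the ionomycin frames: the surge would otherwise make every viable cell
   appear triggering, while ionomycin is only a normalization and viability
   control.

   **Radius scale.** Under the 1/N scaling the components are bounded by
   Parseval's identity: the non-DC moduli of any normalized trace satisfy
   sum|X_k|^2 <= max|x|^2 <= 1, so at most 8 components can ever exceed
   0.34 and a radius of that order can never satisfy the 10% count rule on
   long windows. The historically published exemplar radius 0.34 is kept as
   the config default for continuity, but it corresponds to an unnormalized
   spectrum convention; on 1/N-scaled spectra of ~900-frame windows the
   informative radius is of order 10^-3 (a few times the noise floor
   sd/sqrt(2N)). The automatic mode is therefore the recommended setting,
   and the resolved radius is always logged and written to the run
   manifest.

   **Automatic radius.** The quarter of cells with the lowest non-DC
   spectral energy (identically: lowest windowed-trace variance) serves as
   a noise-proxy population; the radius is the 99th percentile of their
   pooled component moduli, clamped to [1e-4, 1.0]. With fewer than 20
   cells an explicit radius is required.

   **Operating range.** The >10%-of-components rule needs the flux's
   spectral band above the noise-respecting radius to span >10% of
   frequencies. For a single flux (amplitude ~0.8, 10-frame rise, 80-frame
   decay) in a ~900-frame window this holds for white trace noise up to
   roughly 0.015 a.u.; at 0.01 the classifier recovers triggering labels
   essentially perfectly (accuracy 1.00 on 500 simulated cells), while at
   0.05 — several times the noise of a mask-averaged trace — the band
   occupies only ~8% of frequencies at any radius and the count rule breaks
   down regardless of scaling. Passing tests at the operating noise level
   demonstrate the method's behavior on extraction-quality traces, not on
   arbitrarily noisy inputs.

7. **Pattern sorting.** Flux peaks are counted in the derivative of the
   intensity trace: the trace is smoothed with a 5-frame moving average
   (short relative to flux rise times), differenced centrally (one-sided at
   the ends), and local maxima at least 12 frames (~10 s) apart — so one
   flux's rise is not double-counted — are kept if they exceed the peak
   threshold. The effective threshold is max(0.01 a.u./frame, 3.5 robust
   standard deviations of the cell's derivative signal): the floor handles
   noiseless data, the adaptive term keeps the false-peak rate per
   ~900-frame trace low while missing few true rises (a true rise of
   amplitude A over r frames has derivative A/r, ~5x the derivative noise
   at extraction-quality noise). The threshold actually applied is recorded
   per cell. Two or more peaks is oscillatory; one peak is sustained when
   the post-crest linear-fit slope magnitude over a 100-frame window is
   below 20% of (amplitude / window) — "shallow or no decay" — and single
   otherwise; a triggering cell with no discrete peak (slow rise) is
   reported sustained.

8. **Triggering time.** The lag from landing to the first derivative peak,
   in seconds (frame interval 0.82 s by default). The derivative peak marks
   the instant of steepest influx, i.e. the middle of the rise; the
   estimator's jitter on noisy traces is set by the width of the
   max-slope plateau that the 5-frame smoothing produces (~±2-3 frames at
   trace noise 0.05, ±1 frame at 0.01). Non-triggering cells have no
   triggering time (missing, never zero-filled). Two alternative
   procedural definitions circulate for this quantity (differences of
   highest/lowest or highest/second-highest peak times); both reduce to
   peak bookkeeping inconsistent with "time from landing to first flux"
   and are not implemented.

9. **Population metrics.** Per acquisition: triggering fraction (of all
   cells), and single / oscillatory / sustained fractions *of triggered
   cells* (they sum to 1 over triggered cells; reported missing when no
   cell triggered, never as 0). The triggering time is summarized by its
   median — its distribution is long-tailed — and replicates are combined
   as arithmetic mean ± sample sd of each fraction and the mean of
   per-replicate median times. Sustained cells count as triggered and are
   carried in their own fraction so the two-way single/oscillatory split
   remains recoverable. A Welch two-sample t test on replicate-level values
   is provided as plumbing for condition comparisons (no multiplicity
   correction).

## Synthetic data

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated.

* **Geometry** mirrors the target assay: 1000 frames at 0.82 s, ionomycin
  from frame 900 (the final 82 s). Tests use shorter movies where only
  mechanics are exercised; the sizes appear in each test.
* **Traces.** A flux is a linear rise over 10 frames followed by an
  exponential decay (80-frame constant) — sharp rise, slow decay — on a
  baseline of 0.1 a.u. with amplitude 0.8. Oscillatory cells fire 2-4
  fluxes 60 frames apart; their inter-flux decay constant is capped at half
  the period because calcium oscillations return toward baseline between
  spikes (without the cap, consecutive pulses ratchet to ~1.8x a single
  flux's peak and distort the normalization anchor). Sustained cells decay
  10x slower than a single flux. Landing frames are uniform over the first
  35% of the pre-ionomycin window; the flux follows landing by 30 frames
  plus an exponential tail (mean 120 frames), so the 25-frame baseline
  window is always flux-free and triggering times are long-tailed.
  Ground truth records, per flux, both the intensity-peak frame and the
  rise-midpoint frame (the steepest-influx instant a derivative-peak
  detector localizes).
* **Ionomycin** multiplies every cell — responder or not — toward
  gain x its own pre-surge maximum (default gain 1.25) over a 10-frame
  ramp, because the ionophore forces calcium release in every viable cell.
* **Stacks.** Each cell is a Gaussian spot (sigma = half the 6 px cell
  radius, blurred by a 1 px PSF) appearing at its landing frame, with
  additive Gaussian read noise calibrated so the brightest spot peak has
  the requested SNR (default 10), plus a constant offset keeping the
  background positive. Default noise on bare synthetic traces is 0.05 a.u.
* **Not emulated:** cell motility, division, overlap, photobleaching,
  Poisson photon statistics, background structure. Passing tests therefore
  show correct recovery under additive Gaussian noise and static,
  well-separated cells; they do not certify behavior on crowded fields or
  strongly bleaching acquisitions.

## Numerical choices and degenerate inputs

* DFT via `numpy.fft`, validated against an O(N^2) direct DFT to 1e-10
  relative error; windows shorter than 8 frames are rejected.
* The 10% rule uses a strict inequality (exactly 10% outside is
  non-triggering).
* Peak ties: within a violating pair the higher peak wins; exact ties
  resolve to the earlier frame; a plateau counts once, at its first frame;
  series endpoints are never peaks.
* Empty results are explicit: zero detections on a blank movie, missing
  pattern fractions when nothing triggered, missing triggering time when no
  peak exists.
* All CSV output uses a fixed float format, so reruns on identical inputs
  are byte-identical; only the JSON run manifest carries a wall-clock
  timestamp.

## Known limitations

* The triggering radius is scale-bound to the spectrum convention; values
  quoted for unnormalized spectra (such as the 0.34 exemplar) do not
  transfer to the 1/N scaling used here. Use `auto`.
* The count-based triggering rule loses sensitivity for traces whose noise
  approaches the flux amplitude over long windows (see operating range
  above); it is designed for mask-averaged extraction noise.
* Triggering-time precision is limited to ~±2-3 frames by the smoothing
  window's max-slope plateau at realistic noise.
* The balloon force's sign ties DRLSE convergence to inside
  initializations; strongly overlapping cells merge at detection and are
  not split.
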