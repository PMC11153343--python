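# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Sarcomere intensity-profile model

A phalloidin-stained myofibril, projected to a 1-D intensity profile along
the fibril axis, shows one unit per sarcomere: the thin-filament (actin)
region straddling a Z-disk. Each unit is modelled as

    f(x) = b + h                                          |x − c| ≤ W/2
    f(x) = b + h · exp(−(|x − c| − W/2)² / 2σ²)           otherwise

with baseline `b` (AU), amplitude `h` (AU), centre `c` (µm), plateau full
width `W` (µm), and flank widths `σ_L`, `σ_R` (µm) on the two sides. The
plateau is the region of uniform actin density; the half-Gaussian flanks
absorb pointed-end dispersion and optical blur. The function is continuous
(with a kinked derivative) at the plateau edges.

**Centre deactivation.** Actin from the two half-sarcomeres overlaps at the
Z-disk and adds a bump at the plateau centre that the rectangle cannot
represent. Samples with |x − c| < `deactivate_center_fraction`·W/2 receive
zero weight. The extent of the excluded zone is a free choice; the default
is the central 25% of the current Ŵ, re-applied after each parameter update
for `refit_rounds` (default 2) rounds. On a synthetic unit with a bump of
0.3·h the deactivated fit recovers W with roughly five-fold smaller error
than the undeactivated one, and wins in ≥ 80% of paired noisy replicates
(measured by the acceptance script).

**Why the train is fit jointly.** At physiological conditions (SL ≈ 2.0 µm,
TF ≈ 1.0 µm) the thin filaments of neighbouring sarcomeres meet near the
M-line: the units' half-maximum points nearly coincide, valleys between
units are a few percent of `h` deep (for TF > SL/2 the summed model even
peaks *between* units), and a window around one unit contains large
contributions from its neighbours. Independent per-window fits are
therefore unidentifiable on trains, and `fit_profile` instead solves one
least-squares problem for the whole train:

1. **Segmentation** (`segment_units`): the signal region is the span
   between the outer half-maximum crossings; the unit spacing is estimated
   by scanning Fourier magnitude over the expected SL range (1.6–2.6 µm by
   default) on the Hann-tapered interior of the train; the unit count and
   edge offset follow from span = 2·TF + (n−1)·SL. An isolated unit
   (span < 1.2·SL_min) gets one window and a direct level-width seed.
2. **Rigid-grid stage**: a 6-parameter fit (b, c₀, SL, W, h, σ) of
   identical units on an even grid, run for every unit count n compatible
   with the SL range; the candidate with the lowest masked residual per
   active point wins. This stage is what makes the pipeline robust to
   segmentation error on nearly flat trains.
3. **Release stage**: per-unit (c, W, h) plus a shared baseline and — by
   default (`train_shared_flanks`) — one (σ_L, σ_R) pair shared across all
   units of a profile. The flank width is set by the optics and pointed-end
   dispersion, which are common to an image; sharing it removes the
   W-vs-σ trade-off that otherwise inflates per-unit W variance about
   two-fold at 2% noise. Deactivation masks around every centre are
   recomputed each refit round.

Fits use `scipy.optimize.least_squares` (trust-region reflective, numerical
Jacobian — the model's kinks rule out exact derivatives), relative
tolerance 1e-10, bounds keeping W, σ positive and SL within 1.6–2.6 µm. A
unit whose fitted amplitude is below twice the residual noise SD, or with
fewer than 10 active points, is flagged `converged=False`; flagged units
are returned but excluded from measurements. On the evaluator's own
noiseless output the fit recovers all six parameters to ≤ 1e-6 relative
error, and halving the pixel size changes Ŵ by < 0.1%.

## Thin-filament and sarcomere lengths

* TF = W/2 + √(2 ln 2)·σ̄ with σ̄ = (σ_L + σ_R)/2. "Half-width of the flank
  at half-maximum" is HWHM = √(2 ln 2)·σ ≈ 1.17741·σ; with independent
  flank widths the mean is used (per-side values remain available on the
  fit object for audit).
* SL for the pair (i, i+1) is c_{i+1} − c_i. Each unit's measurement
  carries the mean of its left and right spacings when both exist, else the
  single available one; units with no converged neighbour yield no
  measurement. A measurement passes QC only if TF < SL.
* SL windows are closed intervals: [1.85, 2.2] µm for group comparison,
  [1.6, 2.6] µm for the TF~SL regression (ordinary least squares;
  slope, intercept, r², n reported; skipped below 3 in-window points).
* Group comparison: per-genotype mean ± SEM of TF in the window;
  percent-of-control = 100·mean_g/mean_control (identically 100 for the
  control); two-sided Welch t-test per mutant vs control with Holm
  correction across contrasts. The genotype label is a free grouping key,
  so heterozygotes can be carried as their own group.
* Measurements are pooled across fish; fish-level mixed-effects modelling
  is a possible extension, not implemented.

## Splice-event quantification

* PSI per exon i: IRₙ = IR_i/(L_i + r − 1), ERₙ = ER_i/(r − 1),
  PSI = 100·IRₙ/(IRₙ + ERₙ), with exon length L and read length r in bp.
  Exclusion reads upstream and downstream of the exon are summed into ER.
  r ≥ 2 is required (the ER normalisation divides by r − 1). Zero-coverage
  exons return an *undefined* PSI (not 0): zero would assert full exclusion
  without evidence. PSI is scale-invariant in (IR, ER) and strictly
  increasing in IR.
* Junction-locus event frequencies are plain read shares over {canonical,
  each alternative junction, intron retention}, in percent, summing to 100
  within 1e-9. Retention support is supplied directly as a count in the
  input table — read-level counting from alignments is out of scope, which
  keeps the module alignment-free. Whether retention reads should be
  normalised differently from junction reads is an open modelling question;
  the plain share is used and flagged here.
* Consequence classification applies one event — donor/acceptor shift by
  ±Δbp, full intron retention, or exon skip — to a toy transcript model.
  Frame: in-frame iff Δbp ≡ 0 (mod 3), with Δ = intron length for
  retention and −(exon length) for skips. The modified mRNA is translated
  from the annotated CDS start with the standard codon table; a stop whose
  first base lies 5′ of the canonical stop codon's first base is a PTC. The
  exon index containing the first novel stop uses post-event numbering:
  canonical exon indices are kept, a retained intron inherits its upstream
  exon's index, and shift-added intronic bases the index of the exon they
  extend. A frameshift that reaches the transcript end without any stop is
  reported with a `no_stop_found` flag. Minus-strand models are normalised
  to a plus-strand view (reverse complement, mapped coordinates) before any
  sequence operation.

## Muscle mechanics

* Baseline = median of the pre-stimulus segment (first 10% of samples by
  default); max force = max(force) − baseline, flagged if the peak sits at
  a trace boundary (possible truncation).
* Force–frequency: max force by ascending stimulation frequency, one trace
  per frequency per sarcomere-length state (slack/optimal); duplicate
  frequencies within a state are an error, missing ones are permitted.
* Twitch kinetics: activation time = t(peak) − t(first upward crossing of
  baseline + 0.1·(peak − baseline)); relaxation time = t(first downward
  crossing after the peak) − t(peak); crossings located by linear
  interpolation between samples. Both thresholds are relative, so the
  result is invariant to baseline offset and force rescaling. Phases that
  never cross (e.g. decay slower than the trace) are returned undefined
  (None) with a logged warning.
* Elliptical cross-section: csa = π·(mean width/2)·(mean depth/2) from
  three width and three depth measurements (mm). Features are emitted both
  raw and CSA-normalised, since published force values are not always
  area-normalised.
* Group statistics over the feature tables (e.g. two-way ANOVA of force by
  genotype × frequency) are a standard downstream recipe over the output
  TSV, not a bespoke operation here.

## Synthetic generators

All generators draw from a single `numpy.random.default_rng(seed)` per
call: identical specs give bit-identical outputs.

* **Profile trains**: sum of the unit model over evenly spaced centres plus
  an optional Gaussian Z-disk bump (default σ 0.08 µm) and additive iid
  Gaussian noise. Defaults emulate a 3-dpf larval myofibril: SL 2.0 µm,
  TF ≈ 1.0 µm (plateau 1.65 µm, flanks 0.15 µm), 0.05 µm pixels, noise 2%
  of amplitude. The noiseless bump-free curve is pixel-exactly the forward
  model used by the fitter (shared closed form), so generator truth is an
  exact oracle. Noise level and bump size are free parameters to sweep, not
  claims about real images. Generation rejects only plateau collision
  (W ≥ SL); overlapping flanks between neighbours are intended physiology.
* **Junction/exon counts**: junction reads multinomial over the event
  mixture (counts sum exactly to the requested total); exon inclusion reads
  binomial with inclusion probability psi·(L+r−1) / (psi·(L+r−1) +
  (1−psi)·(r−1)), which makes the length-normalised PSI estimator
  consistent for the generating `true_psi`.
* **Toy transcripts**: codon-aware sampling — ATG, then draws from the 61
  sense codons, then one stop — guarantees a PTC-free canonical ORF without
  rejection sampling; introns of length ≥ 4 get GT…AG ends. Plus strand
  only; consumers handle minus strand.
* **Twitches**: linear rise to peak over `rise_time`, exponential decay
  with `decay_tau`, preceded by `stim_onset` (default 30 ms) of baseline so
  that pre-stimulus baseline estimation has a quiescent segment, as in real
  recordings. The force–frequency helper uses a saturating law
  f_max·f/(f + f_half).

What the generators do **not** emulate: 2-D imaging and PSF structure,
non-uniform sarcomere spacing within a train, photobleaching, read-level
sequencing artefacts (mismapping, positional bias), nonsense-mediated-decay
kinetics, or calcium-handling dynamics in force traces. Passing tests
demonstrate correctness of the estimators under the stated generative
assumptions, not robustness to every property of real data.

## Problem sizes and statistical checks

The test suite and acceptance script use: 30 trains × 8 units per true-TF
condition (0.95/1.00/1.05 µm, 2% noise) for recovery, with the mean TF
required within ±0.01 µm of truth and a simulated 6% reduction recovered as
92–96% of control; 20 paired seeds for the deactivation benefit (≥ 80%
improved); 1000 random records for PSI-vs-oracle agreement (≤ 1e-12);
50 seeded loci at 10⁴ reads for mixture recovery — checked as per-category
50-seed means within 3 sd of their own sampling error plus a 4.5 sd
per-draw guard, since demanding every one of 200 binomial draws inside 3 sd
would fail by chance alone in a large fraction of runs. The demo pipeline
is verified byte-identical across repeated runs at a fixed seed.

## Known limitations

* The unit-count selection on nearly flat trains relies on the expected SL
  range; trains whose true SL falls outside 1.6–2.6 µm need the range
  widened explicitly.
* Whether the deactivation extent used in the original Fityk workflow
  matches the 25% default is unknown; it is a configuration knob, swept in
  tests, never asserted as the historical value.
* Per-unit baselines are not estimated on trains (one shared baseline per
  profile); slowly varying background would bias W slightly.
* The consequence classifier assumes the event lies upstream of the
  canonical stop codon's final bases and reports a single event at a time;
  compound events are out of scope.
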