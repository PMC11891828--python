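# Methods

`orca` analyzes calcium-imaging recordings from transgenic flies whose
olfactory receptor neurons are stimulated by odorants eluting, one at a
time, from a gas chromatograph (GC). The flame ionization detector (FID)
records the chemical stimulus waveform; the calcium trace records the
receptor response. The package covers the full path from raw fluorescence
to odor-response profiles, and ships a synthetic-data generator so that
every stage can be validated against known ground truth.

## The response model

Each odorant response is modeled as a linear kinetic cascade driven by
the stimulus concentration profile s(t) (the FID trace, measured at the
highest concentration, where it is well above the detection limit):

    dA/dt  = k_A  (s(t) − A)                    activation
    dCF/dt = k_AF A(t) − k_F CF                 fast calcium component
    dCS/dt = k_AS A(t − D_AS) − k_S CS          delayed slow component
    r(t)   = polarity · (CF + CS)

with zero initial conditions. k_A (s⁻¹) sets the upstroke speed, k_AF
((ΔF/F)/s) the response size, and k_F (s⁻¹) the decay of the fast
component. The optional slow component carries a signed gain k_AS, its
own decay k_S, and an onset delay D_AS (s); it is what models biphasic
responses (a second phase of opposite sign) and slow return tails. The
output nonlinearity of the linear–nonlinear framing is the identity by
default; a saturating transform r′ = R·r/(R + |r|) is available for
saturation studies but is not used by any validation study.

Negative responses (calcium decreases) are value-inverted and fitted
with the same machinery; `polarity` restores the sign. Purely biphasic
shapes are *not* treated as negative — the dominant extremum decides the
polarity and the signed slow gain carries the second phase.

**Identifiability.** For the one-component model the cascade is a
product of two first-order low-pass filters, so the parameter vector is
invariant under exchanging the two poles (k_A ↔ k_F with the gain
rescaled by k_A/k_F). Fits are therefore reported in the canonical
labeling k_A ≥ k_F (upstroke faster than decay), which is the
physiological regime. The two-component model shares the activation
stage between both branches, which breaks the corresponding symmetry.

## Numerical integration

The cascade is integrated with classical fixed-step RK4, treating s(t)
as piecewise linear between samples. Because every stage is a linear
ODE, the RK4 update is a constant-coefficient linear recurrence in the
state; it is evaluated exactly with an IIR filter (`scipy.signal.lfilter`),
which is bit-identical to the explicit step loop but vectorized. The
step subdivides the stimulus sampling interval so that

* k·dt ≤ 0.03 for the fastest rate constant in the parameter set, and
* dt ≤ 0.15 s, so the curvature the activation stage inherits from a
  sharp elution peak (σ ≈ 1.5 s) is resolved even when all rates are
  small.

The subdivision is capped at 64 substeps per sample: rates above
~3 s⁻¹ at the 1.66 Hz calcium sampling are faster than the data can
resolve, and are integrated at a bounded (stable, ~1% accurate) step.
Within the physiological range (0.03–3 s⁻¹) the integrator agrees with
a 100×-finer-step reference integration to better than 10⁻⁴ of the
response peak (`validation.ode_equivalence_study`).

The delay D_AS shifts the activation signal by fractional-sample linear
interpolation rather than whole-sample index rounding; this keeps the
residual continuous in D_AS so bounded least squares can refine it, and
reduces to an index shift when D_AS is a multiple of the step.

## Fitting and model-order selection

Parameters are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with eight
seeded multi-starts: log-spaced rate initializations, a steady-state
heuristic for the gain, and — for the two-component model — starting
delays spread over a coarse grid plus one start at the one-component
solution with k_AS = 0 (which guarantees the nested-model inequality
RSS₂ ≤ RSS₁ after optimization). Bounds: k_A, k_F, k_S ∈ [10⁻³, 50] s⁻¹,
k_AF ≥ 0, k_AS signed, D_AS ∈ [0, 20] s. The stimulus is normalized to
unit peak inside the optimizer (exact, by linearity in the gains) and
the gains rescaled on exit. Optimizer tolerances are 10⁻⁶ — residuals
are noise-dominated, so tighter tolerances only cost time.

Model order (one vs two components) is chosen by the Bayesian
information criterion in its Gaussian-residual form

    BIC = n ln(RSS/n) + p ln(n),   p = 3 or 6,

with ties (|ΔBIC| < 10⁻⁹) resolved toward the one-component model.

## Preprocessing

* **Bleach correction.** Photobleaching is additive on raw fluorescence
  and corrected by fitting A·e^(−x/B) + C on response-free samples
  (multi-start over decay-time initializations). Response windows are
  excluded asymmetrically (default −20 s/+60 s around each elution
  stamp) because decay tails extend far beyond the peak. The corrected
  trace is raw − fit + C, so the post-correction baseline equals C.
  Degenerate inputs (constant or rising traces) return a flagged fit
  with amp ≈ 0 / amp ≤ 0 rather than raising.
* **ΔF/F** = (F_i − F_0)/F_0 with F_0 the mean of frames 10–100
  (1-based inclusive, ≈ 6–60 s after acquisition start at 1.66 Hz),
  computed on the bleach-corrected trace (correction precedes ΔF/F).
* **Response mask.** For movie input, the peak-response frame is
  thresholded at its 60th percentile and linearly rescaled to [0, 1];
  the masked trace is the weight-averaged pixel value per frame. For
  trace-only input this stage is bypassed.
* **Synchronization.** The FID and calcium clocks are aligned on the
  reference odorant: shift = t(calcium peak) − t(FID peak), estimated
  after 3-frame median filtering within ±15 s of the expected elution,
  with the noise gate computed from the unfiltered trace. One shift per
  animal. The measured shift necessarily absorbs the transfer-line
  delay *and* the receptor's rise latency along with the clock offset;
  applying it fully would place response peaks at (or before) their
  stimulus peaks and break the causality the cascade model assumes. The
  pipeline therefore retains an allowance equal to the configured
  transfer delay (3 s default) when applying the shift. A residual
  compression of the apparent rise latency remains — a known limitation
  of single-peak synchronization; fitted k_A values from the full
  pipeline are accordingly upper-bound estimates, while response
  *magnitudes* are unaffected.

## Chunking, leakage removal, alignment

A chunk is the ΔF/F window around one elution stamp (pipeline default
−15 s/+40 s; the wider pre-window accommodates the synchronization
convention above) with the FID segment linearly resampled onto the
calcium frame grid. Strong responses decay over tens of seconds, so the
fitted model of the immediately preceding chunk is re-simulated with its
stimulus zero-padded to the end of the current chunk and the overlapping
tail subtracted before anything else ("leakage removal"); the baseline
(median of the pre-stimulus segment) is subtracted afterwards. Elution
jitter can be corrected by shifting a chunk (whole frames, bounded by a
3 s jitter limit) to the cross-animal median peak latency; the
synthetic generator produces no jitter, so the end-to-end pipeline
leaves chunks unshifted and the operation is exercised by its own
tests.

## Significance, profiles, categories

A response is significant within a recording when its modeled magnitude
(peak of the selected fitted trace, signed by polarity) satisfies
|magnitude| ≥ 2.5 · noise_sd, with noise_sd the SD of the pre-stimulus
ΔF/F segment. At the group level, per-animal values of
(|magnitude| − 2.5·noise_sd) must exceed zero by a one-sample one-sided
t-test at p < 0.01. Both tiers are reported; profile-level outputs use
the group tier. No multiple-testing correction is applied by default,
matching the reference workflow; a Benjamini–Hochberg FDR option
across the odorant panel is available
(`PipelineConfig.multiple_testing = "benjamini_hochberg"`).

Profiles are median signed magnitudes per odorant × dilution, pooled
over animals, sorted descending at the reporting dilution. The
dose-response category of an odorant is the length of the contiguous
run of group-significant dilutions ending at the highest concentration
(3/2/1/0 for the standard 10⁻⁶/10⁻⁴/10⁻² series); significant-at-low
but not-at-high patterns are flagged non-monotone and categorized by
the same contiguous-from-top rule. For cross-dataset comparison the
top-k (default 20) responses of a profile are affinely rescaled so
max → 1 and min → 0.

## Contamination detection and classification

A contamination is a consistent calcium response at a time with no
declared odorant and no FID peak above the detection threshold. The
scan runs on the cross-animal median ΔF/F trace: contiguous regions at
least 3 frames long above 2.5 · noise_sd (after a 3-frame median
prefilter; the noise SD comes from the unfiltered pre-stimulus segment)
each contribute one candidate at their maximum. Candidates are dropped
when they fall inside a declared response window (−5 s to +window
length: a bump riding a known response's tail cannot be attributed),
within the tail span of an already-reported event, or — when per-animal
traces are available — when fewer than 60% of animals show the peak.
Candidates with a visible FID peak are reported separately as
*unassigned odorants*, not contaminations. A registry of known elution
times proposes a matching odorant within ±5 s.

Origin is classified from the dose series of per-animal window maxima
across ≥ 3 dilutions: *component-borne* if the response increases with
concentration (one-sided Spearman trend p < 0.05 **and** top/bottom
fold change ≥ 2 — the reference workflow judges this visually; the
fold-change gate keeps statistically detectable but physically trivial
trends out), *environmental* if both criteria fail, *undetermined*
otherwise.

Detection performance at the design point (contaminant peak = 4× noise
SD): recall 1.0, with ≤ 1 false event per 100 clean runs
(`validation.contamination_detection_study`). Near threshold the
response top is broad and flat, so the reported event time scatters by
a few seconds around the true elution; the study counts a detection
within ±10 s.

## The synthetic-data generator

The generator emulates the statistical structure of GC-coupled antennal
imaging; defaults are the recorded protocol where one exists and
documented instrument-realistic choices elsewhere:

* **FID chromatograms** (10 Hz): exponentially modified Gaussian
  elution peaks (σ = 1.5 s, tail τ = 3 s — the standard chromatography
  peak shape) over a noisy baseline (SD 0.05). Peak area is linear in
  the odorant's relative headspace abundance (`vapor_weight`, the
  vapor-pressure effect that makes early eluates larger) and scales by
  10× per liquid-dilution decade, i.e. 100× per step of the
  10⁻⁶/10⁻⁴/10⁻² series. Hidden contaminants contribute no FID signal.
* **Receptor drive**: |potency| · c/(c + EC50) with c the concentration
  relative to 10⁻². The saturating law reflects the observed behavior
  of best ligands (near-saturated at 10⁻²) while a large EC50 keeps
  weak ligands in the linear regime; without per-odorant saturation the
  published category structure (significant at one, two, or three
  dilutions) cannot coexist at realistic ΔF/F amplitudes. EC50 values
  are per-odorant; the generator's default (0.02) sits between the
  regimes.
* **Calcium recordings** (1.66 Hz, 9–10 min): additive bleaching
  exponential (amp 150, τ 180 s, offset 400 raw units) plus the resting
  fluorescence times the summed forward-cascade responses of all
  odorants — tails overlap into following windows exactly as in real
  runs — plus Gaussian sensor noise (SD 2 raw units, i.e. ΔF/F noise
  ≈ 0.005). The stimulus that drives each ground-truth response is the
  noiseless unit-peak elution profile delayed by the 3 s transfer time;
  the fitted pipeline only ever sees the noisy FID.
* **Determinism**: the dataset is a pure function of the mix
  configuration including its seed (per-trace seeds derive from
  `numpy.random.SeedSequence`).

`example_mix()` is the six-odorant validation panel: a saturating best
ligand significant at all three dilutions (category 3), a simple
positive, a biphasic, and an inhibitory ligand significant at the top
two (category 2), a weak linear-regime ligand (category 1), a
non-ligand (category 0), and an undeclared, FID-invisible contaminant
whose response is concentration-dependent (component-borne). Potencies
are placed a factor ≈ 2 away from the 2.5σ significance threshold at
each dilution so the designed categories are a property of the design,
not of a lucky noise draw.

What the generator does **not** emulate: GC thermodynamics and column
chemistry (contaminants are injected phenomenologically), motion or
focus drift, inter-animal kinetic variability, multi-glomerulus spatial
structure, and the fast initial-adaptation transient seen in some real
strong responses (a third mechanism outside the two-component cascade).
Passing tests therefore certify the analysis logic, not robustness to
these real-data features.

## Validation problem sizes

The seeded studies use: 20 parameter sets (integrator), 100 noisy
chunks at SNR 20 (recovery), 100 + 100 chunks (BIC selection), 50 + 50
dose series (classification), 25 + 200 runs (detection recall / false
positives), and 6 end-to-end pipeline runs on the example panel
(4 animals × 3 dilutions × 6 odorants each). These sizes give stable
rates while keeping a full reproduction run in the tens of minutes on
one core.

## Known limitations

* Peak-based synchronization compresses apparent rise latencies (see
  above); k_A from full-pipeline fits is biased fast, and the BIC then
  sometimes attributes the residual shape mismatch to a small slow
  component. Magnitudes, significance calls, and categories are
  unaffected.
* The leakage model subtracts the *fitted* previous response; when a
  decay time constant is much longer than the chunk window it is weakly
  identified and the extrapolated tail inherits that uncertainty.
* `concentration_dependence` needs ≥ 3 dilutions with ≥ 2 animals; a
  contaminant of unknown dilution can be classified only when the
  surrounding mix was measured as a dose series.
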