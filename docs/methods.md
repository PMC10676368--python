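# Methods

This note documents the models, statistics and numerical choices behind
`earevol`, and what its synthetic fixtures do and do not emulate.

## The scientific setting

Primate hearing sensitivity in the 1–8 kHz band — the band of spoken
language — can be summarized by a single trait, **AT18m**: the average
auditory threshold between 1 and 8 kHz, computed as the audiogram's
integral over log10(frequency) normalized by log10(8).  Comparative
questions about this trait (did the human lineage become more
sensitive after the split from chimpanzees, or was the last common
ancestor already human-like?) hinge on two independent lines of
evidence the package implements end to end:

1. **The phylogenetic arm** — harmonize published audiograms measured
   with different methods, compute AT18m per species, fit a family of
   Gaussian trait-evolution models on a time-calibrated tree, select
   by AICc, and reconstruct ancestral states, in particular at the
   *Homo–Pan* ancestor.
2. **The transfer-function arm** — combine measured middle-ear transfer
   functions (stapes-footplate velocity over tympanic-membrane
   pressure, METF) with modelled ear-canal pressure gain into the
   external/middle-ear transfer function (EMTF), compare species
   groups frequency-wise under FDR control, and regress the measured
   human/chimpanzee EMTF differences against published candidate
   threshold-difference sets, ranked by AICc evidence ratios.

## Audiogram harmonization

Thresholds from auditory-brainstem-response (ABR) and headphone studies
are systematically higher than speaker-based behavioural thresholds.
Correction tables hold per-frequency offsets (other-method minus
speaker) at 11 log-equidistant frequencies 1·8^(k/10) kHz, k = 0…10;
the exact 11 frequencies used in the original analyses are not
published, and the grid is overridable.  Offsets are computed from the
species measured with both methods (ABR pair: *Lemur catta*,
*Nycticebus coucang*; headphone pair: *Macaca fuscata*,
*M. fascicularis*), averaged within method, and subtracted from the
audiograms of species measured only with the non-reference method.

All interpolation is linear in log10(frequency), the same variable the
AT18m integral uses; queries outside an audiogram's measured span raise
rather than extrapolate, because silent extrapolation would bias AT18m.
Corrected audiograms are sampled at the correction grid by default
(`grid="native"` keeps the audiogram's own points).  Thresholds remain
in dB re each source study's reference; only differences are ever
interpreted, so no SPL re-referencing is attempted.

AT18m is invariant to the frequency unit and to the logarithm base
because the integral is normalized by the interval length; these
invariances are asserted to 1e-10 in the test suite.

## Evolutionary models

All models are multivariate normals for the tip values with mean
`z0·1` and covariance a transform of the Brownian-motion (BM) matrix
C (shared root-to-MRCA path lengths, Myr):

| model  | covariance | shape parameter, bounds |
|--------|------------|--------------------------|
| BM     | σ²C | — |
| λ (signal) | off-diagonal ×λ | λ ∈ [0, 1] |
| δ (node-depth rates) | C^δ elementwise | δ ∈ (0.01, 3] |
| κ (branch-length exponent) | path sums of b^κ | κ ∈ [0, 3] |
| OU (fixed root) | σ²/(2α)·e^(−α d_ij)(1 − e^(−2α s_ij)) | α ∈ [1e-8, 50] /Myr |
| ACDC | σ²(e^(r s_ij) − 1)/r | r ∈ [−0.1, 0.1] /Myr |
| BMS | branch lengths × rate scalars | rates ∈ e^±12 |

At neutral parameters every transform reduces to σ²C (asserted to
1e-10).  The OU form is the non-stationary fixed-root variant; the
stationary variant differs and some packages default to it, which is
why the choice is stated here.  On ultrametric trees (all study trees
are time-calibrated) the fixed-root OU covariance coincides with a
depth-based branch-length transform, which is what the
ancestral-state solver uses.

`z0` and σ² are profiled analytically (GLS); the remaining shape
parameter is optimized on a deterministic 21-point grid over its bounds
followed by bounded scalar refinement, which acts as a multi-start and
makes fits reproducible bit-for-bit.  BMS rate scalars are optimized in
log space by L-BFGS-B from three deterministic starts (0, ±ln 10).

The reported headline rate is the df-corrected variance
σ² = σ²_ML · n/(n−1): the ML divisor n ignores the estimated root
state and its median is ≈ 0.94 σ² at n = 28, a removable bias.  The
ML value is kept as `sigma2_ml` and is what the likelihood and AICc
use.

**Rate shifts.** A shift names a branch and multiplies the variance
rate on that branch *and its descendant clade* (the usual
trait-medusa-style semantics; `regime="branch"` restricts it to the
named branch).  On a terminal branch — such as the branch leading to
*Homo*, the headline application — the two regimes coincide.  The
clade default was chosen because a branch-confined shift on an
internal branch injects exactly one shared Gaussian deviation into the
data, so its rate is estimated from a single realization and neither
the rate nor the location is usefully identified.  Relative rates are
reported with the background normalized to 1 (σ_rel = √rate).

**Model selection.** AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = the
number of tips (the convention of the comparative-methods packages).
k counts: BM 2; one-shape-parameter models 3; BMS 2 + 2 per shift when
the location was searched (rate + location), 2 + 1 when it was given.
Single-shift locations are found by exhaustive scan over all branches;
additional shifts by greedy forward addition.  Ten scenarios are
fitted per run: BM, BMS with 1–4 shifts, λ, δ, κ, OU, ACDC.

Known statistical limitations, measured on the 28-tip fixture at
σ² = 1 (they are properties of ML rate-shift selection at this sample
size, not implementation defects — the profile optimum of the true
candidate was verified against a fine grid):

* a ×10 variance shift planted on a 9-tip clade's crown branch is the
  top single-shift pick in ≈ 74% of replicates; misses are
  better-fitting sub-clades or parent branches of the truth;
* on pure-BM data the best searched single-shift model beats the
  0-shift model by AICc in ≈ half the replicates, mostly via near-zero
  "deflation" rates on small clades whose tips happen to lie close
  together; under `regime="branch"` this false-win rate drops to
  ≈ 21% at the cost of the recovery power above;
* OU's α is weakly identified at n = 28 (median relative error of the
  estimate 30–60% for α ≤ 0.05/Myr).

**Ancestral states.** Internal-node values maximize the joint
branchwise Gaussian likelihood given the tips — a sparse linear system
(weighted tree Laplacian with weights 1/branch-length on the
model-transformed tree) solved exactly; this coincides with the
GLS/BLUP estimates and the root equals the GLS mean (1ᵀV⁻¹x)/(1ᵀV⁻¹1).
Variances are universal-kriging prediction variances that account for
the estimated root mean.  Tips reproduce their observations with zero
variance.

## Transfer functions

Measurement frames are averaged coherently (complex mean), because the
measured quantity is a complex frequency-response function.  Spectra
measured over overlapping frequency ranges are concatenated on the
union grid; in overlaps the merged value combines the log-domain
(geometric) mean magnitude — two flat segments 2 dB apart merge to
1 dB from each — with the circular mean phase.  Magnitudes are
converted to dB re 1 mm s⁻¹/Pa and resampled linearly in
(log2 f, dB) onto the analysis grid f_i = 0.2·2^(0.03 i) kHz,
i = 0…187 (last point ≤ 9.8 kHz).  The EMTF is the pointwise dB sum of
the METF and the species' ear-canal pressure gain.  Group mean curves
are arithmetic means of per-specimen dB magnitudes (the audiometric
convention).

**Features.** Extrema are detected on a 5-point (±0.06 octave) moving
average, configurable; plateau ties break toward the lower frequency,
and adjacent same-kind candidates are collapsed to the more extreme one
so kinds alternate.  Slopes are Δmagnitude/Δlog2 f between consecutive
extrema.

**Group comparison.** At each grid frequency a two-sided variance-ratio
F test at the 0.05 level (unadjusted; the gate level is a convention,
not adjusted for multiplicity) chooses between the pooled-variance
t test and the Welch t test; Benjamini–Hochberg adjustment across all
188 grid frequencies controls the false discovery rate, with
significance at adjusted p < 0.05.  Significant bands are maximal runs
of significant frequencies sharing the sign of the mean difference;
the significant fraction per direction is the log-frequency measure of
those bands (one 0.03-octave step per point) over the full logged
range, so a single significant frequency contributes 1/187 ≈ 0.5%.
Under a simulated null (two groups of 5 from one population, 500
replicates) the any-significant rate is ≈ 5%, within the FDR contract.

## Difference-set regressions

Species difference sets are built at the published frequency lists
(audiograms: 125–8000 Hz octaves; transfer functions and sound-power
transmission: 125–5000 Hz plus 8000 Hz for the EMTF).  Audiogram
differences are chimp − human; transfer-function and power differences
are human − chimp, so a negative value always means the chimpanzee ear
is more sensitive.  The EMTF difference at 125 Hz is extrapolated by
fitting 2nd-degree polynomials in raw frequency (Hz) to each species'
mean curve over 200–400 Hz and 200–800 Hz and averaging the two
125 Hz predictions per species; raw-Hz abscissa makes the two windows
genuinely different fits (a log abscissa is available).  Exact
quadratic curves are recovered exactly, and a common offset added to
both species cancels.

OLS fits report slope, intercept, adjusted R², the two-sided slope
p value (BH-adjusted across the declared family of regressions — the
models reported together), and AICc from the Gaussian residual
likelihood with k = 3 (slope, intercept, residual variance; the
criterion requires a convention for the variance parameter and this is
the standard one).  Evidence ratios are exp(ΔAICc/2) relative to the
best model.  Note that ratios computed from *printed, rounded* AICc
values (44.8, 48.4, 47.0 → 6.05 and 3.00) are slightly smaller than
ratios from the unrounded values (6.3 and 3.1); the package computes
whatever its inputs imply.

## Synthetic fixtures: what they emulate

No machine-readable supplementary tables ship with the source article,
so the packaged fixtures are **synthetic stand-ins** generated by
`earevol.synth`; they reproduce the *statistical structure and stated
summary properties* of the study's data, not its numbers.

* **Tree** — 28 primate species with published audiograms; topology
  follows standard cladograms, divergence dates are TimeTree-style
  values rounded to 0.1 Myr; ultrametric, root at 74 Myr; *Homo* and
  *Pan* are sisters at 6.7 Myr.
* **Audiograms** — W-shaped curves (two Gaussian-in-log dips on a flat
  baseline) levelled so each species' noiseless AT18m equals a chosen
  realistic value (human −0.1 dB, strepsirrhines least sensitive);
  0.8 dB measurement jitter; ABR and headphone audiograms add
  frequency-dependent offsets with means 15.8 and 5.0 dB.  The two
  chimpanzee variants are the human curve plus explicit
  chimp-minus-human profiles: the "elder" profile favours chimpanzees
  at low frequency with a human advantage near 4 kHz; the "kojima"
  profile puts chimpanzees 8–13 dB above humans at mid/high
  frequencies.
* **FRF study** — 11 human, 4 chimpanzee and 3 bonobo specimens, 20
  multi-sine frames each on a 0.1–10 kHz grid at 50 Hz resolution with
  10% frame noise; per-specimen level (4 dB sd) and mode-frequency
  (5%) jitter.  Modal resonator responses peak near 1.1 kHz (human)
  and 0.9/6.7 kHz (panin).
* **Ear-canal gain** — a uniform lossy closed-tube transfer function,
  gain = −20·log10|cos(kL)| with k = (2πf/c)(1 − i·damping): human
  canal L = 21.5 mm (quarter-wave peak 4.0 kHz), panin L = 30 mm
  (2.9 kHz), damping 0.08 (≈ 17 dB peak gain).  Wall impedance and
  canal taper of a finite-element canal model are not emulated; only
  the resonance structure matters downstream, and fidelity above the
  first resonance is not asserted anywhere.
* **Sound-power differences** — a fixed 12-value synthetic table with
  the expected sign structure (chimpanzees favoured at low frequency).

Because the fixtures are synthetic, end-to-end runs demonstrate that
the *pipeline reproduces the study's qualitative contrasts* (a
rate-shift on the branch to *Homo* under the kojima assumption with a
much less sensitive *Homo–Pan* ancestor; an ancestor close to the
human value under the elder assumption; EMTF differences that track
the elder difference set and not the kojima one) — they cannot
reproduce the article's exact printed numbers, and passing tests say
nothing about the measurement quality of the original data.

## Problem sizes and determinism

Simulation-based checks use 100–500 replicates (oracle suites: 100
likelihood instances ≤ 8 tips, 20 ancestral instances at 6 tips, 50
statistical instances; recovery: 200 BM fits and 100 shift searches at
28 tips; FDR null: 500 replicates), sizes chosen so the whole suite
and the acceptance script each run in minutes on one CPU.  Every
stochastic operation takes an explicit seed or generator; no global
random state is used anywhere, and fixture generation is deterministic
given its seed.
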