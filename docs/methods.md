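# Methods

## Data model and timing conventions

A recording is a hypnogram: one vigilance state (W/N/R) per 4 s scoring
epoch with a parallel boolean artifact flag, aligned so that t = 0 is the
drug injection. Epoch *i* spans `[t0_offset + 4i, t0_offset + 4(i+1))`
seconds post-injection; analysis windows are half-open, and an epoch belongs
to a window when its start time does. The canonical windows are acute
([0, 7200) s) and prolonged ([0, 21600) s). Artifact flags never modify the
state sequence — they only exclude an epoch's EEG from spectral averaging —
so architecture and transition analyses always operate on the full
hypnogram.

Recordings whose first epoch starts after the window (late alignment) are
analysed on the covered part and surfaced through a coverage warning and the
cohort validation report rather than silently padded or rejected; how to
treat partially covered windows is a genuinely open choice and we prefer
making it visible to guessing.

## Episode (bout) detection

An episode of a state is built in three steps: (1) maximal runs of the state
are located; (2) consecutive runs are merged whenever the intervening run of
other states lasts at most the state's maximum gap (the non-state epochs
between two runs are summed, and their composition is unrestricted — an
interruption of a NREM episode may contain wake or REM); (3) merged
intervals are kept when their *span* — interruptions included — reaches the
state's minimum. Episodes start and end on epochs of their own state by
construction. Defaults: 60 s minimum / 16 s gap for wake and NREM, 16 s / 8
s for REM.

Two readings of the minimum-duration rule exist: minimum merged span versus
minimum net state time. We use merged span ("intervals of at least one
minute" reads most naturally as the interval's length); both span and net
duration are carried on the `Episode` object so the other convention is one
filter away. The detector is verified against an exhaustive-enumeration
oracle (all maximal sub-intervals satisfying the definition) over every
length-10 hypnogram and large random batches; the scan is also checked to be
mirror-symmetric, so the merge order cannot matter.

Sleep-onset latency is the start of the first NREM *episode* (the 60 s
rule), not the first scored NREM epoch; REM latency is measured from sleep
onset to the first single REM *epoch* (a transition into REM). Brief
awakenings — the sleep-fragmentation marker — are maximal wake runs of 1–4
epochs (4–16 s) with sleep (N or R) on both flanks; runs touching a window
edge are not interruptions *of sleep* and are excluded. The rate is
normalized per hour of total sleep time within the window.

## State-transition statistics

Every consecutive epoch pair inside a window is classified by (from, to)
state; the diagonal of the 3×3 count table holds continuations. Counts are
converted to row percentages so animals with different amounts of each state
are comparable; rows without pairs are missing, not zero.

The drug-versus-reference test is the canonical paired non-parametric
scheme. The statistic is the mean within-animal difference (drug − reference)
of one row percentage. The null hypothesis — conditions exchangeable within
animal — is sampled by flipping the sign of each animal's difference
independently, B = 5000 times by default. For the one-sided alternative
"greater", p = #{T\* ≥ T_obs}/B with ties counted toward the numerator and a
floor of 1/B, so p is never zero and the test is conservative rather than
anti-conservative. Results are bit-reproducible given (seed, B), and the
Monte-Carlo p agrees with the exhaustive 2ⁿ enumeration to within its
binomial standard error.

The 9-transition panel reports raw resampling p-values plus a Bonferroni
column; no family-wise scheme is imposed by default because the appropriate
correction depends on which transitions constitute the hypothesis family.
Calibration on identity-drug cohorts shows the N→N continuation test's
type-I error at the nominal 5% (measured 4.8% over 1000 cohorts at n = 8).

## Spectral analysis

Each 4 s epoch of 256 Hz EEG (1024 samples) yields a Hanning-windowed
periodogram at 0.25 Hz resolution, retained on 0–30 Hz (121 bins). Scaling
is one-sided power-per-bin with window power correction: the sum of the full
grid to the Nyquist frequency equals the frame's mean-removed, Hann-weighted
variance exactly (relative error < 1e-6), which fixes the otherwise
arbitrary normalization. An on-grid sinusoid therefore concentrates its
variance (A²/2) in its three-bin neighbourhood.

State spectra average the artifact-free epochs of one state in a window;
recordings with no qualifying epoch (e.g. too little REM) are excluded with
a warning. Relative spectra (drug as % of reference) are computed per animal
on the 0.5–30 Hz analysis band (119 bins — DC and the 0.25 Hz bin are
drift-dominated and excluded) and only then averaged across animals,
matching the within-subject design; the alternative (ratio of group means)
is not used.

Bin-wise testing is tiered: per-animal spectra are log₁₀-transformed (power
is right-skewed and multiplicative effects become additive); a two-way
repeated-measures ANOVA (frequency × condition) screens for an interaction
at α = 0.05 *without* sphericity correction — this step only gates, the
per-bin tests carry the inference; per-bin paired two-tailed t-tests are
then flagged at three tiers: p < 0.05 uncorrected, p < 0.01 uncorrected, and
Benjamini–Hochberg q < 0.05. Neighbouring bins are strongly dependent, so
the uncorrected tier is informative and the FDR tier conservative; reporting
all three brackets the truth. Testing on linear power is available as an
explicitly distinct option. Slow-wave activity (mean 0.5–4 Hz power per
epoch) is provided as a derived trace.

## Group-level statistics

Paired Cohen's d is mean(diff)/sd(diff), the convention under which
d = t/√n for the paired t statistic; the identity is asserted to 1e-4
throughout and pins the convention uniquely against published (t, df, d)
triples.

The main-effect test across k conditions is, for complete data, a one-way
repeated-measures ANOVA with Greenhouse–Geisser ε estimated from the
double-centered within-subject covariance; reported degrees of freedom are
ε(k−1) and ε(k−1)(n−1) — fractional, as conventionally reported. ε is
clipped to [1/(k−1), 1] and equals 1 when k = 2, where F = t² exactly. With
missing cells (unbalanced dosing designs) the model falls back to a REML
mixed model with a random animal intercept; its denominator df
(n_obs − n_animals − (k−1)) is an approximation, and exact agreement with
any particular mixed-model implementation is deliberately not a contract —
the complete-case sums-of-squares decomposition is.

Post hoc comparisons against the reference condition run only after a
significant main effect (otherwise they are reported as "not tested", not as
p = 1). Each comparison is a paired two-tailed t-test; the many-to-one
adjustment is the classical Dunnett two-sided max-|t| tail for m = k−1
equicorrelated (ρ = 1/2) t statistics, evaluated by double Gauss quadrature
over the shared normal factor and the χ mixing variable (verified against a
10⁶-sample Monte-Carlo oracle to < 0.01). With unbalanced pairs each
comparison uses its own df, a mild approximation. Adjusted p is clamped to
be at least the raw p, and for m = 1 equals it exactly.

Power and sample size for paired designs use the noncentral t distribution
(ncp = d√n, df = n−1); the smallest n with power ≥ the target is found by
direct search and cross-checked by simulating the test's rejection rate. For
d = 1, one-sided α = 0.05, power 0.9, the answer is n = 11.

## The synthetic cohort generator

The generator produces the statistical structure the pipeline assumes, not
biophysical EEG; passing tests demonstrate correct recovery of the encoded
effects under this model, not performance on real recordings.

**Hypnograms** are semi-Markov: each bout draws a geometric dwell at 4 s
resolution (memoryless at the epoch scale — the simplest structure that
exercises the episode/interruption logic; real bout distributions are
heavier-tailed) and exits through a per-state kernel. REM is entered only
from NREM. Defaults (W/N/R mean bouts 100/160/64 s; N exits 70% to wake,
30% to REM; R exits 60% to wake) put roughly 33% of time in wake, 60% in
NREM and 7% in REM (REM ≈ 11% of total sleep time) — representative of a
mouse early light phase. No circadian drift is modelled: the 6 h window is
treated as homogeneous. Brief awakenings are an *overlay*: each interior
NREM epoch starts a 1–4 epoch wake intrusion with hazard 0.012 per epoch
(≈ 10 per hour of sleep), provided the intrusion stays strictly inside the
bout. Because they are not emergent from the kernel, their hazard is an
independently recoverable ground-truth parameter. Artifacts are i.i.d. flags
at rate 0.02.

**Drug effects** are multiplicative and map one-to-one onto pipeline
readouts: `rem_entry_mult` rescales the N→R exit probability (wake absorbs
the remainder, so the N→R row percentage scales by exactly this factor);
`nrem_dwell_mult` and `rem_dwell_mult` stretch mean bouts;
`ba_hazard_mult` scales the intrusion hazard; `hi_freq_power_mult`
multiplies 6–30 Hz NREM EEG power. The "cno-like" preset (0.5, 1.5, 0.6,
1.0, 0.85) encodes the qualitative signature of a sedating REM-suppressing
drug; the "null" preset is the identity.

**Cohorts** are within-subject: each animal draws log-normal random effects
on its dwell means (sd 0.15) and hazard (sd 0.20) once, shared across its
conditions; recording seeds spawn deterministically from the master seed, so
a seed fully reproduces a cohort.

**EEG** is synthesized in the frequency domain: target spectrum =
1/f background plus Gaussian peaks (NREM: delta peak at 1.5 Hz; wake/REM:
theta peak at 7 Hz), fixed amplitudes with uniform random phases per epoch,
real inverse FFT. The Hann analysis window smears power across three bins
with weights (1, 4, 1)/6; synthesis amplitudes are obtained by solving that
tridiagonal system (deconvolution), so the analyzer's mean spectrum is an
unbiased estimate of the target even at peaks and at the steep 1/f edge —
the generator/analyzer round trip agrees per bin to within sampling error
(< 3% at 10⁴ epochs). A per-recording log-normal broadband gain (sd 0.05)
emulates session-to-session electrode impedance drift; it is the dominant
noise source for between-condition spectral tests and makes per-bin
differences realistically correlated across frequencies.

## Problem sizes used in the validation suite

The calibration experiment uses 1000 identity-drug cohorts of 8 animals with
B = 2000 resampling iterations; parameter recovery uses the cno-like preset
at n = 12 with NREM spectra from the acute window; the spectral round trip
uses 10⁴ epochs; oracle equivalence covers all 3¹⁰ length-10 hypnograms
under both threshold sets plus 10⁴ random length-100 hypnograms. Monte-Carlo
checks state their tolerance in multiples of the binomial standard error of
the quantity being estimated; fixed seeds make every experiment exactly
reproducible.

## Known limitations

- Geometric dwells underdisperse long bouts relative to real mouse sleep;
  architecture metrics remain exercised, but absolute bout-duration
  distributions should not be read as physiological.
- The mixed-model path's denominator df is approximate; with severe
  missingness its p-values are indicative, not exact.
- The Dunnett adjustment assumes the equicorrelated (balanced many-to-one)
  structure; strong imbalance across comparisons makes it approximate.
- EDF reading is optional plumbing (lazy `mne` import) and is not covered by
  the test suite, which exercises the spectral chain through synthesized
  frames instead.
- No EMG model, no spindles/slow-oscillation waveforms, no wake
  sub-classification, and no multitaper/Welch alternatives — out of scope by
  design.
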