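# Methods

`dyadsync` analyses EEG hyperscanning data from interacting pairs: it
turns two time-locked continuous recordings into frontal alpha asymmetry
(FAA) time courses, measures within-dyad concurrent and lagged agreement
with Lin's concordance correlation coefficient (CCC), and fits the
mixed-effects models that test condition, time and lag effects.  Because
studies of this kind rarely share raw EEG, the package carries a
synthetic dyad generator whose latent structure is known exactly; every
stage of the pipeline is validated against that construction.

## Signal processing

**Filtering.**  Continuous data are bandpass filtered 0.1–40 Hz with a
fifth-order Butterworth section applied forward and backward
(`sosfiltfilt`), giving zero phase and, after the two passes, roughly
−24 dB at 50 Hz and well over −40 dB an octave above the passband.  The
0.1 Hz cut has a ~10 s impulse response, so the padding length is set to
`3 / low_hz` seconds (clipped to the record length); with shorter pads,
edge transients from the high-pass visibly contaminate tens of seconds
of signal.

**Bad channels.**  A channel is rejected when it cannot be predicted
from the rest of the montage: in non-overlapping 1 s windows we compute
each channel's multiple correlation with all other channels from the
ridge-regularised (λ = 0.05) window correlation matrix — for a
unit-diagonal correlation matrix, `R²ᵢ = 1 − 1/precᵢᵢ` — take the median
across windows, and flag channels below 0.9.  Flat channels (zero
standard deviation) are always flagged, and a recording with more than
half its montage flagged raises an error instead of being silently
"cleaned".  The 0.9 criterion is the published interpretation of the
correlation-based rejection threshold used by automated cleaning tools;
those tools' exact internals are deliberately not reproduced.

**Artifact segments.**  Sliding 0.5 s windows with 50 % overlap are
scored by their mean 20–40 Hz band power (Hann periodogram, averaged
over channels).  Windows exceeding the median window power by ≥ 10 dB
are rejected at sample resolution; adjacent rejections merge.  The
median is computed per condition by default (a toggle computes it over
the whole recording); passing the previous mask excludes already-rejected
windows from the median, which makes the operation idempotent.

**Interpolation and reference.**  Flagged channels are rebuilt as
inverse-distance weighted averages of up to six nearest good neighbours
on the bundled 128-channel geodesic layout.  The neighbour radius
defaults to 3× the montage's median nearest-neighbour distance, so the
same rule works for dense caps and for the reduced montages used in
testing; spherical-spline interpolation was not used because cluster-
averaged band power is insensitive to the difference.  Finally the
channel mean is subtracted at every sample (average reference).  Order
of operations is a fixed contract: filter → channel rejection → segment
rejection → interpolation → average reference.

## Spectral analysis and FAA

Cleaned data are cut into non-overlapping 500 ms epochs from each
condition's start (a 120 s condition gives 240 epochs); a trailing
partial window is dropped and epochs touching any rejected sample are
invalid.  Per epoch and channel a Hann periodogram is evaluated on a
zero-padded 0.5 Hz grid (native resolution at 500 ms is 2 Hz).  Absolute
alpha power is the integrated density over 8–12 Hz inclusive (µV²);
relative alpha divides by the integral over 1–40 Hz and therefore lies
in [0, 1].  The relative-power denominator band is configurable.

FAA is `ln(right-cluster power) − ln(left-cluster power)` with cluster
power the mean of the chosen alpha measure over the cluster's channels
(log taken after averaging).  The clusters are the left (E23, E24, E26,
E27, E33) and right (E2, E3, E122, E123, E124) frontal groups of the
geodesic net.  Relative alpha is the default mode.  Exact properties:
swapping clusters negates FAA sample-for-sample, and relative-mode FAA
is invariant to rescaling all channels.

## Concordance

Epoch FAA is averaged into bins of 4 contiguous epochs (2 s; 60 bins per
2 min condition, 45 per 1.5 min).  A bin is the mean of its valid epochs
and missing only when all four epochs are missing.  Agreement is Lin's
CCC, `2·cov(x,y) / (var x + var y + (x̄ − ȳ)²)`, with population (1/n)
moments by default and a 1/(n−1) toggle; fewer than 3 aligned pairs, or
a zero denominator, yields a missing value with a recorded reason.

Lag convention: at lag *k*, the reference person's bin *t* is paired
with the partner's bin *t − k* — the reference person's present against
the partner's past.  Lag 0 is symmetric and identical for the two
partners; lags 1–3 (2–6 s) are not.  Group-level CCC pools the aligned
pairs of all dyads and both perspectives per condition × lag (a
per-dyad-mean table is emitted alongside, since pooling and averaging
are both defensible); subject-level CCC is one value per person ×
condition × lag.  Descriptive summaries per condition (mean, SD, min,
max, moment skewness, excess kurtosis) collapse subjects and lags.
Kurtosis is excess (normal = 0) by default with a raw toggle, because
descriptive conventions differ between tools.

## Statistical models

Both models are linear mixed models with a random intercept per person,
fit by REML (Nelder–Mead first, BFGS fallback; the optimizer used is
recorded on the result).  F tests are Wald statistics with residual
(n − p) denominator degrees of freedom — consistent with the very large
denominator degrees of freedom that epoch-level analyses report — with a
pseudoinverse fallback when missing cells leave the design rank
deficient.

*FAA model:* epoch-level FAA ~ condition × (time + time²).  Time is the
epoch index scaled to [0, 1] within condition and centered; this keeps
linear and quadratic terms comparable across conditions of unequal
length.  Marginal means are evaluated at the mean epoch (time² at its
observed mean, as marginal-means software does for covariates).  Linear
and quadratic trends are extracted every 60 epochs (30 s) per condition
with 95 % CIs and a non-zero flag (CI excludes 0).

*CCC model:* subject-level CCC ~ condition × lag, both categorical.
Pairwise condition contrasts are computed within each lag and
Benjamini–Hochberg corrected within that lag's family; contrasts
touching unobserved cells are flagged rather than estimated.

*Individual differences:* Pearson correlations between per-subject
summaries (restricted to one condition/lag) and covariates,
BH-corrected within the covariate family, with an optional winsorized
variant (5th/95th percentiles by default; the limits are configurable
because no standard exists).

## The synthetic dyad generator

The generator emulates the statistical structure the analysis assumes —
not realistic EEG morphology.  Each subject's latent asymmetry driver
*d(t)* is an AR(1) process at 2 s resolution (the bin scale), piecewise
per condition with a per-condition mean, held constant within steps.
Partner 2's driver is `c·d₁(t − delay) + (1 − c)·e(t)` with independent
*e* of the same law.  Cluster channels carry a common-phase alpha
sinusoid with amplitudes `A·exp(∓d/2)` (left/right), so
`ln(P_right) − ln(P_left) = 2d` exactly in raw absolute power.  Noise is
a broadband background shared across channels with per-channel gains
N(1, 0.1) — standing in for volume conduction, which is what makes real
montage channels mutually predictable — plus independent sensor noise.
Optional extras exercise preprocessing: 20–40 Hz Tukey-enveloped bursts
whose plateau band power exceeds the background's by a configured margin
(default 15 dB), and bad channels rendered flat or high-variance.

Default parameters, chosen once as field-plausible conventions (no
empirical FAA dynamics are available to estimate them from):

| parameter | default | rationale |
|---|---|---|
| sampling rate | 250 Hz | standard acquisition rate |
| schedule | 5 × 120 s | the five-condition interaction task |
| alpha frequency | 10 Hz | centre of the 8–12 Hz band |
| alpha amplitude | 10 µV | typical frontal alpha scale |
| AR coefficient φ | 0.8 per 2 s bin | see below |
| innovation SD | 0.18 | stationary driver SD 0.3, i.e. FAA swings ≈ ±0.6 |
| background SD | 15 µV shared | puts clean-channel predictability ≈ 0.96 |
| sensor noise SD | 5 µV independent | ≈ 3:1 shared-to-independent, cap-like |

**Why φ = 0.8.**  The driver must be smooth enough that 2 s bins are
autocorrelated but rough enough that a delay is identifiable.  Pooling
both partners' perspectives, the group CCC at candidate lag *k* for a
true delay of *D* bins behaves like `(φ^|k−D| + φ^(k+D))/2`.  At φ = 0.9
the margin between the true lag and its neighbour is ≈ 0.013 — below
sampling error at realistic bin counts — while at φ = 0.8 it is ≈ 0.05,
comfortably above it.  This analytic identifiability argument fixed the
default before any recovery experiment was run.

Randomness: a single seed spawns independent child streams in a fixed
documented order (driver 1, driver 2, phases/gains, noise 1, noise 2,
artifacts 1, artifacts 2), so any stream can be held fixed while others
vary.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: volume-conduction forward physics, 1/f
spectral shape, eye-blink/EMG artifact morphology, non-stationary alpha
frequency, or any real relationship between covariates and brain
signals (the covariate table is independent of the EEG by
construction).  Recovery results demonstrate that the pipeline measures
what it claims to measure, not that real dyads couple this way.

**Interaction with the reference.**  Average re-referencing subtracts
the montage-mean alpha component, which steepens the driver→FAA
transfer curve (it stays monotone for |d| ≲ 1 with the default
montage); relative alpha then compresses it.  Recovery through the full
pipeline is therefore assessed by correlation with the latent driver
(≥ 0.95 at default noise levels in practice; the test threshold is
0.8), while the exact `2d` form is asserted on raw cluster powers.

**Calibration nulls.**  "Effect-free" means equal condition means *and*
zero driver variance.  With a stochastic driver, each realisation has
genuine condition-mean differences (the AR process wanders), so
rejecting the null there is correct behaviour, not a false positive;
type-I calibration is only meaningful under a driver-free null, where
epoch FAA is exchangeable across conditions.

## Problem sizes

Tests and the acceptance script run on 16-channel reduced montages (the
ten cluster channels plus six spread over the cap) with the full
five-condition schedule where a check needs the full bin count, and one-
or two-condition 30–120 s schedules elsewhere.  Lag recovery and model
calibration use 20 seeded replicates.  These sizes were chosen so the
entire validation cycle runs on a laptop in a few minutes; every check
scales to full 128-channel montages through the same configuration
objects.

## Known limitations

- EDF output quantises to 16 bits over a per-channel fitted range
  (relative error ≤ 1/32767 of the channel's peak).
- Denominator degrees of freedom are residual-based; Satterthwaite or
  Kenward–Roger approximations are not implemented (subject counts in
  this design make the F denominators large enough that the difference
  is immaterial for the epoch-level model, less so for small CCC
  tables).
- The segment-rejection median is a per-condition statistic by default;
  recordings whose artifacts cover most of one condition would bias the
  baseline upward and under-reject there.
- No surrogate-pair (shuffled-dyad) null is built in; the group CCC
  tables are the hook where one would attach it.
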