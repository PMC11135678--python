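# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, and what the synthetic validation does and does not
demonstrate about field data.

## Received-level measurement

A call's clip (the analyst's selection, bounded in time) is interpreted as a
voltage waveform: full-scale digital amplitude maps to 1.0 V, with an
optional `gain_db` term for recorder gain chains. The 90% energy window
opens at the first sample where cumulative squared amplitude reaches 5% of
the clip total and closes at the first sample reaching 95%, both inclusive;
this first-crossing convention is deterministic and guarantees the window
holds at least 90% of the clip energy. RMS over the in-window samples is
converted to sound pressure with the hydrophone sensitivity *S* (dB re
1 V/μPa, default −171, the nominal Dtag v2 figure):

    RL = 20 log10(V_rms) − S      [dB re 1 μPa]

No noise subtraction or band filtering is applied: the measurement
characterizes the clip as selected. Consequences worth knowing: (i) the
measurement is exactly scale-covariant (×k amplitude ⇒ +20 log₁₀ k dB) and
time-shift invariant; (ii) a clip much longer than the sound it contains
dilutes the window with ambient noise — the in-clip energy signal-to-noise
ratio, not the instantaneous level ratio, controls accuracy. On rendered
synthetic audio the round trip recovers target levels to within ~0.1 dB for
isolated calls at ≥ 20 dB SNR; overlapping calls contaminate each other's
windows, which is a physical property of the measurement, not an
implementation artifact.

## Caller assignment

Matching across tags is by temporal overlap with an onset tolerance
(default 0.1 s; clock offsets between tags are assumed already applied —
no cross-correlation synchronization is attempted). Matching is greedy in
onset order with a nearest-onset tie-break; a detection joins the best
matching bundle that has no member from its own tag, otherwise it opens a
new bundle, so coincident acoustic events yield parallel bundles rather
than collisions. Two same-tag detections with coincident spans (endpoints
within 1 ms) *and* equal levels (within 0.1 dB) are treated as duplicate
annotations of one event and rejected loudly.

The focal rule compares the two highest member levels: a gap of at least
`delta_db` (default 1 dB) makes the loudest member focal and the rest
nonfocal; anything closer makes the whole bundle indeterminate (caller
"undetermined"). The 1 dB criterion applied to the top-two gap is the
minimal reading that yields a unique focal candidate; an `all_pairs`
strategy (every pairwise gap must exceed the criterion) is available as a
flag. Under noiseless geometry (own tag strictly closest), assignment is
provably correct, and the test suite verifies 100% accuracy on such scenes;
with level jitter accuracy degrades smoothly, which the seeded jitter-grid
test tracks.

## Bout analysis

Inter-call intervals (ICIs) are onset-to-onset gaps between consecutive
calls of the same individual. The fitted model is an i.i.d. two-process
exponential mixture — fast (within-bout) and slow (between-bout) — rather
than an explicit alternating two-state process; this matches the likelihood
being maximized and keeps parameter recovery well-posed. The bout-end
criterion is the interval at which the two weighted component densities
intersect:

    t* = ln( p λ_f / ((1 − p) λ_s) ) / (λ_f − λ_s)

**Maximum-likelihood estimator (default).** The likelihood is maximized on
untransformed intervals in unconstrained coordinates (logit weight, log
rates) by L-BFGS-B from 8 deterministic multistarts built from data
quantiles (plus seeded jitter); the best optimum wins and the labels are
ordered so λ_f > λ_s. Fits are flagged degenerate when the weight collapses
to a boundary (p < 10⁻³ or > 1 − 10⁻³), the rate ratio falls below 1.05, or
the densities never cross; a degenerate fit reports the 95th interval
percentile as a fallback criterion so downstream segmentation stays defined,
with a logged warning. Across 20 seeded replicates of n = 2000 drawn at
(p = 0.7, λ_f = 2 s⁻¹, λ_s = 0.05 s⁻¹), the median relative BEC error is
about 2% (tolerance asserted: < 10%).

**Broken-stick estimator.** The classical histogram construction: intervals
are binned on a log₁₀ axis (resolving both timescales), counts are converted
to empirical densities per second, and two least-squares lines are fitted to
log₁₀(density) against bin center *in seconds* on either side of each
candidate break. In these coordinates each exponential process is a straight
line with slope −λ log₁₀e, so the minimum-error break's line intersection
estimates the density crossing directly. Fitting the lines against the
log-interval abscissa instead (a tempting shortcut, since the histogram is
built on that axis) locks onto the fast mode's peak and badly underestimates
the criterion; this package deliberately fits in linear time. Intervals
spanning less than half a decade are rejected as a single cluster
(insufficient data).

**Segmentation and summaries.** Bout membership is strict (< BEC); a gap
exactly equal to the criterion splits. Bouts need ≥ 2 calls and span the
first call's start to the last call's end. The criterion is fitted on
intervals pooled across individuals by default (one criterion for
everybody), with per-individual fitting available by grouping upstream.
Summary tables report, per group: median and IQR of *within-bout* ICIs,
the coefficient of variation (sd/mean) over *all* of the group's ICIs
(between-bout gaps are what the criterion was fitted on and belong in the
overall variability), median bout duration, median calls per bout, and bout
count. Quantiles use linear interpolation (numpy's default, type-7-like);
the convention is a documented flag because IQRs are convention-sensitive.

## Overlap counting

An overlap instance is an unordered pair of focal calls from different
individuals in the same group with strictly positive span intersection;
shared endpoints do not count. Three mutually overlapping calls yield three
instances; an event-cluster mode (connected components of the overlap
graph) is available behind a flag. No significance test against a
permutation null is attempted — with few individuals and highly skewed call
rates such a test would not be robust.

## Call-type taxonomy

Broad types are decided by objective structure in a fixed order: paired
sequence membership → paired burst; heterogeneous multi-segment structure
(e.g. pulsed then tonal with no gap) → complex; a single short broadband
transient → pulse; pulsed structure → LF pulsed (pulsed calls are always
low frequency); tonal structure splits LF/HF at a 2 kHz first-harmonic
threshold; anything else → other. Subtype identities within LF tonal (bop,
grunt) and LF pulsed (whup, thwop, knock, squelch, snort, squish,
pseudo-thwop) are graded calls assigned by analyst consensus; the package
does not attempt to automate them. Analyst hints are validated against the
taxonomy: absent or inconsistent hints resolve to the "other" subtype
within the two subtyped broad types (with a warning on conflict). Calf
thwop variants 1 and 2 fold into thwop, carrying a variant field, since
they share the stereotyped thwop structure. Proportional use divides each
subtype's (or broad type's) count by the column total, so columns sum to 1
by construction.

## Received-level mixed model

The model is a Gaussian random intercept per individual,
`rl = Xβ + b_i + e`, with age class (adult reference) as the only fixed
contrast in the full model. The likelihood is profiled: for a given
variance ratio γ = σ_b²/σ_e² the per-group covariance I + γJ has an
analytic inverse and log-determinant, the fixed effects have a GLS closed
form, and σ_e² a closed form, leaving bounded 1-D optimization over log γ
(with an explicit γ = 0 boundary check). ML is the default because AIC
comparisons across different fixed-effect structures are only valid under
ML; REML is available and both are reported by the pipeline, since
published mixed-model software defaults vary. Parameter counts are fixed
effects + 2 variances (full: 4, null: 3) and AIC = −2ℓ + 2k exactly. The
implementation is cross-checked in the tests against a dense-covariance
likelihood oracle and against an independent mixed-model implementation
(statsmodels MixedLM), agreeing to ~10⁻⁶ in log-likelihood.

## Synthetic scenes: what they emulate and what they do not

The generator produces a static group of 2–3 tagged whales. Per whale, call
onsets follow the two-process mixture (defaults p = 0.7, λ_f = 2 s⁻¹,
λ_s = 0.05 s⁻¹ — a ~0.5 s within-bout rhythm and ~20 s between-bout gaps,
consistent with the bout structure the bout stage is designed to detect).
Subtypes are drawn from published proportional-use columns (pooled adults;
the best-sampled calf for calves — that calf's printed column sums to 0.965
due to rounding in its source and is renormalized). Source levels are
N(155, 6²) dB re 1 μPa at 1 m and propagation is spherical spreading only
(20 log₁₀ r, clamped at 1 m), with the whale's own tag at 2 m; these are
simulator conventions chosen to put received levels in the 120–160 dB range
of tagged-whale recordings, not published claims. Optional Gaussian jitter
on received levels stands in for all sources of level error at once.

Rendered audio uses 16 kHz by default (calls here stay below 4 kHz; real
tags sample at 64–96 kHz) with tonal calls as FM sweeps with harmonics and
pulsed calls as gated tone-burst trains, each scaled so its 90%-window RMS
voltage matches the target level, in Gaussian ambient noise (default 95 dB
re 1 μPa). Single pulses get short (20–40 ms) annotation spans, as an
analyst would draw them.

Not modeled: movement, propagation delay between tags (all tags share call
onsets exactly), frequency-dependent absorption, multipath/surface
reflection, flow noise, detection failure (all calls appear on all tags
unless a detection floor is set), and analyst timing error. Passing the
synthetic validation therefore demonstrates the *algorithms* are correct
under their stated assumptions — closest-tag level ordering, mixture-shaped
interval structure — not that those assumptions hold in any particular
field recording. The deliberately idealized defaults (no level jitter, no
detection floor) keep ground-truth tests exact; jitter grids probe
robustness separately.

## Bundled reference tables

`calltag/data/deployment_summary.csv` is a per-individual summary of a
published Gulf of Maine multi-tag humpback deployment series (16 tagged
whales in 7 groups, July 2006–2009): deployment date, group, per-individual
analysis duration, whale class and focal-call count. It drives the summary
arithmetic in the acceptance script (982 focal calls in total; one group
contributing ~78%; 2812 min of browsed data summed per individual; 13 vocal
individuals). `repertoire_proportions.csv` carries the corresponding
subtype proportional-use columns for adults and three calves, used verbatim
for reporting and renormalized as simulator defaults.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; pipeline runs are
bit-reproducible given config + seed. Test and acceptance problem sizes —
600–3600 s scenes (hundreds to ~1600 calls), n = 2000 intervals × 20 seeds
for estimator recovery, 120 s audio renders — were chosen as the smallest
sizes at which the asserted tolerances are comfortably stable.
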