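# Methods

This note records the models, parameter choices and numerical decisions
behind `eegac`, and what the synthetic validation does and does not
establish.

## Filter bank

Each filter is a flattened Gaussian in frequency,
`exp(-a Δf² - b Δf⁴)·H(f)` with Δf = f - fc.  Its 1/e cutoffs have the
closed form `fc ∓ sqrt((sqrt(a² + 4b) - a) / (2b))`; they are symmetric
about the center, and the bandwidth is governed mostly by `b` (the
quartic term dominates at the 1/e radius for the parameter ranges used
here).

### Band table

The default table assigns (1, 1, 2, 1, 1, 3, 3) filters to delta,
theta, alpha, low beta, mid beta, high beta and gamma.  Band edges are
*ranges*, not points, because the literature disagrees on exact
boundaries: delta starts in 0.5–1 Hz and ends in 3–4 Hz, theta ends in
7–8 Hz, alpha ends in 12–13 Hz.  Where adjacent bands are convention-
ally quoted with a single shared number (the beta subdivisions, the
beta/gamma boundary) the range is taken as ±0.5 Hz around it.  Gamma is
truncated near 38 Hz: twelve filters cover delta through low gamma,
which is the range scalp EEG resolves reliably.  The table and the
allocation are configurable (`BandDefinition`, `load_bands`).

### Center and cutoff windows

A band holding one filter gets a *hard* center window: midpoint of the
(lower-edge-low, upper-edge-low) pair up to midpoint of the
(lower-edge-high, upper-edge-high) pair — for delta this is
(1.75, 2.5) Hz.  A band holding n filters gets n *soft* windows that
partition the admissible center span evenly; the interior split points
are artificial, so the corresponding interior *cutoff* windows are
taken as ±1.5 Hz around the split (band-edge cutoff windows are the
band's edge ranges themselves).  Degenerate windows (collapsed edge
ranges) are rejected rather than silently accepted.

### Two-step design

Step one places all K centers by minimizing the sum of squared
differences of adjacent spacings inside the windows (a smooth box-
constrained problem; L-BFGS-B with the analytic gradient).  Step two
minimizes, for three consecutive filters at a time, the normalized
excess arc length of their summed response between the outer centers —
`(∫ sqrt(1 + S'(f)²) df - chord) / chord` on a 0.01 Hz composite-
trapezoid grid with the analytic derivative — subject to center
windows, shape-parameter bounds (`a ∈ [0.0005, 0.5]`,
`b ∈ [0.01, 0.5]`, bracketing the published values with margin),
cutoff windows, and a neighbor-leakage bound: each filter's gain at the
adjacent centers may not exceed ε = 5·10⁻⁴.  SLSQP with five random
multi-starts per round (the problem is locally rugged and single starts
occasionally stall on the constraint boundary).

The sliding schedule fixes each round's last filter before the next
round fits the following two.  A trailing singleton round is infeasible
in practice — the greedy pair round before it parks the eleventh center
high, leaving no admissible region for the twelfth — so when exactly
three slots remain the final round fits all three together
(3+2+2+2+3 for K = 12).

An optional polish pass (`polish_bank`) minimizes the plateau value
directly over all a, b with centers frozen, under the same constraints.
It replaces the manual parameter trimming such a design otherwise needs
and typically improves P_v by ~15% over the greedy triplet result.
Rebuilt banks agree with the published centers to within 0.5 Hz but not
to the printed third decimal; the published bank's own parameters are
near-optimal but not exactly locally optimal under this objective
(consistent with their having been hand-trimmed), and one neighbor pair
(filter 3 evaluated at center 4) exceeds ε at the printed three-decimal
precision.

The plateau value is evaluated on [fc₁, fc_K] by default: outside the
designed span the summed response necessarily decays to zero, and a
full-Nyquist evaluation measures that roll-off, not design flatness
(the full-range variant is available by passing explicit bounds).

## Intensity extraction

Kernels are built by sampling the one-sided response on the DFT grid of
an N-point window, inverse transforming, and rotating by N/2 so the
response is centered.  N defaults to 8 s of samples: the narrowest
filter's impulse response decays below 10⁻⁴ of its peak well inside
that window.  The sampling rate is never assumed from data-free
context; 256 Hz is the default for synthetic work and must be supplied
explicitly for real recordings.  `fs ≤ 2·fco_hi` is rejected.

Raw intensity is `2|psi * x|` ("same" alignment, zero-padded edges).
The factor 2 compensates the one-sided filter discarding the negative-
frequency half of a real signal's spectrum; a unit sinusoid at any
filter's center reads out steady-state intensity within [0.98, 1.02].

Smoothing uses a Gaussian with sigma = fs/2 samples on support ±3 sigma,
renormalized to unit mass (the truncated continuous normalization loses
~0.27%, and constant-preserving smoothing is the property that matters
downstream).  Each series carries a `valid_span` excluding 3 sigma at
both ends where zero-padding bleeds in; peak detection and summed
intensity honor it.  `decompose` batches all filters through one padded
FFT of the signal — mathematically identical to per-filter time-domain
convolution (verified against it in the tests) and ~3× faster.

## Activation Complexity

Peaks are samples strictly greater than both neighbors; endpoints and
plateaus contribute none.  No prominence or minimum-distance thresholds
are applied by default (the statistic is defined on the bare peak
train); options exist but are off.

Sample entropy uses unordered template pairs (i < j) among the N - m
templates that admit an (m+1)-length extension, Chebyshev distance, and
excludes self-matches.  Defaults m = 2, r = 0.25 with r scaled by the
sample SD of the interval sequence; `r_mode="absolute"` is available.
SD scaling makes AC invariant to the units of the intervals (samples
vs. seconds) and to affine rescaling, which is why intervals are kept
in samples internally and reported in seconds.  Below 100 intervals a
warning is emitted (entropy estimates destabilize); below 10 intervals,
or when either match count is zero, the cell is *undefined* and is
propagated as missing — never as 0 or infinity.  The brute-force
double-loop oracle in the test suite pins the counts bit-for-bit.

Min-max normalization of AC maps (`normalize_ac`) is a visualization
aid only; statistics always run on raw values.

## Synthetic generators

**Tone/chirp composite** — four stationary tones (2.3, 5.6, 8.75,
11.4 Hz; amplitudes 7.5, 4, 5.5, 8), a 0→15 Hz linear chirp of
amplitude 6 spanning 20–30 s, then 2.3 Hz (amp 2.3) + 16.6 Hz
(amp 6.5).  Only the chirp's span is canonical; the stationary segments
default to 5 s each and the mixture to 10 s.  Junctions are abrupt by
design, so brief perturbations in unrelated filters at the seams are
expected behavior, not artifacts.

**Spiking-population LFP** — N neurons fire once per cycle of a
synchronizing rhythm with Gaussian timing jitter; spikes (one biphasic
sine cycle, 2 ms, floor of two samples so the waveform survives low
sampling rates) are summed into one trace.  Defaults: 200 neurons,
10 Hz rhythm, 5 ms jitter, 60 s.  The *isolation fraction* suppresses
each scheduled spike independently per cycle (a per-neuron permanent
mode exists).  The population rate additionally waxes and wanes under a
raised-cosine modulation (0.25 Hz, depth 0.6 by default).  The
modulation is essential, not decorative: without any within-record
envelope structure, the intact and isolated populations produce
intensity fluctuations that differ only in scale, and SD-scaled sample
entropy is scale-invariant — no peak-timing statistic could separate
them even in principle.  Real rhythms wax and wane on multi-second
timescales; isolation noise disrupts the regular surge timing that the
modulation induces, which is precisely the effect the statistic
measures.  The modulation frequency must survive the intensity
smoother (cutoff ≈ 0.3 Hz for fs = 256); the contrast weakens below
~0.2 Hz (modulation too slow to generate enough peaks) and inverts at
high modulation depth (deep troughs starve the envelope and the intact
case fragments into noise peaks).

**Jittered-burst records** (classification study) — an alpha-band
carrier, drawn per record from 8.2–10.2 Hz to emulate individual alpha
frequency variation, amplitude-modulated by Gaussian bursts (width
0.3 s, relative depth 1.5) scheduled every 2.5 s and displaced by a
class-dependent jitter fraction (0, 0.1, 0.25, 0.5 of the period).
Burst *rate* does not depend on jitter, so average band power is
matched across classes by construction; records are additionally RMS-
normalized.  Burst bumps are evaluated out to ±8 widths — truncating
earlier leaves step discontinuities of ~10⁻⁴ whose broadband splatter
is systematically jitter-dependent and measurably leaks class
information into the far filters' (otherwise near-zero) intensities.

What these generators do *not* emulate: 1/f background activity,
artifacts, inter-lead correlation, volume conduction, or any
physiological hypoxia response beyond spike suppression.  Passing the
simulation studies therefore shows the pipeline detects the modeled
mechanism under controlled conditions, not that it reproduces human
cohort effect sizes.

## Validation studies

*Isolation direction* — 40 paired replicates (intact vs isolation 0.4),
600 s records: the 10-minute segment length the statistic was designed
around; 60 s records yield ~25 envelope peaks, far below the ~100
samples entropy estimation needs.  AC is computed in the filter whose
passband contains the 10 Hz rhythm.  A one-sided sign test on the pairs
summarizes the direction.

*Feature comparison* — 20 seeds × 48 jittered-burst records (12 per
class), 300 s at 128 Hz; AC and normalized summed-intensity feature
vectors (one value per filter) scored by 5-NN under stratified 5-fold
CV with standardized features.  Undefined AC cells enter as 0 (a
constant placeholder carries no class information).

*Family-wise error* — 500 all-null cohorts (20 subjects × 192 cells),
max-T bootstrap with B = 1000 resamples of the centered differences;
corrected p-values are additionally floored at the raw t-test p.  The
observed FWER (~0.02 at nominal 0.05) reflects the conservatism of
resampled-centered max-T at this sample size.

Problem sizes throughout (replicate counts, record lengths, B) are
chosen so each study gives stable aggregates in minutes on one core.

## Statistical conventions

"Paired tests between two cohorts" is implemented as the one-sample
t-test on within-subject condition differences — the only reading under
which one-sample tests apply to a two-condition design.  Subject
normalization of summed intensity divides each filter's value by the
per-lead total, exactly canceling multiplicative electrode-conductance
gain; a z-score alternative would not cancel it exactly.  The max-T
family is the full lead × filter grid (per-lead families would control
a weaker error rate).  Degenerate cases are explicit: identical cohorts
give p = 1; zero-variance nonzero differences give p = 0 and a
`degenerate` flag.

The oxygen-saturation class labels used for the four-level comparison
harness follow the conventional strata (non-hypoxic ≥95%, indifferent
85–95%, compensatory 75–85%, critical <75%), treated half-open at the
boundaries.

## Known limitations

- The bank rebuild reproduces the published centers loosely (≤0.5 Hz),
  not the printed parameters; the design problem is degenerate enough
  that many near-flat banks exist.
- Edge transients: the first and last 3 sigma of every intensity series
  are excluded from analysis rather than corrected.
- AC needs long records (≥100 intervals ≈ several minutes of EEG at
  these smoothing settings); it is a trend statistic, not a short-
  window one.
- The isolation study's effect direction is robust, but its magnitude
  depends on the (unobservable) modulation structure assumed for the
  population rate.
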