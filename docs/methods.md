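# Methods

## Overview

`ictonet` implements a computational-biomarker pipeline for photosensitive
epilepsy built entirely on resting interictal scalp EEG: functional networks
are inferred from phase locking in the low-alpha band, a phenomenological
neuronal model is placed on the networks to simulate seizure-like dynamics,
and two derived quantities — brain network ictogenicity (BNI) and node
ictogenicity (NI) — are compared between a photoparoxysmal-response-like
(PPR) group and a control group. Because no clinical recordings ship with
the package, a synthetic cohort generator with known coupling ground truth
stands in for the data and makes every stage testable end to end.

## Preprocessing

Input segments are 20-channel 10–20-montage EEG (C3…T6, fixed alphabetical
order). The conditioning chain is: polyphase anti-aliased resampling to
250 Hz (rational ratio, e.g. 125/256 for 512 Hz sources), a fourth-order
Butterworth band-pass at 6–9 Hz applied forward–backward (zero phase;
effective magnitude response is the squared Butterworth), and a per-segment
common-average reference. The canonical segment is 20 s, i.e. Nt = 5000
samples at 250 Hz. The order (resample → filter → re-reference) is a
documentation convention; the average reference is linear and commutes with
the other stages. Automated segment picking is positional (n windows of
20 s, ≥60 s apart) with an optional amplitude-z-score veto that is off by
default; clinical artifact judgment is not modelled.

## Functional networks

For each unordered channel pair the phase-locking value
PLV = |mean_k exp(i Δφ(t_k))| and the mean lag τ = arg Σ_k exp(i Δφ(t_k))
are computed from Hilbert-transform instantaneous phases. Edges are kept
only if

1. |τ| > 2π/fs — near-zero-lag coupling is discarded as putative volume
   conduction; τ is signed, so the absolute value is compared; and
2. the observed PLV strictly exceeds at least ⌈0.95·n⌉ of n IAAFT-surrogate
   PLVs (95 of 99 at defaults). Ties count against significance.

Surrogates are iterative amplitude-adjusted Fourier transforms (10
iterations, ending on the amplitude-adjustment step, so the surrogate's
sorted sample values equal the original's exactly while the power spectrum
is approximately preserved). One surrogate is generated per channel per
replicate, band-passed again (IAAFT does not exactly respect band limits),
and each replicate contributes one matched surrogate pair per channel pair,
preserving both spectra under the null. Surrogate streams are seeded from
(segment seed, replicate, channel label); keying on the label rather than
the column index makes network inference exactly equivariant under channel
permutations. Because the 6–9 Hz signals are strongly autocorrelated, the
surrogate null for PLV is far above the 1/√Nt white-noise scale (typically
0.2–0.35 at 10 s), which the threshold automatically adapts to.

## Theta-model simulation

Each network node carries an Ermentrout–Kopell theta neuron

    dθ_i/dt = (1 − cos θ_i) + (1 + cos θ_i) I_i(t),
    I_i(t)  = I0 + ξ_i(t) + (K/N) Σ_j w_ji [1 − cos(θ_j − θ_s)],

with I0 = −1.2, Gaussian white noise ξ of standard deviation σ = 0.6 per
unit √time, w the PLV weight matrix, and K a global coupling scale. For
I < 0 the node rests near θ_s = −arccos((1+I0)/(1−I0)); for I > 0 the phase
rotates (the seizure-like state); the transition is a saddle-node-on-
invariant-circle bifurcation at I = 0. Integration is Euler–Maruyama from
θ_i(0) = θ_s with dt = 0.01; the noise increment is (1+cos θ)·σ·√dt·η, the
multiplicative factor entering exactly as the current does. The
`noise_per_step` flag switches to treating each noise draw as a constant
input over one step (amplitude σ·dt); under that reading the effective
noise is too weak to ever ignite the network, which is why the SDE reading
is the default. The first 5 % of steps are discarded as transient.

A node counts as seizure-like while, within its current rotation cycle, its
phase has passed the unstable fixed point θ_u = +arccos((1+I0)/(1−I0)) and
has not yet completed the rotation back to θ_s. This cycle bookkeeping (on
the unwrapped phase) is essential: a memoryless arc test would classify
half of the symmetric resting fluctuations around θ_s as ictal and pin the
seizure fraction near 0.5 regardless of noise level, whereas the
cycle-tracked rule gives 0 at rest, ≈1 under sustained fast rotation, and
the escape-arc fraction for uniform rotation. For I0 ≥ 0 the fixed points
merge at 0 and any rotation counts.

The canonical run length is 4×10⁶ steps; the test suite and the cohort
pipeline scale this down (10⁴–10⁵ steps) and state so per experiment. The
integrator is a numba kernel; a 10⁵-step, 20-node simulation takes ~0.2 s.

## BNI and NI

BNI(K) is the mean over nodes (and simulation repetitions) of the
seizure-like time fraction. The robust, K-free summary integrates the BNI
curve over the fixed interval [K1, K2] = [1, 40] on a uniform 40-point grid
(trapezoid), the same grid for every network; the raw area lies in [0, 39].

For NI, K is first calibrated so the intact network sits at BNI_pre = 0.5:
a coarse scan over [1, 40] (at half the repetition count) brackets the
target, and bracketed false-position refinement on the rep-averaged BNI
closes in, typically within two or three evaluations; an error is raised
if the target is not bracketed, e.g. for an empty network. Each node is then
deleted in turn and

    NI(i) = (BNI_pre − BNI_post(i)) / BNI_pre.

Two choices here deliberately follow the quantity's definition rather than
a shortcut:

- BNI_pre is re-measured at K* with the same seed policy as the post-removal
  runs, not pinned at 0.5. At full simulation length the two agree within
  the calibration tolerance; at reduced length the calibration can stop
  anywhere inside ±tol and that offset is shared across subjects, which
  would bias group comparisons if 0.5 were subtracted blindly.
- After node deletion the K/N normalization keeps the intact network's N.
  Shrinking N to 19 raises every remaining edge's gain by N/(N−1), which
  largely cancels the removal effect and drives NI toward 0 or below;
  keeping N isolates the removal itself, making NI ≤ 1, typically positive,
  and hub-sensitive. `reduced_n_norm=True` restores the shrinking-N variant.

Per-subject quantities are means over the (typically three) per-segment
values; each segment's network is calibrated independently.

## Group statistics

The test statistic reported as "U" is the rank sum W of group 1 (PPR), with
mid-ranks for ties — printed values above n1·n2 identify this convention.
The normal approximation uses μ = n1(n1+n2+1)/2, tie-corrected σ, and a 0.5
continuity correction (right tail: z = (W−μ−0.5)/σ; two-sided: |W−μ|
shrunk by 0.5). For tie-free samples with n1+n2 ≤ 15, `ranksum` switches to
the exactly enumerated null distribution (dynamic program over rank-subset
sums); the continuity-corrected normal approximation alone has worst-case
p-error 0.088 at n1=n2=2, shrinking to <0.02 at n1=n2=5.

Three separate Holm families mirror the analysis structure: the one-sided
BNI test (m=1), the one-sided occipital NI tests O1/O2 (m=2), and the
exploratory two-sided scan of the 18 remaining nodes (m=18). Effect sizes
are unpaired median differences with BCa 95 % CIs from 5000 bootstrap
resamples (scipy), falling back to percentile intervals with a warning when
BCa is degenerate. ROC analysis uses the Mann–Whitney identity
AUC = U/(n1·n2) (tie-averaged); sensitivity/specificity are reported at the
Youden-J-optimal threshold, a choice the source conventions leave open.
Supplementary measures: relative Welch band power (2 s Hann windows, 50 %
overlap) in 6–9 Hz and 7.5–12.5 Hz against a 1–45 Hz total, and occipital
connectivity strength (in- plus out-strength = twice the row sum of the
symmetric PLV matrix).

## Synthetic cohorts

The generator builds each channel as the real part of a weighted mixture of
independent unit-amplitude narrowband phasor sources (random 6–9 Hz carrier,
Brownian phase with 1 rad²/s diffusion): one global source, one per lobe
(frontal/central/posterior), one private source per channel, plus optional
per-pair sources, with white observation noise (sd 0.3) on top. Complex
coherence between two channels is then exactly the overlap of their mixing
shares, so pairwise coupling is controlled directly and independently — a
property Kuramoto-type oscillators cannot provide, because their PLV
matrices are transitively closed (a node cannot be strongly phase-locked to
many mutually independent partners). Shared sources reach channel i with
phase factor e^{iα_i}; the latent offsets α are evenly spaced over the full
circle (minimum pairwise lag 0.314 rad, ten times the zero-lag threshold)
and average to zero as phasors, so the common-average reference removes
almost none of the shared rhythm.

Baseline cohort conditions: global share 0.30, regional share 0.50
(within-lobe coherence 0.80 → PLV ≈ 0.7; cross-lobe 0.30, hovering at the
surrogate threshold), chosen once so that the BNI(K) sweep stays inside
[1, 40] for essentially every segment — the method's own requirement on the
coupling interval. The PPR-like manipulation moves occipital (O1/O2) mixing
share onto the global rhythm (default +0.2 in the study-scale cohort; +0.4
in the recovery experiment), raising the coherence of every O1/O2-involved
pair while leaving all other pairs untouched. Truncated-normal jitter on
the shares acts between subjects (sd 0.04) and between segments (sd 0.02);
lags are never jittered, keeping τ ground truth stable. Cohort layout
defaults to 26 PPR vs 20 non-PPR subjects, three 20 s segments each.

What the generator does not emulate: broadband 1/f spectra, artifacts,
non-stationarity beyond source phase diffusion, photic stimulation, or any
PPR waveform. Passing tests therefore demonstrate that the pipeline
recovers known phase-coupling structure and its ictogenic consequences
under idealized narrowband conditions — not clinical performance.

## Scaled-down experiments

The parameter-recovery experiment uses cohorts of 13 vs 10 subjects, three
10 s segments at 125 Hz, 19 surrogates, 15 000 integration steps, a 5-point
calibration scan, and NI evaluated for O1/O2 only. Simulation seeds are
shared across subjects (common random numbers), so Monte-Carlo error is
strongly correlated across subjects and cancels in the rank-based group
comparison; the networks themselves still differ. At these sizes a +0.4
occipital boost yields one-sided rank-sum z ≈ 2.5–4 per cohort, and null
cohorts reject at the nominal rate.

## Numerical notes and limitations

- Determinism: every stochastic component is seeded; derived seeds come
  from `numpy` SeedSequences keyed on (root, context) tuples, with channel
  labels (not indices) keying surrogate streams.
- Calibration declares failure when BNI(K) does not bracket 0.5 on [1, 40];
  such segments are logged and skipped, and a subject is excluded only if
  all segments fail. Group tests require ≥2 surviving subjects per group.
- The common-average reference introduces a small lag bias (~0.05–0.1 rad)
  when only a few channels carry coherent signal, since the reference mixes
  the coupled channels into every other channel; with the full-circle
  offset design the effect on cohort analyses is negligible.
- `bni_hat`, `calibrate_K` and `node_ictogenicity` accept an injectable
  `bni_fn`, used by the tests to pin integration and calibration against
  analytic stubs.
- NI values are Monte-Carlo noisy at reduced run lengths (sd ~0.05–0.1 per
  segment at 1.5×10⁴ steps); subject-level averaging over three segments
  and common random numbers are what make the group experiment well-powered
  at desk scale.
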