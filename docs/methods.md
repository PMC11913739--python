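# Methods

This document states every analysis rule and simulator choice precisely, in
the package's own terms.  Units are µm, seconds, Hz, and dF/F throughout;
wherever a standard deviation is used (z-scores, CV, influence) it is the
sample (n−1) SD.  Quantities that are undefined under their preconditions
(empty windows, zero SDs, fewer than two samples) return NaN sentinels and
are excluded from downstream aggregation.

## Time base and state classification

**Trial→frame mapping.** A stimulation trial `[onset, offset]` excludes the
closed interval of frames whose times satisfy `onset ≤ t ≤ offset` (at
10 Hz, a trial at 1.0–1.5 s excludes frames 10–15).  Excluded frames carry
photostimulation artifact and are removed from every trace statistic; trial
windows themselves are still measured on the surrounding frames.

**States.** Trials before the convulsant injection time are *baseline*.
After injection, a trial is *ictal* if its onset falls inside a seizure
interval `[onset, offset]`, otherwise *interictal*.  Interictal trials
within 30 s before a seizure onset are sub-labelled *preictal*; within 30 s
after an offset, *postictal*.  A 0.5 s guard band around every seizure
boundary takes precedence over all labels: trials whose onset falls within
it are excluded from state quantifications, because a response window that
straddles an ictal transition conflates states.

## Trace operations

**dF/F.** Whole-trace normalization `(F − m)/m`, where `m` is the mean over
frames that are neither stimulation-artifact nor ictal.  Scale-invariant by
construction; traces whose included-frame mean is non-positive are rejected.

**Activity rate.** Rectangle-rule integral of the deconvolved signal divided
by segment duration (deconvolved signals are event-like; trapezoid adds no
fidelity).

**Recruitment delay.** dF/F is baseline-subtracted against the −1.5 to
−0.5 s pre-onset mean, then the delay is the time of the first frame
at-or-above `frac` × the within-seizure maximum.  `frac` is a required
parameter: 0.65 for recruitment analyses, 0.85 for recruitment-order
displays — the discrepancy between the two conventions is preserved rather
than hidden behind a default.  Frame-resolution output; no sub-frame
interpolation.

**Annulus neuropil.** Per-frame mean over pixels whose centers lie in the
annulus `[r_in, r_out)` = [20, 100) µm around a centroid, with all labelled
somata masks removed.  This is the local population-recruitment signal used
for the neuron-vs-neuropil recruitment comparison.

**ROI overlap filter.** Putatively excitatory ROIs sharing more than 5% of
their pixels with any inhibitory ROI are dropped (label contamination);
inhibitory ROIs are always retained.

## Photostimulation responses

**Response magnitude.** Mean dF/F over the post-window `(offset,
offset + 0.5]` minus the mean over the pre-window `[onset − 0.5, onset)`.
The onset frame belongs to neither window.  Linear in the trace and
invariant to constant offsets.

**Decay constant.** On the mean-FOV trace, the time after stimulation end at
which the signal first falls strictly below 63% of its post-stimulation
maximum.  The crossing is searched after the maximum (the signal must
*decrease* below threshold); traces that never cross are undefined and
excluded.

**Z-scoring.** Each trial's response of each neuron is z-scored against that
same neuron's distribution of baseline-state responses (≥ 2 responses with
positive SD required).  This makes responses comparable across neurons with
different opsin expression and baseline excitability.

**CV.** Sample SD / mean of a neuron's responses within one state.

**Non-target selection.** Non-targets must lie strictly more than 20 µm from
every target centroid (a 20 µm exclusion zone absorbs off-target direct
photostimulation; the boundary itself is excluded).

## Wavefront geometry

A wavefront annotation is a straight line through two points at least 100 µm
apart plus an off-line reference point marking the penumbral side.  Signed
distance to the front is positive on the reference side (ahead of the
front), negative in the core.  Neurons are *proximal* at 0 ≤ d < 100,
*distal* at d > 200, *intermediate* otherwise (including the core side).

**Invasion time.** Within a seizure window, the trace is smoothed with a
3-frame boxcar; the invasion time is the last local minimum before the
within-seizure argmax (the start of the terminal rise to the maximum).

**Rolling profiles.** Values are binned by distance in 40 µm windows sliding
in 5 µm steps; bins with fewer than 5 values are suppressed; the 95% CI is
t-based on the bin's sample.

**Exclusion of recruited targets.** When profiling target responses against
front distance, a (trial, target) measurement is dropped if the target's
estimated invasion time falls within the trial's response window padded by
1.5 s on both sides.  The pad must cover the invasion-time estimator's own
error: on a slowly decaying ictal plateau the argmax drifts with noise, and
the measured error distribution of the estimator at default noise reaches
≈ 1.25 s.  A recruited target slipping through this exclusion contributes
its ictal calcium rise (z ≈ +15 to +40) to a proximal bin and corrupts the
profile sign.  The collateral cost is that proximal measurements within
≈ speed × (pad + window) of the front are lost; at default speed the 0–55 µm
rolling bins empty out, and the proximal claim is carried by the surviving
55–100 µm bins.

## Influence mapping

For a trial `t` and non-target `j` with response `r_jt`, the *predicted
response* `p_t` is the mean response of all non-targets on that trial, the
deviation is `d_jt = r_jt − p_t`, and the influence is
`I_jt = d_jt / SD_t(d_j·)` — the deviation normalized by that neuron's
across-trial deviation SD.  Subtracting `p_t` removes shared per-trial
excitability fluctuations exactly (the metric is invariant to adding any
per-trial constant to all neurons), which an ordinary trial-mean response
would confound with stimulation-driven influence.

**Distance profile.** Each (target, non-target) pair within 400 µm
contributes the non-target's across-trial mean influence to the 40 µm bin of
the pair distance.  The bin mean is pair-weighted (a non-target near several
targets genuinely carries their summed coupling), but since all pairs
sharing a non-target contribute the identical value, the bin SEM is computed
across distinct contributing non-targets — a pair-level SEM would be
overconfident by roughly the square root of the pairs-per-neuron ratio.

**Sham trials.** Artificial control trials are placed at the midpoints of
consecutive real trial onsets (same duration), where no stimulation
occurred.

**Totals.** Per-trial summed target response vs summed non-target response,
z-scored within the experiment, with their correlation: a positive
correlation is the signature of the shared excitability fluctuation the
influence metric removes.

## Circular statistics

Seizure onsets are assigned to their nearest stimulation (symmetric
nearest-neighbor in time); the onset's offset from that stimulation, divided
by the local inter-stimulation period, maps to an angle in (−π, π].  With
binning on (the default), offsets are first quantized into 1 s bins, so an
onset within ±0.5 s of a stimulation lands exactly at phase 0.  Events
outside the stimulation span are dropped.

**V-test.** For angles `θ_i` and hypothesized direction µ:
`V̄ = R·cos(θ̄ − µ)` (mean resultant length projected on µ),
`u = V̄·√(2n)`, and `p` is the upper tail of the standard normal at `u`.
Four identical angles at µ give `u = √8`, `p ≈ 0.00234`.

**Triggered fraction.** The fraction of events within ±0.5 s of their
nearest stimulation.

## The simulator

The simulator generates the study conditions, not a tuned target for the
analysis: defaults are chosen from the physical picture and frozen.

- **Geometry.** 512 × 512 µm field at 4 µm pixels; 100 neurons (40 targets,
  10 inhibitory; inhibitory neurons are never targets — the opsin is driven
  by an excitatory promoter); somata are 5 µm disks.
- **Spontaneous activity.** Poisson transients (0.08 /s, amplitude 0.5 dF/F)
  convolved with a 1 s exponential kernel, on per-neuron baselines of
  80–120 a.u., with 5% per-frame multiplicative noise; 10 Hz frames.
- **Seizures.** Scheduled (or stimulation-triggered) intervals of 30 s after
  a convulsant-injection time (150 s).  A straight front starts at the field
  corner with the smallest projection on the propagation direction and
  advances at constant speed (default 25 µm/s); each neuron is recruited
  when the front passes it.  Recruitment is a fast sigmoidal rise (0.1 s) to
  a 3.0 dF/F plateau decaying with τ = 20 s, with spontaneous transients
  suppressed while recruited (indicator saturation) and a 2 s fall after
  seizure offset; 30 s of post-ictal suppression (×0.6) follows.  This shape
  makes the within-seizure maximum the end of the recruitment rise — the
  premise of both the 65%-threshold recruitment delay and the invasion-time
  estimator.
- **Stimulation.** 0.25 s trials every 10 s.  Target amplitude =
  0.21 dF/F × gain(front distance) × (1 + ε_t), with ε_t a shared
  N(0, 0.2²) per-trial fluctuation and gain ×0.1 (core), ×0.3 (0–100 µm
  ahead), ×1.0 (100–200 µm), ×1.5 (> 200 µm).
- **Coupling.** Non-targets receive the sum over targets of a signed kernel
  of pair distance: +0.60 within 25 µm, −0.03 at 25–200 µm, 0 beyond.  The
  magnitudes are deliberately asymmetric.  Under ensemble stimulation each
  non-target sums ~20 weak suppressive weights from its 25–200 µm surround
  but rarely more than one excitatory weight, so equal magnitudes would
  produce an unphysically large net suppression and — because the 20 µm
  analysis exclusion zone removes all sub-20 µm pairs — would leave the
  nearest distance bin (dominated 1:4 by 25–40 µm suppressive pairs) with a
  *negative* mean, contradicting the local-excitation structure the kernel
  is meant to encode.  The +0.60 local weight keeps the surviving 20–25 µm
  excitatory shell visible through that geometric dilution.
- **Triggered seizures.** With probability `trigger_prob` a stimulation
  outside a seizure ignites one within 0–200 ms of stimulus offset.
- **Wavefront speed regimes.** The excitability experiments use the slow
  default (25 µm/s), giving well-separated front distances across trials.
  The neuron-vs-annulus recruitment null uses a fast front (400 µm/s):
  the 20–100 µm annulus aggregates recruitment over ±100 µm around the
  soma, so its 65% crossing lags the soma's by ≈ (annulus projection
  percentile)/speed; a null of coincident recruitment is only meaningful
  when that geometric lag is below frame resolution.
- **Ground truth.** Onset distances, recruitment times and flags, per-trial
  gains and front distances, the coupling matrix, triggered trial ids, and
  the shared fluctuations are all returned for recovery tests.
- **Determinism.** One seeded generator drives every draw; a fixed seed
  reproduces the experiment bit-identically.

## Known estimator limitations

- The self-normalized influence metric has an O(1/T) negative skew bias
  (occasional large spontaneous transients inflate a neuron's deviation SD
  in the same trials that inflate its mean deviation); it is negligible
  against bin SEMs once several hundred trials contribute, but visible in
  short recordings.
- The invasion-time estimator's argmax drifts along slowly decaying ictal
  plateaus; its error (median ≈ 0.6 s, max ≈ 1.25 s at default noise) sets
  the 1.5 s exclusion pad above.
- Recruitment delays are frame-resolution by design; RMSE against ground
  truth is bounded below by discretization (~0.3 frame periods) plus the
  threshold crossing's noise sensitivity.
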