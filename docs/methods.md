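# Methods

`pairflow` analyzes pairs of 1-D+channel trajectories — two agents moving
along a quasi-one-dimensional tank whose two channels are joined by one or
more doors — and asks two separate questions: *who moves first* (temporal
order) and *who is the information source* (direction of information flow,
DIF). Anticipatory dynamics (AD) is the regime where the two answers
disagree: the information receiver's motion runs ahead of the source's.

## Time-lag mutual information

For symbol series U and V the time-lag mutual information is the plug-in
estimate

    I(U, V, δt) = Σ P(u_{t+δt}, v_t) log₂ [ P(u_{t+δt}, v_t) / (P(u_{t+δt}) P(v_t)) ],

evaluated lag by lag on the truncated overlap of the shifted series (no
wraparound, no stationarity correction — the simplest estimator consistent
with the definition). A peak at positive lag means V leads U. With this
orientation a series that is a delayed copy of the other puts the peak at
minus the delay. All logs are base 2; entropies and MI are in bits.

x positions are discretized into `2^b` equal-width bins anchored at the
physical tank span (not the data range), default b = 2; y positions reduce
to a 1-bit channel state (upper channel = 0, a point exactly on the divider
counts as lower). Peak ties break toward the smallest |lag| and then toward
negative lag, biasing toward "no lead" over a spurious lead. The normalized
peak height divides the cross peak by the mean of the two auto zero-lag
values (the two agents' auto references are averaged because either one is
an equally defensible reference); the half-decay time is the first
nonnegative lag at which an auto curve falls below half its zero-lag value,
reported for agent 0. Default lag windows are ±5 s for x and ±30 s for y,
wide enough to contain every observed peak of either component.

## Direction-of-information-flow detectors

**Granger causality.** Per direction, an OLS autoregression of the target
on its own p lags (restricted) is compared with one that adds the other
series' p lags (unrestricted), both on the same sample window, no
intercept, inputs mean-centered. The statistic is
`F = ln(var ε / var η)` with scalar residual variances (each regression is
univariate, so the covariance determinants reduce to variances); the
direction call is the larger F. p-values use the large-sample equivalence
`n·F ~ χ²(p)` under the null — at the sample sizes involved (n ≈ 15,000)
this is indistinguishable from the exact F test, and the suite verifies a
5% nominal size to within ±2% over 1000 null simulations. The VAR order is
chosen by AIC/BIC, `IC(p) = ln det Σ_p + c(4p+2)/n` with c = 2 or ln n; a
criterion that is strictly decreasing through `p_max` (common on
long-memory trajectories, which saturate rather than attain a minimum)
returns `p_max` with a saturation flag. Default `p_max` = 20.

**Liang's T.** The closed-form covariance information-flow rate

    T_{V→U} = (C_UU C_UV C_{V,U̇} − C_UV² C_{U,U̇}) / (C_UU² C_VV − C_UU C_UV²),

with forward-difference derivatives `u̇_i = (u_{i+1} − u_i)/Δt` and all
series truncated to the common length. Covariances use 1/(n−1); the ratio
is insensitive to that choice, and T is invariant under separate linear
rescaling of either input. Direction is read off by magnitude comparison.

**Transfer entropy.** The Schreiber reduction
`T_{U→V}(h) = H(V_t | V_hist) − H(V_t | V_hist, U_hist)` with equal history
lengths h on both series, plug-in over the joint embeddings, no bias
correction. The joint state count `(2^b)^(h+1)` is the finite-sample guard:
when it reaches the sample size the estimate is strongly biased, and the
package warns rather than fails (4 states at h = 8 already span 262,144
joint states). Default h = 2..5 in the pipeline.

### Which series the detectors see

Liang's T runs on the raw x series. Granger causality and TE run on the
*discretized* series, like the TLMI. This matters more than it may appear:
when one agent is a noiseless (or nearly noiseless) causal filter of the
other — exactly the situation of the anticipatory simulator below — the
raw-series regression of the response collapses to machine-precision
residuals and GC trivially names the drive as the source, a regime no
recorded trajectory reaches. Quantization injects the observation-level
roughness that real data always has; on 2-bit series GC is correct on
following-mode data and mis-assigns the source on anticipatory data, the
same pattern the other two detectors show. At 4-bit resolution the GC call
on anticipatory pairs flips back to the true direction — direction calls
from these tools are resolution-dependent, which is itself one of the known
caveats of entropy-based causality.

## The anticipatory simulator

The negative-group-delay (NGD) responder

    Ż(t) = −α Z(t) + k (S(t) − Z(t − t_d))

is a damped system with delayed negative feedback. Its transfer function
`H(ω) = k / (iω + α + k e^{−iω t_d})` has positive phase at low frequency —
group delay ≈ −(1 − k t_d)/(α + k) — so for a band-limited drive the output
*leads* the drive while being entirely caused by it: anticipation with a
known DIF. Defaults: α = 20 s⁻¹, k = 5 s⁻¹, t_d = 1 s, Euler step
dt = 0.01 s, 300 s duration.

The drive is an Ornstein–Uhlenbeck process (Euler–Maruyama,
`W_{n+1} = W_n + dt(−W_n/τ) + σ√dt ζ_n`, τ = 1 s, σ = 63.2 s⁻¹; the noise
is scaled by √dt as usual for an SDE with unit-variance white noise ζ)
passed through a 0.3 Hz lowpass. The lowpass is implemented as **two**
cascaded single-pole IIR stages. One stage is not enough: the NGD filter
only anticipates below ≈ 0.4 Hz and amplifies-and-lags the band just above
it, so the −6 dB/octave leakage of a single pole cancels the lead almost
exactly (measured peak lag ≈ +0.01 s); with the two-stage rolloff the
responder leads by 0.06–0.08 s in every tested seed. Initial conditions
are zero and no burn-in is discarded. The feedback delay is a ring buffer;
`t_d` must be an integer multiple of dt. Fixed seeds give bit-identical
output, and halving dt leaves the sign of the lead unchanged.

On this benchmark all three detectors assign the information source to the
temporally leading Z — Granger (on the 4-bit series, matching the
discretization used for the benchmark's TLMI/TE), Liang's T (raw), and TE
(4-bit, h = 1..8) — even though the true flow is S → Z. That misdirection,
not any numeric value, is the reproducible claim, and the acceptance tests
check it as rates over ≥ 20 seeds.

## The synthetic trajectory generator

No public recordings exist, so the generator defines the test conditions.
It is deliberately minimal — the smallest model with the two empirical time
scales (sub-second x coupling; seconds-scale channel decisions):

* **Leader (following mode):** mean reversion (relaxation time 0.4 s)
  toward a goal that alternates between the channel ends with Poisson rate
  0.5 Hz, Brownian position noise 18 mm/√s, reflective walls. End-anchored
  goals reproduce the observed preference for the channel ends, and hence
  the under-use of middle doors in three-door geometries. Channel changes
  occur only within 20 mm of a door, with hazard 0.15 s⁻¹.
* **Follower (following mode):** relaxes (0.3 s) toward the leader's
  position delayed by 0.5 s, and adopts the leader's channel at its next
  door visit (hazard 1.5 s⁻¹) — so its channel changes trail by seconds.
* **Anticipatory mode:** the leader is a lowpass-OU roamer (τ = 1 s,
  0.3 Hz two-stage lowpass, ±45 mm) rather than a goal-switcher, because
  Poisson goal switches are memoryless and nothing can anticipate them;
  anticipation presupposes a predictable drive. The follower applies the
  NGD filter (α = 20 s⁻¹, k = 10 s⁻¹, t_d = 1 s at the 30 fps frame rate)
  to the leader's position; k = 10 widens the negative group delay to
  ≈ −0.3 s so the x lead (+0.13 to +0.23 s measured at 2-bit resolution)
  clears the two-frame ambiguity tolerance. Channel changes still trail.
* **Independent mode:** two uncoupled leader-style agents locked in
  different channels — the door-blocked control.

Defaults: 30 fps, 500 s (15,000 samples), 216 mm channel, divider at
70 mm, one central door. Under these defaults the following mode lands in
the empirical envelope (x half-decay 0.3–0.5 s, x cross peak −0.73 s,
y cross peak −1 to −8 s, y decay 2–9 s). The normalized x peak height runs
higher (≈ 0.55–0.77) than in real recordings (0.09–0.31) because the
synthetic coupling has no perception noise, posture dynamics, or role
drift; the classifier thresholds only require it to clear 0.10. What
passing tests show is therefore that the *pipeline logic* — relabeling,
sign rule, thresholds, detector battery — behaves correctly on data with
the right correlation structure, not that real fish would be classified
with this accuracy. Roles are constant within a run by construction;
role-switching data is out of scope.

## Classification

Labels are a pure function of the report: after relabeling agents so the y
cross peak is ≤ 0 (agent 0 = channel-change leader = information source),

* `no_interaction` iff normalized x height < 0.10 (configurable; real
  datasets contain rows at 0.09 that round to the threshold),
* else `ambiguous` if |x peak lag| ≤ 0.067 s (two frames — within tracking
  resolution no lead can be claimed),
* else `anticipatory` if the x peak lag is positive,
* else `following`.

Swapping the input agents changes no numeric output, only the `relabeled`
flag; the estimator identity I(U,V,δ) = I(V,U,−δ) on matched windows makes
the relabeling exact rather than approximate.

## Numerical and scope notes

* Plug-in estimators only; no kernel/k-NN MI, no bias correction, no
  surrogate significance testing. MI ≥ 0 and TE ≥ 0 hold exactly for these
  estimators and are asserted in tests.
* Degenerate inputs (constant series, zero-variance denominators,
  single-channel recordings) raise typed errors or skip the y analysis
  with a warning rather than emitting NaNs silently.
* No multiple-testing correction is applied to GC p-values; they are
  reported raw.
* Batch runs are deterministic: same inputs, config, and seeds give
  byte-identical summary tables.
* Out of scope: video tracking, 2-D joint discretization, bidirectionally
  coupled responders, conditional/multivariate GC, and intervention-based
  causality. The ≥6-bit TE resolution sweep is not an analysis surface;
  the resolution dependence it probes is documented above.
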