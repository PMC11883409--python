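# Methods

## The adaptation model

Every measure's time course during the 20-min split-belt bout is modelled as

y_ij(t) = c + b_i + a_f·exp(−t/r_f) + a_s·exp(−t/r_s) + ε_ij

for subject *i* at time *t* (seconds from adaptation onset), with signed
amplitudes (a measure that rises toward its plateau has negative amplitudes),
b_i ~ N(0, σ_b²) a subject-level random plateau, and ε ~ N(0, σ²) i.i.d.
The single-rate model drops the slow component. Time constants are the
63.2 % (1 − e⁻¹) completion times of their components.

**Estimation.** Because the random effect enters linearly with Gaussian
noise, the marginal likelihood is available in closed form: the per-subject
covariance is compound-symmetric, σ²(I + λJ) with λ = σ_b²/σ², so no Laplace
approximation or quadrature is needed — the reported log-likelihood is exact
and reproducible. Given (r_f, r_s, λ), the linear coefficients are profiled
by GLS and σ² by its ML expression, leaving a 2–3 dimensional smooth
optimization over (log r_f, log(r_s − r_f), log λ). The log(r_s − r_f)
parameterization enforces r_f < r_s and eliminates label switching.
Starting values come from a deterministic log-spaced 8×8 grid over the time
constants ranked by OLS residual sum of squares, plus a moment estimate of λ;
Nelder–Mead refines (xatol 1e-6, fatol 1e-9, max 4000 evaluations). When
single- and dual-rate fits are compared, the dual fit is additionally started
from the single solution, guaranteeing its likelihood dominates. Model
selection is by AIC (k counts all free parameters including the two variance
components; boundary fits with λ→0 count one fewer); ties go to fewer
parameters. Standard errors come from the central-difference Hessian of the
full log-likelihood with time constants and variance parameters on the log
scale, delta-method-transformed to (r_f, r_s).

**Degenerate inputs.** Exactly noiseless data drive σ̂² to zero; a floor of
1e-300 keeps the profile likelihood finite and the optimizer still converges
to the exact parameters. A dual fit of single-rate data collapses (a_s ≈ 0
or r_s → r_f); the result is flagged `boundary` rather than silently
reported.

## Signal processing

Kinematics are low-pass filtered at 6 Hz and forces at 20 Hz, both with a
fourth-order Butterworth applied forward–backward (zero phase; the stated
order is per pass, so the effective attenuation order doubles — at the cutoff
the two-pass amplitude gain is 0.5). Both filters are zero-phase: a phase
lag in the kinematic filter would bias step lengths, so the force filter's
convention is applied to both streams. Gait events are 20 N threshold
crossings of the filtered per-belt vertical force with sub-sample timing by
linear interpolation; load bouts under 100 ms are discarded. Strides span
consecutive fast-leg strikes and must contain the ipsilateral foot-off and
the contralateral strike and foot-off, otherwise they are flagged invalid.

**Stability.** Lab frame: x anterior, y left-lateral, z up; 0-based
indexing; positions in metres internally, MoS reported in cm. Plates report
the moment of the GRF about their own origin, so per-plate ML CoP is
Mx/Fz + plate offset; the combined CoP is the load-weighted mean with
sub-50 N plates masked. The ML CoM is recovered by a complementary filter:
ML acceleration (F/m) is trapezoid-integrated twice with linear detrending
after each integration (drift control), and the absolute position is
CoP + highpass(position − CoP) with a second-order Butterworth crossover at
0.4 Hz (configurable) — below the crossover the CoP carries the CoM, above
it the force integral does. ω₀ uses the measured leg length (trochanter
height), falling back to 0.53·height. The base of support is the stance
leg's ankle-marker ML position at contralateral foot-off (the only foot
markers collected), and MoS is signed so a medial xCoM is positive.

**Energetics.** Brockway coefficients 16.58 and 4.51 J ml⁻¹. The onset
transient of net metabolic rate is removed by dropping all breaths before
the maximum of a trailing 30-s moving average restricted to the first 3 min;
when the smoothed series plateaus, ties within one standard error of the
maximum resolve to the latest time (the end of the rise) — a plain argmax on
a plateaued series would cut at an arbitrary noise peak and retain pre-decay
breaths. CoM velocity for the work model integrates (F − mg ẑ)/m per stride
with integration constants zeroing each stride's mean velocity; leg power is
v_CoM·GRF + v_belt·(−GRF) with the belt surface moving posteriorly; work
rates are rectified trapezoid integrals over the stride divided by stride
duration, and the net rate is the sum of the four signed per-leg rates.

## Epoch and fitness analyses

Epochs: initial = [0, r_f] with r_f from the SLA dual-rate fit (not
per-measure fits; configurable); later = minutes 15–17 for biomechanics.
Metabolic windows are shifted by a 3-min lag ([lag, lag + r_f] and minutes
18–20) and their bin clocks mapped back onto the biomechanics clock. Bins
default to 3 s (5 s, also used in the field, is available via config);
a partial trailing bin is kept when it covers at least half a bin.

The interaction models (outcome ~ predictor × epoch + random intercept, ML)
reuse the same closed-form machinery as the nonlinear fits, so a
single-subject fit reduces exactly to OLS; statsmodels MixedLM serves as an
independent cross-check in the tests, not as the implementation. The
interaction is tested both by Wald F with a Satterthwaite-style denominator
df (computed numerically from the variance-parameter Hessian; the
observation-level df matches the convention of reporting fractional
denominator df) and by likelihood ratio. Simple slopes per epoch are Wald
tests on the same df machinery.

The fitness analysis centers V̇O₂peak within gender, fits linear and
quadratic OLS with and without a gender covariate, retains gender only if it
improves AIC by more than 2, selects linear vs quadratic by AIC, and — when
the quadratic wins with positive convexity — reports the vertex
−tilt/(2·convexity) on the centered scale and mapped back to raw units by
adding the sample-mean V̇O₂peak.

## The synthetic-data generator

**Measure tier.** Per-stride series (1.1-s cadence) and per-breath series
(≈4-s cadence, ±20 % jitter) are drawn from the adaptation model with
calibration defaults: SLA c = 0.05, a_f = −0.20, a_s = −0.10 with the fitted
time constants 23/321 s; fast-leg step length 25/210 s on a 0.4–0.7 m scale;
single-rate MoS 40 s (fast) and 51 s (slow) in cm; net metabolic rate
353 s slow constant with a 60-s fast constant (the fast constant is not
reported; 60 s is a plausible on-kinetics-adjacent value, chosen once —
anything much faster would be erased by transient removal); net work
30/357 s in W kg⁻¹. Amplitudes and plateaus are calibration choices on
physiological scales, not reported values; time-constant recovery is
insensitive to the amplitude scale at these signal-to-noise ratios. Noise
SDs (e.g. 0.02 SLA, 0.8 cm MoS, 0.25 W kg⁻¹ metabolic per breath) are
typical stride-to-stride / breath-to-breath variabilities.

Per-subject plateau offsets are one standard-normal draw scaled by each
measure's plateau SD, shared across the kinematic and energetic measures;
the MoS measures use an independent draw with a small SD (0.1 cm) — a
sizeable MoS plateau correlated (or even chance-correlated at n = 17) with
the SLA plateau would let the random-intercept model manufacture a
later-epoch MoS–SLA slope that the generator truth does not contain. The
slow-leg step series is derived from the fast-leg and SLA curves so the
three are algebraically consistent with the SLA definition up to noise.
Cross-measure couplings define the epoch-regression ground truth: the SLA
series receives the MoS curves' deviation-from-plateau (stability shapes SLA
only while stability itself is adapting — an initial-epoch-only effect) and
the net-work series' full deviation including stride noise (a stride-level
mechanical coupling that persists into the later epoch). The metabolic
series is uncoupled, mirroring the null finding for metabolic rate. The
metabolic series is delayed: a normalized mono-exponential rise (τ = 30 s)
reaches the start-of-adaptation value exactly at the configured lag (default
120 s, within the observed 1.5–2.5 min), after which the lag-shifted decay
follows.

**Signal tier.** Raw trials are built by inverse construction. Gait is
periodic (stride period T = 1.1 s, stance 65 %); stance vertical force is a
half-sine bump whose peak balances body weight exactly over integer strides
and which leads each scheduled strike by the time the rising flank needs to
reach the 20 N event threshold, so detected events land on schedule.
Ankle AP trajectories ride the belt line from each strike until after the
contralateral strike samples them, then transition to the next stance line
with a ninth-order (C⁴) segment ending 0.08 T before the strike — no sampled
instant is within the kinematic filter's reach of the transition, keeping
filtered step lengths within ~0.5 mm of schedule. ML force is m·ÿ for a
prescribed sway y = A sin(2πt/T) (A = 2 cm); plate moments encode the CoP
under the stance foot; stance-foot ML placements are solved so the MoS at
contralateral foot-off equals the scheduled curve. Both legs follow a
common stability schedule at this tier: the CoP-anchored CoM estimator makes
the low-frequency CoM equal the load-weighted placement midline, so opposite
common-mode drifts of the two feet are structurally unobservable — per-leg
distinct MoS dynamics are exercised at the measure tier. Per-leg AP shear
impulses (half-sine, opposite signs) carry the scheduled net work rate
through the belt power term. Breaths invert the Brockway relation at RER
0.85 around a standing rate of 1.3 W kg⁻¹.

**What the generator does not emulate** (hence what passing tests do not
show about real data): double-bump vertical GRF, marker soft-tissue
artefact and dropouts, breath-by-breath gas-exchange kinetics beyond the
rise-plus-decay shape, step-width and cadence dynamics, and any
musculoskeletal detail. Signal-level sensor noise is available but off by
default.

## Replicated validation experiments

The recovery experiments (`splitbelt.experiments`, run by
`scripts/acceptance.py` and `analysis/07`) use 17 subjects × 20 min per
cohort and 10 replicates per measure — the study's own scale, which also
keeps the full suite within minutes on one CPU. Known behaviour: the
metabolic slow constant is recovered with a ~5–10 % upward skew (replicate
means typically 355–425 s against 353 s truth). The removal rule discards
the first ~1.5 fast time constants of data, leaving r_f weakly identified,
and the likelihood geometry then skews (r_f, r_s) jointly upward; multistart
confirms these are global optima, and an oracle cut at the true decay start
shows the same skew, so this is a property of the procedure under
breath-level noise, not of the optimizer. In this experiment the onset rise
completes over three time constants (90 s) with decay following immediately.
The epoch-pattern experiment (50 replicate cohorts) checks significance
patterns only (MoS initial-only, work both epochs), at α = 0.05.

The pipeline demo (`analysis/03`) fits the *coupled* default cohort, where
the SLA series contains the stability and work couplings in addition to its
own curve; its fitted SLA fast constant therefore sits a few seconds above
the pure-curve truth. The acceptance experiments generate each measure
standalone, which is the stated recovery design.

## Known limitations

- Random effects on the plateau only and i.i.d. residuals (no
  autocorrelation), matching the stated model; stride-to-stride
  autocorrelation in real data would deflate the reported SEs.
- Random-intercept-only interaction models (no random slopes).
- The Satterthwaite-style df is a numerical approximation; LRT p-values are
  reported alongside.
- The sample-size heuristic needs at least two candidate sizes below a
  selection point, so it can never select the smallest tested N.
- The signal tier's common-mode MoS limitation above.
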