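# Methods

## Model

The OIE (optimal information and effort) model treats muscle
coactivation `u` as the control variable of an active-sensing
trade-off. The hand's deviation from the planned trajectory has
standard deviation `σt(u)` with

    σt²(u) = σv² + σκ²(u),      σκ(u) = c0 + c1·exp(−c2·u),

where `σv` is the effective visual noise of the target and `σκ` the
compliance-related deviation; the coefficients `(c0, c1, c2) =
(5.18, 49.65, 6.11)` were identified for wrist tracking and are the
package defaults (`ComplianceNoiseCoeffs`). Maximum-likelihood fusion
of the visually guided estimate with an independent haptic channel of
deviation `σh` yields the prediction error (fused variance)

    Γ(u) = σt²(u)·σh² / (σt²(u) + σh²),

bounded by `min(σt², σh²)` and strictly decreasing in `u` through `σκ`.
Coactivation adapts by gradient descent on the cost

    V(u) = Γ(u) + (γ/2)·u²,

with effort ratio `γ > 0`. A literal unit-step gradient update diverges
whenever `γ > 1` (the effort term alone maps `u ↦ (1−γ)u`), so the
iterative form uses an explicit step size ε (default 0.01):
`u ← max(u − ε·dV/du, 0)`. The fitted quantity is the equilibrium, not
the transient, and the stationary point is independent of ε.

`u` is the *normalized* coactivation (per-participant min-max rescaling
of trial means onto [0, 1], dimensionless); the compliance-noise law is
applied to it directly. The coactivation search interval is
`[0, u_max]` with `u_max = 2` by default, leaving room for supra-unity
optima. Noise deviations are in the effective model units in which the
compliance law was identified.

The stationary point solver scans `dV/du` at 64 log-spaced points on
`(0, u_max]` for a sign change (the gradient at 0 is always negative
because `dΓ/du < 0`) and refines by Brent's method to 1e−10. The
log-spaced scan guards against the flatness of the exponential at large
`u`. The blind limit (no vision, `σv → ∞`) is implemented analytically:
`Γ → σh²` independent of `u`, so the optimum is 0 for every `σh` and
`γ`; the numeric agreement of `optimal_coactivation` at `σv = 1e6` is a
test, not the implementation.

Physical-to-effective noise maps: visual `σv = −αv + βv/(1+exp(−σc))`
(logistic in the cloud's angular deviation `σc`, mm) and haptic
`σh = αp + βp·σp + δp·σp²` (quadratic in the perturbation amplitude
`σp`, Nm); default coefficients `(1.21, 66.18)` and
`(5.05, 6.84, 41.68)`. Note that with `σc` in mm the logistic is
saturated for any non-zero cloud (`exp(−21.32) ≈ 5e−10`), so the weak
and strong visual levels are nearly indistinguishable through this map
even though their identified effective deviations differ (63.66 vs
65.30). The map is implemented as stated; predictions use the
identified effective deviations directly, and `fit_visual_regression`
reports its own achieved coefficients and residual rather than
asserting the defaults.

## Comparison model

TEM (tracking-error minimization): `u_new = α·e + (1−γ)·u` with error
gain `α > 0` and forgetting rate `γ ∈ (0, 1)`. For constant error it
contracts geometrically to `u∞ = α·e/γ`, linear and increasing in `e`.
Because tracking error grows with both visual and haptic noise, TEM
predicts coactivation increasing along both noise axes — the failure
mode the OIE comparison hinges on. Only the ratio `α/γ` is identifiable
from equilibrium data, so `fit_tem_ratio` is one-parameter least
squares on that ratio. Model comparison uses AIC with the small-sample
correction, `AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)`, reported raw
and normalized by `n`; parameter counts default to `k = 7` for OIE
(six noise deviations + γ) and `k = 2` for TEM and are configurable.

## Parameter identification

If observed condition means sit at optima of `V`, the cost derivative
must vanish in every condition. The identification objective is the
summed squared stationarity (KKT) violation

    R(ξ, γ) = Σᵢⱼ [ dΓ/du(u_ij; σv_i, σh_j) + γ·u_ij ]²

over `ξ = (σv0, σv1, σv2, σh0, σh1, σh2)`, box-bounded in `[0, 70]⁶`.

**Noise search at fixed γ** (`fit_noise_pso`): a coarse grid (8 points
per axis) seeds a vectorized particle swarm (60 particles, 300
iterations, inertia 0.729, cognitive = social = 1.494, velocity
clamped to 20% of the box span) with 5 seeded restarts; each restart's
best point is refined by bounded trust-region least squares on the
nine-component residual vector with an analytic Jacobian. The polish
matters: the residual has a nearly scale-invariant valley (rescaling
`σv` and `σh` jointly changes `R` only through the fixed compliance
term), and swarm search alone stalls several percent short of the
minimizer inside it. The result is flagged consistent when the best
two restarts agree within 2% per parameter.

**Effort ratio** (`solve_gamma`): stationarity is linear in γ, so
minimizing `R` over γ at fixed ξ has the closed form
`γ* = −Σ u_ij·(dΓ/du)_ij / Σ u_ij²`.

**Joint fit** (`alternate_fit`): the coupling between ξ and γ is
genuinely degenerate. At any fixed γ the bounded search finds a
rescaled ξ with near-zero residual, so alternating the two steps is a
fixed point of whatever γ it starts from; an unconstrained joint
7-parameter search instead collapses into the trivial corner
`γ → 0, σh → 0` where every stationarity term vanishes. What breaks
the tie is the *profile* residual `r(γ) = min_ξ R(ξ, γ)`: on a
stationary-point table it is orders of magnitude smaller at the
generating effort ratio (≈1e−21) than anywhere else on the valley
(≈1e−9). The joint fit therefore (i) maps `r(γ)` on a 13-point
log-spaced grid over `[0.3, 8]`, each evaluation a multi-start bounded
least-squares run seeded from the best coarse-grid points, a Sobol
covering of the box, and the minimizers of neighbouring γ values
(valley tracking); (ii) refines every local minimum of the sampled
profile by bounded scalar minimization; (iii) re-runs a global search
at the best γ — the landscape also contains spurious scaled-down
basins whose own γ-dip lies close to the true one, and this hop moves
the search onto the deeper branch — and follows it with one more
bracket refinement; (iv) runs the full swarm search at the final γ,
keeps the deeper of that result and the profile minimizer, and
finishes with the closed-form γ solve. A single-pass sequential mode
(one noise search at a given γ, one closed-form solve) is available
behind a flag. With observation noise on the table the profile minimum
blurs and γ becomes ill-conditioned; the result is then flagged
unconverged rather than hidden.

## Synthetic experiment generator

The generator emulates the wrist-tracking study so the whole pipeline
runs without recorded data. Study conditions are the defaults
throughout: 20 s trials sampled at 100 Hz, 9 visual × haptic
conditions (cloud angular deviation σc ∈ {0, 21.32, 52.78} mm; torque
perturbation amplitude σp ∈ {0, 0.08, 0.19} Nm), 9 trials per
condition, effort ratio 2.26 and the identified effective noise
deviations as generating truth.

- **Target**: `q*(t) = 18.5·sin(2.031·t*)·sin(1.093·t*)` deg with
  `t* = t + t0`; the trial offset `t0` is drawn uniformly from the
  multi-sine's zero set, computed analytically as
  `{kπ/2.031} ∪ {kπ/1.093}` on [0, 20] s (the product of sines
  vanishes exactly where either factor does).
- **Perturbation**: `σp·sin(25t)·sin(30t)` Nm, with spectral lines at
  (30−25)/2π ≈ 0.80 Hz and (30+25)/2π ≈ 8.75 Hz.
- **Cloud**: eight dots, one replaced per 100 ms step (round-robin by
  index); per-dot draws are vertical ~ N(0, 15²) mm, angular
  ~ N(0, σc²) mm, velocity ~ N(0, 101.6²) mm/s. Frames record the
  draws; a rendering helper applies the velocity drift over a dot's
  0.8 s lifetime. Angular offsets are kept in mm on screen; a screen
  gain (1 mm ↔ 0.1 deg) applies where angular units are needed.
- **Coupling**: spring torque `0.03·(q_c − q)` Nm/deg against a
  scripted partner — the noiseless target delayed by a configurable
  lag (default 0), standing in for a predictive tracking controller,
  which is out of scope; the spring law itself is exact.
- **EMG envelopes**: a constant coactivation floor plus a reciprocal
  drive proportional to the target (gain 0.02 per deg) and a scaled
  perturbation response (gain 2), split into positive/negative parts
  for flexor/extensor, plus truncated Gaussian noise (SD 0.01). The
  pointwise minimum recovers the floor exactly in the noiseless case.
- **Wrist angle**: target plus low-pass-filtered (2 Hz) Gaussian
  deviation with SD `0.1·√Γ(u*)` deg, so synthetic tracking error
  inherits the fused-noise structure and grows with both noises.
- **Condition table**: the true value per condition is the OIE
  stationary point; the observed value adds Gaussian noise (default
  SD 0.02 normalized units) truncated at zero.

What the generator does *not* emulate: internal sensorimotor noise,
neuromuscular dynamics, reaction time, learning transients, and any
closed-loop dependence of the wrist trajectory on coactivation.
Passing round-trip tests therefore demonstrate that the identification
machinery inverts the model's own generative assumption at the study's
scale — not that the model fits arbitrary real data.

## Signal processing

EMG envelope: 2nd-order Butterworth high-pass at 20 Hz, full-wave
rectification, 2nd-order Butterworth low-pass at 15 Hz; causal
(forward-only) by default to match real-time acquisition, with a
zero-phase option; output clipped at zero because the low-pass can
undershoot and the calibration model assumes non-negative activation.
Calibration is ordinary least squares of envelope against known
torques, rejecting rank-deficient designs and non-positive
coefficients. Reciprocal activation is flexor minus extensor (flexion
positive — the sign convention is a package choice), coactivation the
pointwise minimum; the pair is a bijection on non-negative inputs.
Trial integrals (RMS tracking error, mean coactivation) use the
trapezoid rule on the 100 Hz grid. Spectra use a single un-windowed
FFT of the mean-removed 20 s trial (0.05 Hz resolution) with an
optional Hann taper.

## Numerical and design choices

- Root finding tolerances: Brent `xtol 1e−10`; least-squares polish
  `xtol/ftol/gtol 1e−14`; swarm reproducibility via
  `numpy.random.SeedSequence` spawning per restart.
- Degenerate inputs raise: empty/constant normalization range,
  all-zero coactivation tables, sign-violating calibrations,
  out-of-bounds identification parameters.
- A fitted deviation on the lower box boundary is floored at 1e−9 so
  it remains representable in the strictly-positive `EffectiveNoise`
  type.
- Tabular I/O is plain CSV with explicit headers (angles deg, torques
  Nm, times s); run manifests record config hash and SHA-256 output
  checksums, and reruns with identical config and seed reproduce
  byte-identical data files.
- Problem sizes used by the test suite and acceptance script: 20 s ×
  100 Hz trials, the 3×3 condition grid, swarm fits with 5 restarts,
  and eight randomized round-trip draws — sizes at which the full
  pipeline runs in minutes on one CPU.

## Known limitations

- The model cannot simulate movement dynamics; it predicts equilibrium
  coactivation only.
- γ identification from a single noisy 3×3 table is ill-conditioned
  (see the profile analysis above); multi-participant or repeated
  tables would be needed for stable joint estimates in practice.
- The saturated visual noise map makes σc → σv prediction uninformative
  between non-zero cloud sizes; effective deviations should be used
  directly.
- The TEM fit uses equilibrium levels only; trial-by-trial learning
  curves are out of scope.
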