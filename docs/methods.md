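# Methods

This note documents the models implemented in `ringrecal`, the numerical
choices behind them, and what the synthetic protocols do and do not show.

## Full ring attractor

The central ring is a continuum of rectified-linear rate neurons on
ψ ∈ [0, 2π), discretized at n bin centers (default n = 256; the plastic
model uses n = 128):

    τc · ∂r_c/∂t = −r_c + [W_cc ⊛ r_c + I_ext]₊

with circular convolution scaled by the grid spacing 2π/n so results are
n-independent in the continuum limit. The recurrent kernel is a Gaussian
excitatory lobe (s.d. 0.5 rad, amplitude 6 before normalization) on a
constant inhibitory floor (−0.5).

**Kernel normalization.** With a rectified-linear activation the recurrent
map is positively homogeneous, so bump amplitude is neutral: a generic
kernel makes every bump either decay or blow up exponentially. We therefore
rescale the kernel by the principal eigenvalue of the rectified map (found
by power-type iteration on the bump shape), making the converged bump an
exact, amplitude-neutral fixed point. This gives the isolated central ring
its textbook behavior: from pseudo-random nonnegative initial rates a single
bump forms, typically within ~50 ms (τc = 10 ms), and persists indefinitely
with no external input. About 1% of initializations produce two near-equal
bumps whose winner-take-all competition takes slightly longer than 100 ms to
resolve — a genuine property of marginally normalized rectified dynamics.

**Rotation rings and amplitude stability.** CW/CCW rotation rings are
quasi-static (algebraic) functions of the central activity and the velocity
neurons, matching the invariant-bump-shape (ansatz) assumption of the
reduced model: `r_i = [w_ci·r_c + W_v,i(ψ)·(u_i(v) − u_i0) + w_v0·u_i0 − Ī]₊`
with `u_cw(v) = [u0 − α v]₊`, `u_ccw(v) = [u0 + α v]₊` (u0 = 50 Hz,
α = 50 Hz per rad/s, so the linear range is |v| < 1 rad/s; out-of-range
velocities are clipped with a warning by default). In the full network the
central kernel is slightly supercritical (gain 1.08 × the neutral
normalization) and the rotation-to-central feedback is *inhibitory*
(w = −0.1) with a signed whole-bin offset b (default −6 bins ≈ 0.147 rad).
This combination is what makes the bump amplitude robustly stable with pure
ReLU rates: recurrent supercriticality pushes amplitude up, bump-limited
offset inhibition pushes it down, and the balance pins a finite amplitude
with the rotation rings genuinely active (~38% of the ring). An *excitatory*
feedback loop, by contrast, is destabilizing for any finite-amplitude bump
under a homogeneous activation. The offset sign is chosen jointly with the
feedback sign so that positive (CCW) velocity moves the bump CCW.

**Velocity pathway split.** The velocity-neuron *baseline* u0 reaches the
rotation rings through a uniform weight (w_v0 = 0.3), while only the
velocity-modulated component u_i(v) − u_i0 is weighted by the per-neuron
sensitivity profile W_v,i(ψ). With the textbook combined form, a nonuniform
W_v,i makes the baseline drive asymmetric about the bump and the bump drifts
at v = 0, destroying both the immobility invariance and the meaning of the
spatially distributed gain. The split preserves exact immobility invariance
for any W_v,i and leaves the analytic gain expression unchanged, since the
profile enters it only through the product α·W_v,i.

**Visual drive.** A bump-shaped current (scaled copy of the converged bump,
amplitude ~3 Hz) injected at θ\*; attractor dynamics pull the bump toward
it, realizing the stabilizing feedback β of the reduced model.

## Reduced model and the analytic gain profile

Bump location obeys `dθ/dt = β(θ̃) + k(θ)v` with `θ̃ = θ* − θ` wrapped to
(−π, π]. The gain profile is evaluated by quadrature on the neural grid:

    k(θ) = −b / (τc‖∂r*/∂ψ‖²) · ∫ ∂²r*(ψ−θ)/∂ψ² ·
           Σ_i α_i · W_i−c(ψ) · W_v,i(ψ) · sign(r_i*(ψ,θ,0)) dψ

with central differences for the derivatives, the squared L2 norm of the
bump-template gradient in the denominator, and `sign(·) ∈ {0,1}` the
indicator of nonzero rotation-ring activity at immobility. The integrator
for the reduced ODEs is fixed-step RK4 (dt = 10 ms default); Euler is
available for parity with the full network. The error-dynamics integrator
uses identical RK4 stages, so the two descriptions agree to machine
precision under the affine change of variables.

**Accuracy of the reduction.** The projection formula is a first-order
(small-b, small-perturbation) result. Numerically, the dominant residual is
a second-order moving-bump shape correction that scales like
τc · v · (modulation depth); we therefore use τc = 5 ms and b = 6 bins for
the full network, which puts the uniform-profile agreement below 1% across
v ∈ [0.05, 0.5] rad/s and the ±40% modulated-profile agreement near 4%
(validated at v = 0.05). Narrow rotation-ring active windows are avoided:
they require velocity weights so small that grid pinning (the discrete
lattice's residual translation barrier) dominates.

## Gain-update rules and condition checkers

Rules are plain callables `g0(k0, θ̃, v)`. The necessary-condition checker
evaluates the sign identity on a velocity × error grid around θ̃∞ (±0.5 rad,
21 points; θ̃∞ may be a constant or a function of v, estimated in practice
as the trailing-window circular mean over the last 10% of a trajectory).
The sufficient-condition checker locates the rule's zero in θ̃ (Brent's
method near the origin) and takes a central-difference slope (step 10⁻⁴ rad,
tolerance 10⁻⁸ s⁻¹). A sign subtlety in the velocity-biased (partial)
rule `g0 = μ(η k0 v² + θ̃ v)`: its zero lies at θ̃∞ = −η k0 v, so for
positive v the settled positional error is negative with magnitude η k0 v;
at operating points where the settled average gain is ≈ 1 this magnitude is
η·v, the form quoted for partial recalibration.

## Plastic (recalibrating) network

Three modifications (all parameters below are package defaults):

1. **Association ring** — leaky-rectified ring (τ = 5 ms) driven by weak
   hardwired topographic central input (gain 0.35) and plastic input from a
   visual ring (cosine bump, 30 Hz peak, half-width 1 rad) through a full
   weight matrix, threshold 16 Hz. Hebbian potentiation (rate-normalized
   outer product, rate 0.3 s⁻¹, decay 0.05 s⁻¹, bound 1.5) during a
   novel-environment phase (~4 laps at 0.5 rad/s with veridical landmarks)
   builds a diagonal band: the ring becomes visually driven and implements
   the landmark-to-position mapping. Training alternates running direction
   every lap: a moving bump is slightly tilted, and unidirectional exposure
   would imprint that tilt into the map as a systematic positional bias.
   The hardwired central gain (0.35) is set so the residual map bias is
   nulled; weaker or stronger teachers leave a positive or negative offset.
2. **Error-rate code** — the association ring inhibits the rotation rings
   through offset connections (CCW offset to the CCW ring, CW to the CW
   ring; offset 1.0 rad, gain 0.2). The CCW ring's mean rate then increases,
   and the CW ring's decreases, monotonically with θ̃ over at least ±0.4 rad
   (Spearman |ρ| = 1.0 on a 17-point sweep). The same differential
   modulation acts as a virtual velocity signal: after an abrupt landmark
   jump it re-aligns the bump with θ\* within a few seconds (error
   correction without any direct visual-to-central connection). The offset
   must be comparable to the bump half-width; a few-bin offset modulates the
   overlap of wide bumps too weakly to produce a usable code.
3. **Plastic velocity weights** — covariance-style Hebbian updates
   `ΔW_v,i ∝ (u_i(v) − u_i0)·(r_i − baseline_i)` (rate 5×10⁻⁵, bounds
   [0.2, 4] × initial). The baseline is the zero-error rotation-ring rate
   computed algebraically from the *current* central activity with the
   actual association profile translated to the zero-error position: shape
   and amplitude cancel exactly, and only the positional displacement — the
   error — drives the mean weight change, in the direction of θ̃·v as
   recalibration requires. The zero-error reference includes a
   velocity-proportional alignment offset measured once after training under
   veridical motion (the population-vector decode of a moving bump is
   displaced by its tilt). Because that reference is calibrated at gain 1,
   a recalibrated (faster or slower) bump mismatches it slightly, which
   saturates the weight drive before k0 reaches k\*: recalibration is
   stable, monotone and direction-correct in k\*, but settles short of the
   target (e.g. k\* = 1.5 → k0 ≈ 1.43 after 240 s; k\* = 0.7 → k0 ≈ 0.78),
   while veridical landmarks (k\* = 1) leave the gain within 2%. This
   imperfection is emergent, not imposed.

**Gain probes.** PI gain is estimated by landmark extinction: a copy of the
network runs with the visual ring silent and plasticity frozen at constant
probe velocity (0.5 rad/s) for one nominal lap, and the gain is the
unwrapped decoded displacement over v·T. Probing a full lap averages out
spatial gain inhomogeneity; shorter probes give local (biased) estimates.

## Synthetic protocols

The track has unit circumference mapped 1:1 to angle, so velocities are in
rad/s and gains dimensionless. The pause–resume fixture runs at 0.5 rad/s
with exact zero-velocity stops at [300, 330] s and [1200, 1230] s of a
30-minute session; the smoothed-random fixture is a low-pass (~0.1 Hz)
positive Ornstein–Uhlenbeck-style trace — a behavioral *fixture*, not a
locomotion model. Landmark protocols hold a piecewise-constant visual gain
and optional off-intervals. All generators are deterministic given a seed.

What these protocols do not capture: real running statistics (accelerations,
place-dependent speed), sensory noise in the landmark signal, spiking
variability, and 2D environments. Passing tests therefore show the
mechanisms are internally consistent and robust at these operating points,
not that parameter values are biologically calibrated.

## Problem sizes and tolerances

Default problem sizes keep every simulation deterministic and tractable on
one CPU: n = 256 (full network, dt = τc/20), n = 128 (plastic model,
dt = τc/10), 30-minute reduced-model sessions at dt = 10 ms, 180–240 s
plastic recalibration sessions per visual gain. Key validated tolerances:
full-vs-reduced speed equivalence within 5% (measured <1%), modulated
gain-profile prediction within 5% (measured ~4%), bump-shape invariance
under motion within 2% relative RMS (measured ~0.7%), immobility drift
< 0.01 rad over 10 s (measured ~1e−15, exact by symmetry), equilibrium and
change-of-variables identities at 1e−9 or better.

## Known limitations

* The analytic gain profile is first-order; its accuracy degrades for
  strong static feedback loops, fast time constants relative to bump speed
  are required, and agreement was validated only for the default network
  family.
* The plastic model's zero-error baseline uses the decoded bump position,
  which quantizes the error signal to one grid bin (~0.05 rad at n = 128);
  recalibration equilibria inherit jitter of that order.
* Recalibration learning rates are chosen for hundreds-of-seconds sessions;
  the biological timescale (tens of minutes) corresponds to proportionally
  smaller rates with identical fixed points.
* The velocity-neuron linear range bounds usable speeds; behavior outside
  |v| < u0/α is clipped, not modeled.
* The spatial gain profile is *not* homogenized by recalibration in this
  implementation: the local weight correction arrives phase-shifted (landmark
  feedback lags by ~v/β′ and the error-code wiring is offset by ~1 rad), so a
  spatial harmonic of k(θ) is slowly amplified rather than washed out during
  long sessions with a strongly inhomogeneous initial profile. Recalibration
  of the spatial average, which the protocols measure, is unaffected on the
  session lengths used here.
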