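# ringrecal

Ring attractor simulation and analysis of **path-integration gain
recalibration**.

Continuous bump attractor networks (CBANs) keep a persistent, localized bump
of activity whose peak position encodes a continuous variable — here, an
animal's position θ on a circular track. Velocity input shifts the bump
(path integration) with a gain `k` relating animal speed to bump speed, and
a landmark-driven visual input pulls the bump toward the true position θ\*.
Experiments on hippocampal place cells show that persistent conflict between
self-motion and landmarks (landmarks moved at an experimentally imposed
visual gain `k*`) does more than correct position errors: it *recalibrates*
the integration gain itself. This package implements, end to end, a theory
of how that can happen in a ring attractor:

* **Full network** (`network_core`) — firing-rate dynamics of a central ring
  (local excitation / global inhibition, rectified-linear rates) with CW/CCW
  rotation rings that conjoin bump position with velocity-neuron input and
  push–pull the bump through offset feedback connections.
* **Reduced model** (`reduced_model`) — projection of the network onto the
  bump's translation mode gives

  ```
  dθ*/dt = k* v
  dθ/dt  = β(θ* − θ) + k(θ) v
  ```

  with a landmark feedback β (sign-matching its argument, e.g. `0.66·sin`)
  and a *spatially distributed* gain profile `k(θ)` evaluated analytically
  from the network's weights and bump template; `k0` is its spatial average.
* **Gain adaptation** (`gain_adaptation`) — pluggable update rules
  `dk0/dt = g0(k0, θ̃, v)` for the wrapped error `θ̃ = θ* − θ`, the error
  dynamics in `(θ̃, k̃ = k* − k0)` coordinates, and numerical checkers for
  the recalibration conditions: `g0` must share the sign of `θ̃·v`
  (necessary; generalized to `(θ̃ − θ̃∞)·v` for partial recalibration), and
  a positive slope of `g0` with respect to `θ̃·v` at its zero is sufficient.
* **Plastic network** (`plastic_network`) — a modified ring attractor that
  actually achieves recalibration: an association ring learns the
  landmark-to-position mapping by Hebbian plasticity, offset inhibitory
  connections onto the rotation rings turn the positional error into a
  rate code (CCW rate rises, CW falls with θ̃), and covariance-style Hebbian
  plasticity of the velocity-to-rotation weights then moves the gain in the
  direction of `θ̃·v` — yielding stable, slightly imperfect recalibration
  toward `k*`, plus landmark-driven error correction.
* `synthetic_inputs` generates velocity profiles (constant, pause–resume,
  smoothed random) and landmark protocols; `analysis_io` provides configs,
  trajectory containers (CSV/HDF5) and summaries; a thin `ringrecal` CLI
  wraps the simulators.

## Worked example

Recalibrate the reduced model with the simplest sufficient rule
(`g0 = μ·θ̃·v`, μ = 0.02) against a visual gain `k* = 1.5`, starting from
`k0 = 1` (initial gain error 0.5), with β = 0.66·sin and a 30-minute
pause–resume running profile:

```python
from ringrecal import (
    ReducedState, beta_sinusoidal, gain_rule_linear,
    make_velocity_profile, simulate_reduced, summarize_trajectory,
)

velocity = make_velocity_profile("pause_resume", duration=1800.0, mean_v=0.5)
traj = simulate_reduced(
    initial=ReducedState(k0=1.0),
    velocity=velocity,
    k_star=1.5,
    beta=beta_sinusoidal(0.66),
    rule=gain_rule_linear(mu=0.02),
    dt=0.01,
)
print(summarize_trajectory(traj))
```

prints (numbers from an actual run):

```
{'t_final': 1800.0, 'n_samples': 18001,
 'theta_tilde_final': 6.33428953733528e-07,
 'theta_tilde_steady': 1.364692490394886e-06,
 'abs_theta_tilde_final': 6.33428953733528e-07,
 'k0_final': 1.4999991735712155,
 'k_tilde_final': 8.264287845172191e-07}
```

The gain error `k̃ = k* − k0` decays from 0.5 to ~8×10⁻⁷ (complete
recalibration), and the positional error is fully corrected whenever the
animal pauses (θ̃ ≈ 10⁻¹⁰ rad at pause ends). Classify a rule's
recalibration conditions from the command line:

```bash
ringrecal check-rule --rule cubic
```

reports that the cubic rule `g0 = μ(θ̃v)³` satisfies the necessary sign
conditions but fails the sufficient slope condition (its slope at the origin
is 0), exactly as the theory predicts.

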