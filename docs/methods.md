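# Methods

Mathematical construction of the model and the measurement conventions used
throughout the package. Notation: `n = 15` features, `τ = 10 ms`,
`τ_L = 150 ms`, `σ_x² = 0.1` unless stated.

## 1. Generative model

A Gaussian scale mixture (GSM) over image patches `x ∈ R^576` (24 × 24 px):

```
u ~ N(0, C)                      local feature coefficients
z ~ TruncNormal(0, 1, z ≥ 0)     global contrast
x | u, z ~ N(z A u, σ_x² I)
```

`A` (576 × 15) is a Gabor bank: 3 orientations {0, π/3, 2π/3} × 5 locations
(center plus four points 1/6 image-width in from the corners), cosine phase,
envelope minor axis 0.1 image-widths along the wave vector, major axes
linspace(0.1, 0.5, 15) assigned filter by filter, wavelength 0.13. A single
global rescale `A ← A / sqrt(tr(AᵀA)/n)` sets the mean eigenvalue of `AᵀA`
to 1; all observables reported here are invariant under such a rescale
(`u`, `C`, `M` compensate; `A u`, `z`, times, and frequencies are unchanged).
The eigenvalues of the resulting Gram matrix span a factor ≈ 4.7.

The prior covariance is matched to the likelihood so that unit-contrast
patches are approximately whitened in feature space:

```
C = (1 − σ_x²) (AᵀA)⁻¹
```

### Posteriors

Conditional on `z`, the posterior over `u` is Gaussian:

```
Σ(z) = (C⁻¹ + z²/σ_x² AᵀA)⁻¹,     ū(x, z) = z/σ_x² Σ(z) Aᵀ x
```

The joint posterior `P(u, z | x)` is handled by 1-D quadrature over a
`z`-grid (0 to 6, 801 points) after a QR reduction of `A`, giving the
marginal moments `E[u | x]`, `Var[u | x]`, `E[z | x]`, `sd[z | x]` at
`O(n)` cost per grid point (`gsm.marginal_posterior`). Because the
truncated-normal prior shrinks large contrasts, `E[z | x] < z_gen` for
high-contrast stimuli (e.g. ≈ 1.8 at `z_gen = 2`).

## 2. The Hamiltonian EI network

Hamiltonian sampling augments `u` with momenta `v` and targets
`P(u, v | x, z) ∝ P(u | x, z) N(v; B u, M⁻¹)` — a Gaussian momentum
distribution centered on `B u` so that `v` is interpretable as an inhibitory
population tracking the excitatory one. With `B = I` and the mass matrix

```
M = max(0, (AᵀA)⁻¹)    (elementwise clip; verified positive definite)
```

the stochastic dynamics

```
τ u̇ = W_uu u − W_uv v + (τ/τ_L) I_input + τ·sqrt(2/τ_L) η_u
τ v̇ = W_vu u − W_vv v − I_input       + τ·sqrt(2/τ_L) η_v
```

with the feedforward current `I_input = z/σ_x² Aᵀ(x − z A u) − C⁻¹ u
= Σ(z)⁻¹ (ū − u)` and weights

```
W_uu = BᵀMB − (τ/τ_L) MB      W_uv = BᵀM − (τ/τ_L) M
W_vu = MB + (τ/τ_L) BᵀMB      W_vv = M + (τ/τ_L) BᵀM
```

leaves the target invariant: the antisymmetric (frictionless) part is the
Hamiltonian flow and conserves the log joint density exactly in continuous
time (`dynamics.drift_hamiltonian_pure`; unit tests verify the drift of the
conserved quantity vanishes as `dt → 0`), while the `τ/τ_L` friction terms
and the noise form an Ornstein–Uhlenbeck (OU) dissipation matched by the
fluctuation–dissipation relation at noise rate `ρ² = 2/τ_L ≈ 13.3 s⁻¹`.

All four weight matrices are elementwise nonnegative because `M` is clipped
and `τ < τ_L` — the network satisfies Dale's law (`u` purely excitatory,
`v` purely inhibitory). This holds for the default bank and for randomized
valid masses (property tests).

### Contrast subsystem

The contrast is inferred jointly by one additional E-I pair `(z, v_z)` with
`B = M = 1`, scalar weights `(1 ∓ τ/τ_L, 1 ± τ/τ_L)`, and current
`I_z = (A u)ᵀ(x − z A u)/σ_x² − z`. The constraint `z ≥ 0` is enforced by a
reflecting boundary (reflect `z`, negate `v_z`), which preserves the
truncated-normal target.

### Langevin control

The control sampler drops the momenta entirely:
`u̇ = I_input/τ_L + sqrt(2/τ_L) η` (and the analogous scalar `z` equation
with `|z|` reflection). It targets the same posterior at the same noise
level, differing only in the absence of the oscillatory Hamiltonian flow.

### Stationary-law oracles

For fixed `z` the network is linear: an OU process with drift matrix

```
F = (1/τ) [[W_uu − (τ/τ_L) Σ⁻¹,  −W_uv], [W_vu + Σ⁻¹,  −W_vv]]
```

and diffusion `(2/τ_L) I`. Its stationary covariance is the block-Gaussian
target `[[Σ, ΣBᵀ], [BΣ, M⁻¹ + BΣBᵀ]]`, which solves the Lyapunov equation
`F S + S Fᵀ = −(2/τ_L) I` (checked against `scipy` to machine precision, and
against long empirical simulations within Monte-Carlo error).

## 3. Analytic reductions

### Contrast–frequency law

For fixed `z` the frictionless flow of each whitened component is a harmonic
oscillator with stiffness equal to the posterior precision, giving

```
f(z) = (1/2πτ) sqrt(z²/σ_x² + 1/(1 − σ_x²))
```

= 16.8, 30.2, 53.1, 102.0 Hz at `z` = 0, 0.5, 1, 2. The network oscillates
at the *inferred* contrast, so stimulus-averaged LFP peaks track
`f(E[z | x])` rather than `f(z_gen)`.

### Inferred-contrast transient model

Substituting the instantaneous contrast estimate `z ≈ x/(A u)` into the
fixed-z oscillator yields a 1-D nonlinear oscillator with stiffness
`x²/(σ_x² A² u²) + 1/(1 − σ_x²)`: very stiff when `u` is small (onset), soft
when `u` is large. Integrated from `u(0) = 0.1`, `u̇(0) = 0` with
`A = u_bar = 1`, the first excursion overshoots to 6.2 / 10.7 / 19.4 and
returns to baseline after 30.3 / 29.0 / 28.1 ms for `x = 0.5 / 1 / 2` —
an onset transient whose magnitude grows with contrast but whose duration is
contrast-invariant (~30 ms). Integration is velocity-Verlet at `dt = 10 µs`;
the excursion is measured to the *first local maximum* and its subsequent
return crossing (a global argmax is wrong for a conservative oscillator:
integrator energy drift can make a later cycle marginally taller).

## 4. Measurement conventions

### Integration

Euler–Maruyama, `dt = 50 µs`, recording every 10 steps (`f_s = 2 kHz`).
Observables were checked at `dt = 20–25 µs`: frequencies, convergence times,
and transients are unchanged. The one known discretization effect is a
~13% inflation of the stationary `u`-variance at `dt = 50 µs` (first-order
OU bias); tests that compare empirical covariances against exact targets
therefore integrate at `dt = 10 µs`, where the bias is below Monte-Carlo
resolution.

### LFP and spectra

LFP = mean excitatory membrane potential `mean_i u_i(t)`. Spectra are Welch
estimates (500 ms segments, 50% overlap, Hann taper), averaged over trials;
the reported peak is the argmax of power × frequency above a 5 Hz floor.
Spectrograms use a Gaussian window of 100 ms standard deviation.

At `z_gen = 2` the full sampler's spectrum is bimodal: a gamma bump near
`f(E[z|x]) ≈ 90 Hz` and a slow collective mode of the coupled `(u, z)`
dynamics near 25 Hz (it is the spectral peak of the `z` trace and disappears
when `z` is clamped). The two have comparable power × frequency on average,
so the single-peak statistic at high contrast is bistable across stimulus
draws. This is converged behavior of the model, not an estimator artifact:
the sampler's stationary moments match the quadrature posterior, and the
mode is insensitive to `dt` and to the discarded transient.

### Convergence curves (sampling efficiency)

Per repetition: draw a fresh stimulus at `z_gen = 1`, initialize the network
from the prior (`u ~ N(0, C)`, `v = B u + N(0, M⁻¹)`, `z ~ |N(0,1)|`,
`v_z ~ z + N(0,1)`), run with the stimulus on from `t = 0`, and form the
running time-average `û(t)` of the recorded `u` (the `t = 0` record — the
initial condition — is excluded). The error is
`mean_i (û_i(t) − E[u_i | x])² / Var[u_i | x]`, averaged over 100
repetitions: the sampler infers `z` jointly, so the correct reference and
normalization are the *marginal* posterior moments, and a single fair
posterior sample has expected normalized error exactly 1. The convergence
time is the first time the repetition-averaged curve drops to 1. The curve
is shallow near that level for the Langevin sampler, so its crossing time
has a large (~±20%) seed-to-seed spread; the Hamiltonian crossing is steep
and stable (~70–78 ms vs ~340–520 ms, a 4–6× speed-up).

### E–I balance

Recurrent excitatory current on cell `i` is `[W_uu u]_i`, inhibitory
`[W_uv v]_i`. Across stimuli and cells, the trial-averaged currents lie on
the identity line (total-least-squares slope ≈ 1.0): because stationarity
gives `E[v] = B E[u]` and `W_uu = W_uv` for `B = I`, balance is a structural
consequence of the sampler. Dynamically, the population-mean inhibition
tracks excitation with a short positive lag (Pearson cross-correlation peak
at positive lag, i.e. inhibition lags), as the momentum variables integrate
the excitatory state.

### Transients

Population rate = `mean(max(u, 0))` over cells and trials. Baseline = mean
of the last half of the pre-stimulus epoch; steady state = mean of the last
quarter of the post epoch; peak = max of the 5 ms-boxcar-smoothed rate in
the first 150 ms after onset. A transient is *absent* when the peak does not
exceed steady state by 3 baseline standard deviations (the null maximum over
the search window sits near 2 sd, so a 3 sd margin is required for
detection); otherwise its duration is the time from peak until the rate
first falls below steady + 10% of the excursion.

## 5. Biophysical time constants

`σ_x = 1/sqrt(N r Δt)` is the coefficient of variation of the spike count a
target population receives from `N` afferents firing at rate `r` within an
integration window `Δt` — a few hundred afferents at tens of Hz over ~5 ms
gives `σ_x ~ 0.3`, i.e. `σ_x² ≈ 0.1`.

`τ_L = 2σ²/(s r v)` follows from matching the injected noise rate
`ρ² = 2/τ_L` to the membrane-potential variance `σ²` produced by synaptic
bombardment with PSP size `s`, slope `v`, and rate `r`;
`parameters.propagate_lognormal` carries 95% ranges of all four factors
through the formula exactly (lognormal closure), spanning roughly tens to
hundreds of ms with a central value of order 100 ms. The default adopts
`τ_L = 150 ms`, i.e. `ρ² = 13.3 s⁻¹`.
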