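# Methods

## Model and discretization

The model is a 1D (ring) or 2D (T-maze lattice) continuous attractor
network with divisive normalization and spike-frequency adaptation:

    τ  dU/dt  = −U + ρ ∫ J(x,x′) r(x′) dx′ − V + I_ext
    r         = g U² / (1 + k ρ ∫ U′² dx′)
    τ_v dV/dt = −V + m U

`U` is synaptic input, `r` firing rate (arbitrary units), `V` the slow
adaptation current. Internally time is in milliseconds and space in meters;
`v_ext` is converted from m/s.

**Density folding.** Neurons sit on a uniform grid with spacing `1/ρ` (1D)
or cell area `1/ρ` (2D), so every `ρ ∫ (·) dx` becomes a plain sum over
neurons. The discrete dynamics are then invariant under refining the grid
at fixed ρ; conversely, the lattice spacing *is* a physical parameter — it
sets the neuron density and with it the recurrent drive `ρJ₀`.

**Domain.** The "linear track" is a periodic ring of circumference
`n/ρ = 2π m` (512 cells at ρ = 256/π). A ring avoids boundary artifacts;
runs that wrap are unproblematic by translation invariance (verified to
1e−8 in the tests). All 1D distances — connectivity, input, decoded
displacement — use the ring metric.

**Integration.** First-order Euler with δt = 0.3 ms (δt ≪ τ = 3 ms; a
warning triggers above τ/5). Halving and quartering δt changes the sweep
trajectory by under 2 % and the sweep amplitude by under 1 %; the error
shrinks linearly as expected for forward Euler. The model has no noise
source: every run is bit-reproducible.

**Initialization.** The network is seeded with a stereotyped Gaussian bump
at the input's start and relaxed for 500 ms with the input held static
("warmup"). Seeding matters in 2D, where a self-sustained bump coexists
with a low, input-slaved state and a zero start falls into the wrong basin.

**Rate nonlinearity and the gain.** The gain enters as `g·U²` with the
normalization integral over bare `U²`. The alternative reading `(gU)²`
was rejected empirically: it shifts the operating point so far that the
default drive cannot hold the bump (the network becomes a lapping traveling
wave instead of an oscillatory tracker).

**Silencing.** Transient inactivation clamps `r(x,t) = 0` for the window
while `U` and `V` keep integrating and the input continues — the literal
"network off" manipulation. Decoded position is undefined (NaN) inside the
window.

## Closed-form theory

All constants were (re)derived from the Gaussian integrals
(∫e^{−x²/2a²}dx = √(2π)a, ∫e^{−x²/4a²}dx = 2√π a) with the gain `g`
carried through; `g` multiplies `ρJ₀` wherever the recurrent drive appears.
This matters: with the default constants a gain-free threshold would put
`k_c ≈ 0.41 < k = 5` and predict no bump at all, contradicting simulation;
the gain-corrected `k_c = (gρJ₀)²/(8√(2π) a ρ) ≈ 10.2` is consistent.

- **Stationary bump** (m = 0):
  `A_u = [gρJ₀ + √((gρJ₀)² − 8√(2π) kρa)] / (4√π kρa)` (stable, larger
  root), `A_r = gA_u²/(1 + √(2π)kρa A_u²)`. Simulation settles onto `A_r`
  within 0.3 %.
- **Traveling bump** (α = 0, m > τ/τ_v): solving the four projection
  equations simultaneously gives, with λ = mτ_v/τ,
  `d = 2a√(1 − 1/√λ)` (adaptation lag), and
  `v_int = (2a/τ_v)·√(λ − √λ)`,
  which satisfy the center-motion relation `τ_v(1 − d²/4a²) v_int = d`
  identically (asserted to 1e−10 in the tests).
- **Oscillatory tracking** (α > 0): in the inhibition-dominated limit
  `A_u = (gJ₀ + 2√π akα)/(2√π ak(1+m))`, `ω = √(α/(τ τ_v A_u))`,
  `d₀ = τ_v v`, `A_v = √(m A_u (τA_u + ατ_v)/τ_v)` and
  `c₀² = A_v²[8a² ln(mA_u/A_v) − τ_v²v²] / (2αmA_u)`;
  oscillation exists iff the bracket is positive, which is the
  smooth/oscillatory boundary used by `classify_regime`.

**Accuracy limits (measured, not assumed).**

- `ω`: within ~2 % of simulation across the oscillatory region of the
  phase-diagram window (α ∈ [0.05, 0.16], m ∈ [0.9, 1.8]) and still ~2 %
  at the strong-adaptation default preset.
- `v_int`: the closed form overestimates the simulated drift by a nearly
  uniform ~25 % across m ∈ [0.025, 0.31]. The cause is structural: the
  ansatz treats the adaptation field as a rigid Gaussian lagging the bump,
  whereas the true traveling-state adaptation is a one-sided exponential
  smear of spatial extent `v_int·τ_v ≳ 2a`. A refinement using the exact
  co-moving adaptation filter (erfc closed form) reduces the error to
  ~17 % but no closed form we derived reaches few-percent accuracy; the
  m-dependence `√(λ − √λ)`, however, matches the simulation well. The
  simulated drift itself is fully converged (invariant under δt refinement,
  density doubling, and decoder choice).
- `c₀`: order-of-magnitude only at large m, where the constant-amplitude
  assumption behind the oscillatory solution fails (the bump height
  visibly oscillates between forward and backward sweeps there).
- The regime classifier cannot represent the driven traveling-wave state
  (weak input, strong adaptation): its decision tree maps every α > 0
  point to smooth or oscillatory. On simulation points that are smooth or
  oscillatory, classifier and simulation agree on ≳ 90 % of a grid over
  the window above, with mismatches confined to the boundary band.

## Operating point

With the stated track constants (τ=3 ms, τ_v=144 ms, ρ=256/π, a=0.4 m,
J₀=0.2, g=5, k=5, α=0.19, m=3.02) both theory and simulation put the bump
oscillation at ≈ 11.4–11.6 Hz (88 ms cycles), above the 6–10 Hz theta
band; theta-band frequencies arise in the moderate-adaptation window
(α ∈ [0.05, 0.16], m ∈ [0.9, 1.8]). Several downstream phenomena are
sensitive to this operating point:

- The bimodal→unimodal transition: the backward/forward peak-height ratio
  falls from 0.38 at m = 3.02 to ≈ 0.06–0.09 by m ≈ 3.4, crossing the 0.1
  reporting floor near m ≈ 3.3–3.4 (not between 3.02 and 3.125). The
  mechanism — stronger adaptation suppresses the backward sweep — is
  robust; the critical m is not.
- Transient silencing: the phase-vs-position curve is preserved to
  < 0.1 rad for windows of ~3 theta periods and for all cycles from the
  second after resumption, but the very first post-resume sweep deviates
  by up to ~1 rad for 1-period windows, when the half-decayed adaptation
  field distorts the restart.
- Speed invariance of phase-vs-position holds to ≤ 0.15 rad through the
  core of the precession branch; the steep tail shifts with speed because
  the sweep offset `d₀ = τ_v·v_ext` is itself speed-dependent.

## Analysis conventions

- **Cycle segmentation**: positive-going crossings of `s(t) = z − x_input`
  through its mean after 5 ms boxcar smoothing; crossings closer than
  50 ms are ripple and merge into the ongoing cycle; NaN stretches
  (silencing) are bridged linearly. Phase 0 therefore sits mid-forward
  sweep: the forward window is phases (−π/2, π/2] (s rising), the backward
  window (π/2, 3π/2].
- **Decoding**: rate-weighted circular mean of the 10 most active neurons;
  an all-silent population decodes to NaN. The decoder quantization ripple
  (≈ half a grid spacing) sets the floor used to call a trace
  non-oscillatory.
- **Peak detection**: `scipy.signal.find_peaks` with a prominence floor of
  1 % of the trace maximum; at most the largest peak per window per cycle.
  Phase curves additionally drop peaks below 5 % of the cell's maximal
  forward rate — a phase read off near-zero firing is noise. The
  phase-shift stage requires the forward peak ≥ 30 % of the traversal
  maximum (the bump actually crossing the cell).
- **Modality**: bimodal iff the median backward/forward peak-rate ratio
  over shift-stage cycles ≥ 0.1. The floor is a reporting convention —
  the underlying ratio varies continuously with m.
- **Correlograms**: biased finite-window estimator
  `(f⋆g)(ℓ) = Δt Σ f(t)g(t+ℓ)`, lags ±500 ms, optionally peak-normalized.
- **Heatmap**: firing-rate mass accumulated over (normalized field
  position `x̃ = (x − x₀)/5a`, phase unwrapped over two cycles onto
  (0°, 720°)), normalized to total mass 1.
- **Spectra**: Hann-windowed periodogram of the mean-removed rate trace;
  peaks are local maxima in 1–30 Hz sorted by power.

## T-maze

Geometry: central arm 0.84 m × 3.14 m along +y from the origin; two side
arms 0.84 m × 2.36 m along ±x at the top; junction at (0, 3.14). Neurons
on a square lattice of spacing h = 0.06 m (≈ 2 000 cells) clipped to the
T; connectivity is the 2D kernel `J₀/(2πa²)·exp(−d²/2a²)` with straight-
line Euclidean distance (left- and right-arm cells interact directly, but
at > 5 a separation the weight is negligible). The input moves up the
central-arm midline at 1.5 m/s and clamps at the junction (no decision is
made). Its Gaussian has denominator 2a², i.e. width a/√2.

The published T-maze constants stop at a = 0.3 m and J₀ = 0.0125; the
remaining operating point is this package's choice, set so the 2D network
is a self-sustained oscillatory tracker whose sweeps reach the arms:
k = 0.02 (the 2D normalization scales differently with density; k = 5
admits no bump at this lattice), α = 2.0 and m = 3.7 (input strong enough
to hold the large-amplitude 2D bump, adaptation strong enough that sweeps
cover the 1–2 m to the junction within a cycle). Result: ~6.6–7.3 Hz theta,
sweeps confined to the central arm far from the junction, strict L/R
alternation on approach, arm-cell autocorrelogram peak at 2.1 theta
periods and L/R cross-correlogram peak at 1.0 period with a zero-lag
trough. The alternation cadence is ~6–7 arm sweeps per second; pushing it
to 8 Hz while keeping arm-reaching sweeps was not achievable anywhere in
the scanned (α, m, k) range — the per-cycle arm reach is capped by the
intrinsic sweep speed, and parameter changes that speed up theta shorten
the sweeps by the same token.

## Spikes

Counts per bin are Poisson with mean `rate × Δt` (inhomogeneous thinning is
unnecessary at the bin widths used); spike times are uniform within their
bin; one seeded generator per call. The spike-phase read-out reproduces the
rate-peak phase precession (median circular deviation < 0.5 rad at the
amplitudes used in the tests). No refractoriness or non-Poisson statistics.

## Synthetic oracles and what the tests show

Unit tests validate each primitive against closed forms or brute-force
oracles (ring row sums, Gaussian normalization integrals, rejection-
sampled T-maze area, the arcsine phase law on an ideal sinusoidal sweep,
Poisson mean/Fano). The simulation-level tests exercise the same generator
the science runs use; since the model is its own ground truth (no external
data), passing tests demonstrate internal consistency of dynamics, theory
and analysis — not agreement with any experimental recording. Problem
sizes in the default test run are scaled (2.2–2.6 s simulations, 4×4
regime grids, the T-maze approach phase) relative to the full protocols,
which remain available through the CLI.
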