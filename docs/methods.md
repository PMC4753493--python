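# Methods

## Model

`actolayer` simulates a two-dimensional incompressible active polar fluid
confined between two parallel surfaces — a minimal continuum model of a thin
actomyosin layer sandwiched between a membrane and the cytosol.  The state is
a unit polarity field p(x, y, t) (local mean filament orientation, angle θ to
the x axis) on a domain periodic in x and bounded by walls at y = 0 and
y = L.  The walls anchor the polarity parallel to the surface, p = (1, 0),
and exert a generalized-slip friction on the flow: the wall shear stress is
proportional to the local slip velocity, σ_xy = ±μ v_x, which interpolates
between a stress-free surface (μ = 0) and a no-slip surface (μ → ∞).

Distortions of p cost Frank elastic energy (splay constant K₁, bend K₃; twist
does not exist in 2D), whose negative variational derivative is the molecular
field h.  The fluid obeys Stokes flow (inertia negligible at cell scales):
force balance ∂_j σ_ij = ∂_i P with incompressibility ∇·v = 0, where the
deviatoric stress is the sum of

* the symmetric constitutive stress 2η ũ + (ν/2)(p⊗h + h⊗p, traceless) +
  α p⊗p — viscosity η, flow-alignment coupling ν, and the active stress with
  activity α (α > 0 contractile: energy-consuming motors pull along p);
* the antisymmetric stress ½(p_i h_j − p_j h_i) (torque balance);
* the Ericksen stress (equilibrium stress of a distorted anisotropic fluid).

The polarity evolves by advection, corotation with the vorticity, the ν
strain-rate coupling, and relaxation h/γ (rotational friction γ), projected
transverse to p so |p| = 1 is conserved exactly in continuous time.  The full
sign table is in `docs/conventions.md`; the signs were fixed jointly by three
physical requirements — a passive (α = 0) film must dissipate its Frank
energy through the coupled flow, |ν| > 1 must flow-align while |ν| < 1
tumbles, and a contractile film must destabilize above a positive activity
threshold.  All three are enforced by tests, so any sign error in the
cross-couplings would surface as an energy-increasing passive fluid or an
inverted phase diagram.

Because the Lagrange multiplier that pins |p| = 1 is implemented as a
transverse projection of the polarity equation only, the stresses carry the
distortion molecular field (including its parallel component) and the Stokes
problem keeps a constant isotropic viscosity.  The alternative — feeding the
constraint multiplier back into the ν-coupling stress — would add an
anisotropic viscosity of order γν² and make the flow solve state-dependent;
at the parameter values used here the difference enters only the parallel
normal stress, which is gauge-like under incompressibility at linear order.

## Units and default parameters

Lengths are measured in l, stresses in σ = K/l², time in τ = γ l²/K.  The
package defaults set K₁ = K₃ = K = 1, γ = 1, η = 1, so l = τ = σ = 1 and all
quantities below are dimensionless:

| parameter | default | meaning |
|---|---|---|
| η | 1 | shear viscosity |
| γ | 1 | rotational friction of p |
| K | 1 | Frank constant (one-constant default; K₁ ≠ K₃ supported) |
| ν | 0.5 (tumbling preset) / 1.5 (aligning preset) | flow-alignment parameter |
| μ_b, μ_t | 0.01, 0.1 | wall friction (ratio 10, within the 1–10 band) |
| L_x = L_y | 10 | domain length and film thickness |
| grid | 65 nodes per direction (64 unique + wrap in x) | |
| dt | 0.0004 | RK4 step at the full grid |

The small default frictions keep the numerical spontaneous-flow threshold
within a few percent of the analytic lower bound used to normalize α/α_c, so
the first transition sits at α/α_c ≈ 1.  Activities are always specified as
ratios to that lower bound,

    α_c = (π² K / L²) [ 2η/(γ(1+ν)) + (1+ν)/2 ],

which is the exact stress-free-wall threshold of the x-invariant sector; the
no-slip threshold is exactly 4× larger (mode with kL = 2π), and finite μ
interpolates monotonically between the two.  The initial condition for every
production run is the uniform x-aligned state with the centre node rotated so
|p − (1,0)| = 0.01 (a 1% centre perturbation).

## Numerics

* **Spatial discretization.**  Fourier collocation along periodic x; centered
  second-order finite differences along y with one-sided wall rows
  (third-order for first derivatives, so composed first derivatives remain
  second-order up to the walls).  The molecular field is evaluated in an
  expanded pure-second-derivative form; this matters because a form built
  from composed first derivatives leaves the x-Nyquist mode undamped
  (spectral ∂_x annihilates it for real transforms) and admits a spurious
  self-sustained grid-scale zigzag at high activity.  A regression test pins
  the zigzag's decay.
* **Stokes solve.**  Per x-wavenumber dense collocated (v̂_x, v̂_y, P̂)
  boundary-value systems in y, with friction/no-slip/stress-free wall rows
  and continuity imposed at every node; factorized inverses are cached per
  (grid, η, bc).  The k_x = 0 block is solved separately (v_y ≡ 0; the
  pressure follows from the y-momentum quadrature).  The discrete system is
  solved to machine precision, so the momentum, divergence and wall-stress
  residuals recomputed with the package's canonical operators sit at ~1e−15
  (contract: ≤ 1e−8).  Manufactured-solution velocity errors converge at
  second order.  Known limitation: the collocated pressure space carries a
  weakly-constrained odd–even mode, so the recovered *pressure* converges at
  roughly first order near the walls; the velocity (the only quantity fed
  back into the dynamics) is unaffected.  When both walls are exactly
  stress-free the mean-slip mode is fixed by a zero-mean gauge, and a
  genuinely unbalanced mean force (which no wall can absorb) raises a gauge
  error at the 5% level — discrete compatibility of consistent data holds to
  O(h²), so a tighter check would reject valid inputs.
* **Time stepping.**  Classical RK4 on the polarity (each stage re-solves the
  Stokes problem), renormalization of |p| after each full step (stage states
  carry O(dt²) norm drift, the step-level drift before projection is
  ≤ 1e−10), anchored rows frozen.  Fixed dt = 0.0004 at the 65² grid;
  coarser grids use proportionally larger steps re-validated by the
  Richardson self-convergence test (measured temporal order ≥ 3.7).
* **Linear stability.**  The x-invariant linearization reduces to a 1D
  nonlocal operator in θ(y) (the wall friction enters through the uniform
  shear-stress constant); its spectrum is computed densely and the threshold
  bisected.  The numeric threshold lies inside the analytic interval for all
  tested (μ, ν, K, L) and converges at second order in the mesh.

## Diagnostics

* **Spatiotemporal correlation** C(Δr, Δt) = ⟨p(r₀, t)·p(r₀ + Δr, t + Δt)⟩_t,
  the dot product of unit polarities (= cos Δθ), bounded in [−1, 1] with
  C(0,0,0) = 1; r₀ defaults to the domain centre.  Both the full (Δx, Δy)
  map and the Δy = 0 cut are available.
* **k–ω spectra** of θ: subtract the anchored mean profile, Hann window in
  time, zero-pad y, 3D FFT, normalize total power to 1, sum out k_y.  The
  frequency axis uses the θ ~ e^{i(kx−ωt)} convention so a +x-traveling wave
  has ω = ck, c > 0.  The group velocity is a power-weighted straight-line
  fit through the per-k_x peak frequencies; the ridge power fraction (share
  of non-DC power within ±1.5 ω-bins of the line) distinguishes
  non-dispersive waves (→ 1) from dispersive or irregular signals.
* **Maximum Lyapunov exponent** by Benettin renormalization: companion
  trajectory offset by δ₀ = 1e−6 in the interior-RMS polarity-angle norm,
  window 0.02 time units (50 steps at dt = 0.0004; at coarser dt the window
  duration is preserved), log-growth recorded and the separation rescaled
  each window; λ is the mean over post-transient windows (first quarter
  discarded by default) with a stationarity check comparing the two halves
  of the tail.  Reported uncertainty: three standard errors of the mean.  On
  a clean periodic attractor the window samples converge deterministically
  to the neutral phase direction and the standard error collapses below any
  meaningful scale, so the classifier treats λ as "zero" within
  max(3·stderr, 1e−3 τ⁻¹); the 1e−3 floor is two orders below the slowest
  elastic rate K(π/L)²/γ ≈ 0.099 and below measured chaotic exponents
  (≈ 0.02 at the scaled grid).
* **Regime classification** (HSS / SF / TW / SC) follows the rules in
  `diagnostics.classify_regime`; all thresholds (ε_v = ε_x = 1e−6, ridge
  fraction ≥ 0.5, correlation-decay cut 0.2 in RMS over offsets at the
  largest lag, steadiness tol 1e−6) are configurable and recorded in the
  report, and an input matching no rule is labelled "indeterminate", never
  silently guessed.

## Scaled problem sizes

Full-scale runs (65² grid, dt = 0.0004, t = 400, 30 000 Lyapunov windows)
reproduce the reference phenomenology but are cluster-scale.  The package's
test suite and reproduction script therefore run the same pipeline at sizes
chosen as desk-scale defaults: 17²–33² grids, horizons t = 50–120, hundreds
of Lyapunov windows, with dt enlarged in proportion to the coarser mesh and
re-validated by the Richardson test.  At 33² the tumbling-regime sequence
HSS (α/α_c = 0.5) → SF (3) → TW (15) is reproduced cleanly; the transition
to spatiotemporal chaos at α/α_c = 100 requires the fine scales of the full
65² mesh (at 33² the same activity yields a modulated traveling wave with a
marginally positive exponent), so chaos-sensitive checks state the grid they
use.  The synthetic fixtures (manufactured Stokes solutions, plane-wave
trajectories, coupled logistic-map lattices) emulate the solver inputs and
the diagnostics' signal classes, not real cortical data: passing tests
demonstrate correctness of the operators and detectors under the model's own
assumptions (fixed |p| = 1, no defects, homogeneous activity, no turnover or
noise), not biological fidelity.

## Known limitations

* Pressure accuracy is first-order near walls (collocated weak mode, above).
* The constraint multiplier is excluded from the stress (projection closure).
* No polarity-magnitude dynamics and hence no topological defects; no
  actin turnover, no activity regulation, no thermal or active noise.
* Regime boundaries at scaled resolution shift relative to the full grid
  (notably the TW → SC boundary); thresholds quoted by the scan tools carry
  the bracketing interval as their uncertainty.
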