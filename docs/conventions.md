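# Sign and convention table

Every algebraic convention used by the implementation, in one place.
Coordinates: x periodic (length L_x), y wall-to-wall (thickness L = L_y),
walls at y = 0 (bottom) and y = L_y (top).  Fields are arrays of shape
`(n_y, n_x)`, row 0 = bottom wall.

## Kinematics

| Quantity | Definition |
|---|---|
| velocity gradient | ∂_i v_j (first index = derivative) |
| strain rate ũ_ij | ½(∂_i v_j + ∂_j v_i) − ½ δ_ij ∇·v (symmetric, traceless) |
| vorticity ω_ij | ½(∂_i v_j − ∂_j v_i); ω_xy = +Ω for rigid rotation at angular velocity Ω |
| polarity angle | θ = atan2(p_y, p_x); e⊥ = (−p_y, p_x) |

## Free energy and molecular field

- f = (K₁/2)(∇·p)² + (K₃/2)(∂_x p_y − ∂_y p_x)²  (splay + bend; no twist in 2D)
- h_i = −δF/δp_i; component form used in code (expanded, one-constant-checked):
  h_x = K₁ ∂²_x p_x + K₃ ∂²_y p_x + (K₁−K₃) ∂_x∂_y p_y, and x↔y swapped for h_y.
- h∥ = h·p, h⊥ = h·e⊥.  One-constant identity: h⊥ = K ∇²θ (any amplitude).
- For θ = ε sin(πy/L): h⊥ = −K ε (π/L)² sin(πy/L) — restoring (torques toward
  the anchored uniform state).

## Stresses (deviatoric), total σ = σˢ + σᵃ + σᵉ

- σˢ_ij = 2η ũ_ij + (ν/2)(p_i h_j + p_j h_i) − (ν/2)(p·h) δ_ij + α p_i p_j
  - α > 0 contractile: positive active stress along the polar direction.
  - the isotropic −(ν/2)(p·h)δ_ij term makes the ν-coupling traceless; under
    incompressibility it only shifts the pressure.
- σᵃ_ij = ½(p_i h_j − p_j h_i);  σᵃ_xy = +h_y/2 for p = (1,0).
- σᵉ_ij = −(∂f/∂(∂_j p_k)) ∂_i p_k (Ericksen); satisfies
  ∂_j σᵉ_ij + h_k ∂_i p_k = −∂_i f (generalized Gibbs–Duhem).

## Polarity equation of motion

∂_t p_i + (v·∇) p_i + ω_ij p_j = −ν ũ_ij p_j + h_i/γ, projected transverse to
p (the Lagrange multiplier enforcing |p| = 1), so p·dp/dt = 0 pointwise.

Reduced angle equation in uniform simple shear v = (γ̇ y, 0):
dθ/dt = −(γ̇/2)(1 + ν cos 2θ):  |ν| > 1 flow-aligning (Leslie fixed point),
|ν| < 1 flow-tumbling.

## Force balance and boundary conditions

- ∂_j σ_ij − ∂_i P = 0, ∇·v = 0; with the stress split this is
  η∇²v − ∇P + f = 0 where f = ∇·Σ(p) collects every v-independent stress.
- Walls: v_y = 0; friction (generalized slip) on the TOTAL shear stress:
  σ_xy(y=0) = +μ_b v_x(0),  σ_xy(y=L) = −μ_t v_x(L)  (traction opposes slip).
  μ = 0 ⇒ stress-free; μ → ∞ ⇒ no-slip.
- Pressure gauge: domain mean of P is zero.

## Validity flags (contractile spontaneous-flow regime)

α ≥ 0 (contractility) and ν > −1 (both closed-form threshold bounds positive).

## Critical-activity interval (one-constant K, x-invariant sector)

α_c ∈ [1, 4] × (π² K / L²) · [ 2η/(γ(1+ν)) + (1+ν)/2 ]

lower bound: stress-free walls, mode sin(πy/L); upper bound: no-slip walls,
mode with k L = 2π.  All α/α_c ratios are normalized by the lower bound.

## Discretization

- x: Fourier collocation on the n_x unique periodic nodes ("65 nodes" =
  64 unique + wrap).  y: centered second-order differences; one-sided rows at
  the walls (third-order for the first derivative so composed first
  derivatives stay second-order; see docs/methods.md).
- The spectral first derivative annihilates the x-Nyquist bin of an even
  grid (real transforms drop its imaginary part); the Stokes solver therefore
  treats the Nyquist mode like k = 0 (∂_x → 0) while keeping its −k² viscous
  damping, so the solved system matches the canonical operators exactly.
- Renormalization of |p| to 1 after each full RK4 step (stage states carry
  O(dt²) norm drift).
- k–ω spectra use the convention θ ~ e^{i(k x − ω t)}: a +x-moving
  non-dispersive wave has ω = c k with c > 0.
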