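# actolayer

Simulation and analysis of a two-dimensional **contractile active polar
fluid** sandwiched between two frictional surfaces — a minimal hydrodynamic
model of an actomyosin layer such as the cell cortex, confined between the
membrane and the cytosol.  The package is for physicists and quantitative
biologists who want to reproduce and probe how a single control parameter,
the activity, drives the layer through qualitatively different dynamical
states.

## Model in brief

The state is a unit polarity field **p** = (cos θ, sin θ) on a channel that
is periodic in x and bounded by walls at y = 0, L.  Distortions cost Frank
elastic energy f = ½K₁(∇·p)² + ½K₃(∂ₓp_y − ∂_yp_x)², with molecular field
h = −δF/δp.  The flow obeys Stokes force balance ∂ⱼσᵢⱼ = ∂ᵢP with ∇·v = 0,
where the deviatoric stress

σᵢⱼ = 2η ũᵢⱼ + (ν/2)(pᵢhⱼ + pⱼhᵢ − p·h δᵢⱼ) + α pᵢpⱼ + ½(pᵢhⱼ − pⱼhᵢ) + σᵉᵢⱼ

combines viscosity η, the flow-alignment coupling ν, the contractile active
stress α p⊗p (α > 0), the antisymmetric stress, and the Ericksen stress σᵉ.
The polarity follows

∂ₜpᵢ + (v·∇)pᵢ + ωᵢⱼpⱼ = −ν ũᵢⱼpⱼ + hᵢ/γ   (projected so |p| = 1),

with wall anchoring p = (1,0) and generalized-slip friction σ_xy = ±μ v_x at
the walls.  Above the critical activity

α_c = (π²K/L²) [ 2η/(γ(1+ν)) + (1+ν)/2 ]

(the stress-free-wall bound; the no-slip bound is exactly 4×) the quiescent
film undergoes a spontaneous-flow transition, the active analogue of the
Fréedericksz transition.  Increasing α/α_c further yields, in the
flow-tumbling regime (|ν| < 1): homogeneous steady state (HSS) → steady
spontaneous flow (SF) → traveling waves with traveling vortices (TW) →
spatiotemporal chaos (SC); the flow-aligning regime (|ν| > 1) shows no chaos
over the same activity span.  See `docs/methods.md` for the full method
description and `docs/conventions.md` for every sign convention.

## Worked example

```python
import actolayer as al

grid = al.GridSpec(n_x=32, n_y=33, L_x=10.0, L_y=10.0)
params = al.preset("tumbling")                    # eta=gamma=K=1, nu=0.5
lo, hi = al.alpha_c_interval(params, grid)
print(f"alpha_c in [{lo:.4f}, {hi:.4f}], numeric {al.find_alpha_c(params, grid):.4f}")

params = params.with_alpha(3 * lo)                # alpha/alpha_c = 3
state = al.initial_condition(grid, perturbation_percent=1.0)
traj = al.run(state, t_end=60.0, dt=0.002, params=params, grid=grid, stride=250)
sol = al.solve_flow(traj.states[-1], params, grid)
print(f"max |v_x| = {abs(sol.flow.v_x).max():.3f}, "
      f"max |v_y| = {abs(sol.flow.v_y).max():.2e}, "
      f"x-invariance = {al.x_invariance_deviation(traj.states[-1].theta):.2e}")
```

prints (exact digits may vary in the last place):

```
alpha_c in [0.2056, 0.8225], numeric 0.2150
max |v_x| = 1.623, max |v_y| = 4.16e-16, x-invariance = 2.22e-16
```

— the spontaneous-flow state: a finite shear flow along x, an x-invariant
bent polarity profile, and no wall-normal flow.  At α/α_c = 15 the same
pipeline breaks x-symmetry and `power_spectrum` + `group_velocity` report a
non-dispersive traveling wave (ridge power fraction ≈ 1); at α/α_c = 100 on
the full 65-node grid `benettin_mle` reports a positive maximum Lyapunov
exponent.

A CLI wraps the same pipeline:

```bash
actolayer simulate --preset tumbling --alpha-ratio 3 --t-end 60 --outdir out/
actolayer stability --preset tumbling
actolayer scan-alpha --preset tumbling --ratios 0.5,3,15,100 --out scan.csv
```

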