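"""Continuous-field operators of the active-gel theory on the discrete grid.

The model describes a thin incompressible film of contractile active polar
fluid.  The local mean filament orientation is a unit polarity field
p = (cos θ, sin θ); distortions cost Frank elastic energy

    f = (K1/2) (∇·p)²  +  (K3/2) (∂_x p_y − ∂_y p_x)²

(splay and bend; twist is absent in two dimensions).  The molecular field
h = −δF/δp drives relaxation, and the deviatoric stress is the sum of a
symmetric part (viscous + ν-coupling + active α p⊗p), the antisymmetric
part ½(p_i h_j − p_j h_i) and the Ericksen stress.  Every sign convention
used here is tabulated in docs/conventions.md.
"""

from __future__ import annotations

import numpy as np

from .fields import FieldState, FlowState, MolecularField, TensorField
from .grid import GridSpec
from .params import MaterialParams


def _splay_bend(state: FieldState, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    S = grid.ddx(state.p_x) + grid.ddy(state.p_y)
    B = grid.ddx(state.p_y) - grid.ddy(state.p_x)
    return S, B


def frank_energy_density(state: FieldState, params: MaterialParams,
                         grid: GridSpec) -> np.ndarray:
    """Frank distortion energy density f = K1/2 (∇·p)² + K3/2 (curl p)²."""
    # loose tolerance: RK4 stage states carry O(dt²) norm drift by design
    state.validate(anchoring=False, tol=1e-2)
    S, B = _splay_bend(state, grid)
    return 0.5 * params.K1 * S**2 + 0.5 * params.K3 * B**2


def total_frank_energy(state: FieldState, params: MaterialParams,
                       grid: GridSpec) -> float:
    return grid.integrate(frank_energy_density(state, params, grid))


def molecular_field(state: FieldState, params: MaterialParams,
                    grid: GridSpec) -> MolecularField:
    """Distortion molecular field h = −δF/δp and its (h∥, h⊥) projections.

    h_x = K1 ∂_x(∇·p) − K3 ∂_y(curl p),  h_y = K1 ∂_y(∇·p) + K3 ∂_x(curl p).
    In the one-constant case this reduces to h⊥ = K ∇²θ for any amplitude,
    so h⊥ torques the polarity toward the distortion-free state.
    """
    state.validate(anchoring=False, tol=1e-2)
    # expanded second-derivative form (uniformly second-order to the walls):
    # h_x = K1 px_xx + K3 px_yy + (K1-K3) py_xy, and x<->y swapped for h_y
    K1, K3 = params.K1, params.K3
    h_x = (K1 * grid.d2dx2(state.p_x) + K3 * grid.d2dy2(state.p_x)
           + (K1 - K3) * grid.ddy(grid.ddx(state.p_y)))
    h_y = (K3 * grid.d2dx2(state.p_y) + K1 * grid.d2dy2(state.p_y)
           + (K1 - K3) * grid.ddy(grid.ddx(state.p_x)))
    h_par = h_x * state.p_x + h_y * state.p_y
    h_perp = -h_x * state.p_y + h_y * state.p_x
    return MolecularField(h_x, h_y, h_par, h_perp)


def strain_rate_vorticity(flow: FlowState, grid: GridSpec) -> tuple[TensorField, TensorField]:
    """Symmetric-traceless strain rate ũ and vorticity ω of the velocity field.

    Convention: ω_xy = (∂_x v_y − ∂_y v_x)/2, so a rigid rotation with angular
    velocity Ω has ω_xy = Ω.
    """
    dxvx = grid.ddx(flow.v_x)
    dyvx = grid.ddy(flow.v_x)
    dxvy = grid.ddx(flow.v_y)
    dyvy = grid.ddy(flow.v_y)
    tr = 0.5 * (dxvx + dyvy)
    u = TensorField(dxvx - tr, 0.5 * (dxvy + dyvx), 0.5 * (dxvy + dyvx), dyvy - tr)
    w = 0.5 * (dxvy - dyvx)
    omega = TensorField(np.zeros_like(w), w, -w, np.zeros_like(w))
    return u, omega


def symmetric_stress(u_tilde: TensorField, state: FieldState, h: MolecularField,
                     params: MaterialParams) -> TensorField:
    """Symmetric deviatoric stress of the constitutive relation.

    σˢ_ij = 2η ũ_ij + (ν/2)(p_i h_j + p_j h_i) − (ν/2) p·h δ_ij + α p_i p_j.

    The isotropic −(ν/2) p·h δ_ij term keeps the ν-coupling traceless; under
    incompressibility it only renormalizes the pressure.  α > 0 produces
    positive (contractile) stress along the polar direction.
    """
    nu, alpha, eta = params.nu, params.alpha, params.eta
    iso = 0.5 * nu * (state.p_x * h.h_x + state.p_y * h.h_y)
    xx = 2 * eta * u_tilde.xx + nu * state.p_x * h.h_x - iso + alpha * state.p_x**2
    yy = 2 * eta * u_tilde.yy + nu * state.p_y * h.h_y - iso + alpha * state.p_y**2
    xy = (2 * eta * u_tilde.xy + 0.5 * nu * (state.p_x * h.h_y + state.p_y * h.h_x)
          + alpha * state.p_x * state.p_y)
    return TensorField(xx, xy, xy.copy(), yy)


def antisymmetric_stress(state: FieldState, h: MolecularField) -> TensorField:
    """σᵃ_ij = ½ (p_i h_j − p_j h_i); vanishes when h ∥ p."""
    xy = 0.5 * (state.p_x * h.h_y - state.p_y * h.h_x)
    z = np.zeros_like(xy)
    return TensorField(z, xy, -xy, z.copy())


def ericksen_stress(state: FieldState, params: MaterialParams,
                    grid: GridSpec) -> TensorField:
    """Equilibrium (Ericksen) stress σᵉ_ij = −(∂f/∂(∂_j p_k)) ∂_i p_k.

    Satisfies the generalized Gibbs–Duhem identity
    ∂_j σᵉ_ij + h_k ∂_i p_k = −∂_i f, i.e. its divergence combines with the
    molecular-field force into a pure gradient absorbed by the pressure.
    """
    state.validate(anchoring=False, tol=1e-2)
    S, B = _splay_bend(state, grid)
    dxpx, dypx = grid.ddx(state.p_x), grid.ddy(state.p_x)
    dxpy, dypy = grid.ddx(state.p_y), grid.ddy(state.p_y)
    K1S, K3B = params.K1 * S, params.K3 * B
    # sigma^e_{ij}: first index i = derivative direction of p, j from pi_{jk}
    xx = -(K1S * dxpx + K3B * dxpy)
    yx = -(K1S * dypx + K3B * dypy)
    xy = K3B * dxpx - K1S * dxpy
    yy = K3B * dypx - K1S * dypy
    return TensorField(xx, xy, yx, yy)


def polarity_rate(state: FieldState, flow: FlowState | None, h: MolecularField,
                  params: MaterialParams, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side dp/dt of the polarity equation of motion.

    dp_i/dt = −(v·∇)p_i − ω_ij p_j − ν ũ_ij p_j + h_i/γ, projected transverse
    to p so that p·dp/dt = 0 pointwise (the Lagrange multiplier enforcing
    |p| = 1), with dp/dt = 0 on the anchored wall rows.
    """
    if flow is None:
        raise ValueError("polarity_rate requires a solved FlowState; "
                         "pass FlowState.zero(grid) to disable advection")
    u, omega = strain_rate_vorticity(flow, grid)
    adv_x = flow.v_x * grid.ddx(state.p_x) + flow.v_y * grid.ddy(state.p_x)
    adv_y = flow.v_x * grid.ddx(state.p_y) + flow.v_y * grid.ddy(state.p_y)
    rx = (-adv_x - omega.xy * state.p_y
          - params.nu * (u.xx * state.p_x + u.xy * state.p_y)
          + h.h_x / params.gamma)
    ry = (-adv_y - omega.yx * state.p_x
          - params.nu * (u.xy * state.p_x + u.yy * state.p_y)
          + h.h_y / params.gamma)
    par = rx * state.p_x + ry * state.p_y
    rx -= par * state.p_x
    ry -= par * state.p_y
    rx[0, :] = rx[-1, :] = 0.0
    ry[0, :] = ry[-1, :] = 0.0
    return rx, ry
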