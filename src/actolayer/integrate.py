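"""Method-of-lines time integration of the coupled polarity/flow system.

Each RK4 stage recomputes the molecular field and stresses, solves the
quasi-static Stokes problem, and evaluates the transverse-projected polarity
rate; after a full step the polarity is renormalized to unit length to remove
the O(dt^5) drift of the stage combination.  Anchored wall rows never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import molecular_field, polarity_rate
from .fields import FieldState, FlowState
from .grid import GridSpec
from .params import MaterialParams
from .stokes import StokesBC, get_solver, body_force


class IntegrationError(RuntimeError):
    """Blow-up or NaN detected during time stepping."""


def initial_condition(grid: GridSpec, perturbation_percent: float = 1.0) -> FieldState:
    """Uniform x-aligned polarity, perturbed at the centre node.

    The centre polarity is rotated so that |p − (1, 0)| equals
    ``perturbation_percent`` / 100 there (unit norm preserved exactly);
    the walls stay anchored at (1, 0).
    """
    if not 0.0 <= perturbation_percent <= 10.0:
        raise ValueError("perturbation_percent must be in [0, 10]")
    state = FieldState.uniform(grid)
    eps = perturbation_percent / 100.0
    if eps > 0.0:
        # chord length |p - e_x| = 2 sin(theta/2) = eps
        theta = 2.0 * np.arcsin(eps / 2.0)
        iy, ix = grid.n_y // 2, grid.n_x // 2
        state.p_x[iy, ix] = np.cos(theta)
        state.p_y[iy, ix] = np.sin(theta)
    return state


def _rate(p_x: np.ndarray, p_y: np.ndarray, t: float, params: MaterialParams,
          grid: GridSpec, bc: StokesBC, include_flow: bool):
    """Fused stage rate: shares FFTs across the operator chain.

    Numerically identical (to rounding) to composing molecular_field,
    body_force, the Stokes solve and polarity_rate; a test pins the two
    paths against each other.
    """
    rfft, irfft = np.fft.rfft, np.fft.irfft
    n_x = grid.n_x
    ik = grid.ik_r
    Dy = grid.Dy1
    K1, K3, nu, alpha, gamma = params.K1, params.K3, params.nu, params.alpha, params.gamma

    pxh = rfft(p_x, axis=1)
    pyh = rfft(p_y, axis=1)
    dxpx = irfft(ik * pxh, n=n_x, axis=1)
    dxpy = irfft(ik * pyh, n=n_x, axis=1)
    dypx, dypy = Dy @ p_x, Dy @ p_y
    S = dxpx + dypy
    B = dxpy - dypx
    # expanded second-derivative molecular field (matches core.molecular_field)
    ik2 = ik**2
    Dy2 = grid.Dy2
    h_x = (K1 * irfft(ik2 * pxh, n=n_x, axis=1) + K3 * (Dy2 @ p_x)
           + (K1 - K3) * (Dy @ dxpy))
    h_y = (K3 * irfft(ik2 * pyh, n=n_x, axis=1) + K1 * (Dy2 @ p_y)
           + (K1 - K3) * (Dy @ dxpx))

    if include_flow:
        K1S, K3B = K1 * S, K3 * B
        iso = 0.5 * nu * (p_x * h_x + p_y * h_y)
        sxx = nu * p_x * h_x - iso + alpha * p_x**2 - (K1S * dxpx + K3B * dxpy)
        syy = nu * p_y * h_y - iso + alpha * p_y**2 + (K3B * dypx - K1S * dypy)
        sym_xy = 0.5 * nu * (p_x * h_y + p_y * h_x) + alpha * p_x * p_y
        anti = 0.5 * (p_x * h_y - p_y * h_x)
        sxy = sym_xy + anti + (K3B * dxpx - K1S * dxpy)      # sigma_{xy}
        syx = sym_xy - anti - (K1S * dypx + K3B * dypy)      # sigma_{yx}
        fxh = ik * rfft(sxx, axis=1) + rfft(Dy @ sxy, axis=1)
        fyh = ik * rfft(syx, axis=1) + rfft(Dy @ syy, axis=1)
        solver = get_solver(grid, params.eta, bc)
        vxh, vyh, _ = solver.solve_hat(fxh, fyh, rfft(sxy[0]), rfft(sxy[-1]))
        v_x = irfft(vxh, n=n_x, axis=1)
        v_y = irfft(vyh, n=n_x, axis=1)
        dxvx = irfft(ik * vxh, n=n_x, axis=1)
        dxvy = irfft(ik * vyh, n=n_x, axis=1)
        dyvx, dyvy = Dy @ v_x, Dy @ v_y
        tr = 0.5 * (dxvx + dyvy)
        uxx, uxy = dxvx - tr, 0.5 * (dxvy + dyvx)
        uyy = dyvy - tr
        w = 0.5 * (dxvy - dyvx)
        rx = (-(v_x * dxpx + v_y * dypx) - w * p_y
              - nu * (uxx * p_x + uxy * p_y) + h_x / gamma)
        ry = (-(v_x * dxpy + v_y * dypy) + w * p_x
              - nu * (uxy * p_x + uyy * p_y) + h_y / gamma)
        flow = FlowState(v_x, v_y, np.zeros_like(v_x))
    else:
        rx = h_x / gamma
        ry = h_y / gamma
        flow = FlowState.zero(grid)
    par = rx * p_x + ry * p_y
    rx = rx - par * p_x
    ry = ry - par * p_y
    rx[0, :] = rx[-1, :] = 0.0
    ry[0, :] = ry[-1, :] = 0.0
    return rx, ry, flow


def rk4_step(state: FieldState, dt: float, params: MaterialParams, grid: GridSpec,
             bc: StokesBC, *, include_flow: bool = True,
             renormalize: bool = True) -> FieldState:
    """One fourth-order Runge–Kutta step of length dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    px, py, t = state.p_x, state.p_y, state.t
    k1x, k1y, _ = _rate(px, py, t, params, grid, bc, include_flow)
    k2x, k2y, _ = _rate(px + 0.5 * dt * k1x, py + 0.5 * dt * k1y, t + 0.5 * dt,
                        params, grid, bc, include_flow)
    k3x, k3y, _ = _rate(px + 0.5 * dt * k2x, py + 0.5 * dt * k2y, t + 0.5 * dt,
                        params, grid, bc, include_flow)
    k4x, k4y, _ = _rate(px + dt * k3x, py + dt * k3y, t + dt,
                        params, grid, bc, include_flow)
    new_x = px + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    new_y = py + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    if renormalize:
        norm = np.sqrt(new_x**2 + new_y**2)
        new_x = new_x / norm
        new_y = new_y / norm
    vmax = max(np.abs(new_x).max(), np.abs(new_y).max())
    if not np.isfinite(vmax) or vmax > 10.0:
        raise IntegrationError(
            f"polarity blow-up at t={t + dt:.6g} (max component {vmax:.3e})")
    return FieldState(new_x, new_y, t + dt)


@dataclass
class Trajectory:
    """Time-ordered polarity snapshots with per-sample scalar diagnostics."""

    times: np.ndarray
    states: list
    flows: list | None
    params: MaterialParams
    grid: GridSpec
    stride: int
    max_rate: np.ndarray = field(default=None)
    max_speed: np.ndarray = field(default=None)

    @property
    def dt_sample(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def theta(self) -> np.ndarray:
        """Polarity-angle stack of shape (n_snapshots, n_y, n_x)."""
        return np.stack([s.theta for s in self.states])


def run(state: FieldState, t_end: float, dt: float, params: MaterialParams,
        grid: GridSpec, bc: StokesBC | None = None, *, stride: int = 1,
        include_flow: bool = True, record_flow: bool = False) -> Trajectory:
    """Fixed-step RK4 integration with snapshot recording every ``stride`` steps.

    Deterministic: identical inputs give bit-identical trajectories.
    """
    if bc is None:
        bc = StokesBC.from_params(params)
    n_steps = int(round((t_end - state.t) / dt)) if t_end > state.t else 0
    times = [state.t]
    states = [state.copy()]
    flows = [] if record_flow else None
    rx, ry, flow0 = _rate(state.p_x, state.p_y, state.t, params, grid, bc,
                          include_flow)
    max_rate = [float(np.hypot(rx, ry).max())]
    max_speed = [flow0.max_speed]
    if record_flow:
        flows.append(flow0)
    cur = state
    for step in range(1, n_steps + 1):
        cur = rk4_step(cur, dt, params, grid, bc, include_flow=include_flow)
        if step % stride == 0 or step == n_steps:
            rx, ry, flow = _rate(cur.p_x, cur.p_y, cur.t, params, grid, bc,
                                 include_flow)
            times.append(cur.t)
            states.append(cur.copy())
            max_rate.append(float(np.hypot(rx, ry).max()))
            max_speed.append(flow.max_speed)
            if record_flow:
                flows.append(flow)
    return Trajectory(np.asarray(times), states, flows, params, grid, stride,
                      np.asarray(max_rate), np.asarray(max_speed))


def detect_steady_state(traj: Trajectory, tol: float = 1e-6,
                        consecutive: int = 10) -> tuple[bool, float | None]:
    """Steady iff max-norm of dp/dt stays below tol over consecutive samples."""
    if traj.max_rate is None or len(traj.max_rate) == 0:
        raise ValueError("trajectory carries no rate diagnostics")
    below = traj.max_rate < tol
    count = 0
    for i, ok in enumerate(below):
        count = count + 1 if ok else 0
        if count >= min(consecutive, len(below)):
            return True, float(traj.times[i - count + 1])
    return False, None
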