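"""Quasi-static Stokes flow slaved to the polarity field.

Force balance  ∂_j σ_ij − ∂_i P = 0  with  ∇·v = 0, where the total
deviatoric stress splits into the isotropic viscous part 2η ũ and the
velocity-independent polarity stress Σ(p) (ν-coupling + active + antisymmetric
+ Ericksen).  The momentum equation solved for v is therefore

    η ∇² v_i − ∂_i P + f_i = 0,        f_i = ∂_j Σ_ij(p),

with periodic x, impenetrable walls (v_y = 0) and generalized-slip friction:
total shear stress σ_xy = +μ_b v_x at y = 0 and σ_xy = −μ_t v_x at y = L_y
(wall traction opposing slip); μ = 0 is stress-free and μ → ∞ approaches
no-slip.  The solver Fourier-transforms along x and solves a dense
(v̂_x, v̂_y, P̂) two-point boundary-value system per wavenumber; the k_x = 0
block is handled separately (v_y ≡ 0 there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (antisymmetric_stress, ericksen_stress, molecular_field,
                   symmetric_stress)
from .fields import FieldState, FlowState, MolecularField, TensorField
from .grid import GridSpec, divergence
from .params import MaterialParams


class GaugeError(RuntimeError):
    """The k_x = 0 velocity block is singular and the data are incompatible."""


@dataclass(frozen=True)
class StokesBC:
    """Wall boundary conditions for the flow.

    ``kind_*`` is one of ``friction | no_slip | stress_free``; friction with
    μ = 0 is identical to stress_free.  v_y = 0 at both walls always.
    """

    mu_bottom: float = 0.0
    mu_top: float = 0.0
    kind_bottom: str = "friction"
    kind_top: str = "friction"

    def __post_init__(self) -> None:
        for kind in (self.kind_bottom, self.kind_top):
            if kind not in ("friction", "no_slip", "stress_free"):
                raise ValueError(f"unknown wall kind {kind!r}")
        if self.mu_bottom < 0 or self.mu_top < 0:
            raise ValueError("friction coefficients must be non-negative")

    @classmethod
    def from_params(cls, params: MaterialParams) -> "StokesBC":
        return cls(mu_bottom=params.mu_bottom, mu_top=params.mu_top)

    def mu_eff(self) -> tuple[float, float]:
        """Effective (μ_b, μ_t) with stress_free mapped to 0; None for no-slip."""
        mb = None if self.kind_bottom == "no_slip" else (
            0.0 if self.kind_bottom == "stress_free" else self.mu_bottom)
        mt = None if self.kind_top == "no_slip" else (
            0.0 if self.kind_top == "stress_free" else self.mu_top)
        return mb, mt


@dataclass
class StokesSolution:
    flow: FlowState
    residuals: dict


# ----------------------------------------------------------------------
# polarity stress and body force
# ----------------------------------------------------------------------

def polarity_stress(state: FieldState, h: MolecularField, params: MaterialParams,
                    grid: GridSpec) -> TensorField:
    """Total velocity-independent stress Σ(p) = σˢ(ũ=0) + σᵃ + σᵉ."""
    zero_u = TensorField.zero(grid.shape)
    return (symmetric_stress(zero_u, state, h, params)
            + antisymmetric_stress(state, h)
            + ericksen_stress(state, params, grid))


def body_force(state: FieldState, h: MolecularField, params: MaterialParams,
               grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """f_i = ∂_j Σ_ij plus the wall rows of Σ_xy entering the friction BC.

    Returns ``(f_x, f_y, g_bottom, g_top)`` where g_* are the polarity
    contributions to the wall shear stress.
    """
    sig = polarity_stress(state, h, params, grid)
    f_x = grid.ddx(sig.xx) + grid.ddy(sig.xy)
    f_y = grid.ddx(sig.yx) + grid.ddy(sig.yy)
    return f_x, f_y, sig.xy[0, :].copy(), sig.xy[-1, :].copy()


def _sigma_yy_mean_profile(state: FieldState, h: MolecularField,
                           params: MaterialParams, grid: GridSpec) -> np.ndarray:
    return polarity_stress(state, h, params, grid).yy.mean(axis=1)


# ----------------------------------------------------------------------
# per-wavenumber solver with cached factorizations
# ----------------------------------------------------------------------

class StokesSolver:
    """Direct solver for one (grid, η, bc) combination; factorizations cached."""

    def __init__(self, grid: GridSpec, eta: float, bc: StokesBC) -> None:
        self.grid = grid
        self.eta = eta
        self.bc = bc
        n = grid.n_y
        self._nk = grid.n_x // 2 + 1
        self._kx = 2.0 * np.pi * np.fft.rfftfreq(grid.n_x, d=grid.h_x)
        # the x-Nyquist bin of an even grid is annihilated by the spectral
        # first derivative, so it is solved like the k = 0 block (below) with
        # the -k^2 Laplacian term retained
        self._has_nyquist = grid.n_x % 2 == 0
        last = self._nk - 1 if self._has_nyquist else self._nk
        # batched explicit inverses for the regular k != 0 modes
        self._inv = (np.stack([np.linalg.inv(self._matrix(k))
                               for k in self._kx[1:last]])
                     if last > 1 else None)
        self._nreg = last - 1
        self._k0 = self._k0_matrix()
        if self._has_nyquist:
            n = grid.n_y
            self._knyq = self._k0_matrix()
            self._knyq[1:n - 1, :] -= (eta * self._kx[-1] ** 2
                                       * np.eye(n)[1:n - 1, :])

    # -- assembly -------------------------------------------------------

    def _matrix(self, k: float) -> np.ndarray:
        grid, eta, bc = self.grid, self.eta, self.bc
        n = grid.n_y
        D1, D2 = grid.Dy1, grid.Dy2
        A = np.zeros((3 * n, 3 * n), dtype=complex)
        ivx, ivy, ip = 0, n, 2 * n
        mb, mt = bc.mu_eff()
        # x-momentum interior rows
        for j in range(1, n - 1):
            A[j, ivx:ivx + n] = eta * D2[j, :]
            A[j, ivx + j] += -eta * k**2
            A[j, ip + j] = -1j * k
        # wall rows: friction / no-slip on v_x
        for row, wall in ((0, "b"), (n - 1, "t")):
            mu = mb if wall == "b" else mt
            if mu is None:  # no-slip
                A[row, ivx + row] = 1.0
            else:
                A[row, ivx:ivx + n] = eta * D1[row, :]
                A[row, ivy + row] = eta * 1j * k
                A[row, ivx + row] += -mu if wall == "b" else mu
        # y-momentum interior rows
        for j in range(1, n - 1):
            A[ivy + j, ivy:ivy + n] = eta * D2[j, :]
            A[ivy + j, ivy + j] += -eta * k**2
            A[ivy + j, ip:ip + n] = -D1[j, :]
        # impenetrable walls
        A[ivy + 0, ivy + 0] = 1.0
        A[ivy + n - 1, ivy + n - 1] = 1.0
        # continuity at every node
        for j in range(n):
            A[ip + j, ivx + j] = 1j * k
            A[ip + j, ivy:ivy + n] = D1[j, :]
        return A

    def _k0_matrix(self) -> np.ndarray:
        grid, eta, bc = self.grid, self.eta, self.bc
        n = grid.n_y
        A = np.zeros((n, n))
        A[1:n - 1, :] = eta * grid.Dy2[1:n - 1, :]
        mb, mt = bc.mu_eff()
        if mb is None:
            A[0, 0] = 1.0
        else:
            A[0, :] = eta * grid.Dy1[0, :]
            A[0, 0] += -mb
        if mt is None:
            A[-1, -1] = 1.0
        else:
            A[-1, :] = eta * grid.Dy1[-1, :]
            A[-1, -1] += mt
        return A

    # -- solve ----------------------------------------------------------

    def solve(self, f_x: np.ndarray, f_y: np.ndarray,
              g_bottom: np.ndarray | None = None,
              g_top: np.ndarray | None = None) -> FlowState:
        grid = self.grid
        zx = np.zeros(grid.n_x) if g_bottom is None else g_bottom
        zt = np.zeros(grid.n_x) if g_top is None else g_top
        vxh, vyh, ph = self.solve_hat(np.fft.rfft(f_x, axis=1),
                                      np.fft.rfft(f_y, axis=1),
                                      np.fft.rfft(zx), np.fft.rfft(zt),
                                      want_pressure=True)
        v_x = np.fft.irfft(vxh, n=grid.n_x, axis=1)
        v_y = np.fft.irfft(vyh, n=grid.n_x, axis=1)
        v_y[0, :] = v_y[-1, :] = 0.0        # exact in hat space; scrub irfft roundoff
        P = np.fft.irfft(ph, n=grid.n_x, axis=1)
        P -= grid.mean(P)
        return FlowState(v_x, v_y, P)

    def solve_hat(self, fxh: np.ndarray, fyh: np.ndarray, gbh: np.ndarray,
                  gth: np.ndarray, want_pressure: bool = False):
        """Hat-space solve; pressure (k=0 quadrature) only when requested."""
        grid = self.grid
        n = grid.n_y
        vxh = np.zeros((n, self._nk), dtype=complex)
        vyh = np.zeros((n, self._nk), dtype=complex)
        ph = np.zeros((n, self._nk), dtype=complex)
        mb, mt = self.bc.mu_eff()
        # regular k != 0 modes, batched
        if self._nreg > 0:
            nm = self._nreg
            mr = 1 + nm
            rhs = np.zeros((nm, 3 * n), dtype=complex)
            rhs[:, 1:n - 1] = -fxh[1:n - 1, 1:mr].T
            if mb is not None:
                rhs[:, 0] = -gbh[1:mr]
            if mt is not None:
                rhs[:, n - 1] = -gth[1:mr]
            rhs[:, n + 1:2 * n - 1] = -fyh[1:n - 1, 1:mr].T
            sol = np.matmul(self._inv, rhs[:, :, None])[:, :, 0]
            vxh[:, 1:mr] = sol[:, :n].T
            vyh[:, 1:mr] = sol[:, n:2 * n].T
            ph[:, 1:mr] = sol[:, 2 * n:].T
        if self._has_nyquist:
            # Nyquist: d/dx -> 0 under the canonical operators; v_y = 0 and
            # v_x solves the 1D viscous balance with the -k^2 shift
            rhsn = np.empty(n)
            rhsn[1:n - 1] = -fxh[1:n - 1, -1].real
            rhsn[0] = 0.0 if mb is None else -gbh[-1].real
            rhsn[-1] = 0.0 if mt is None else -gth[-1].real
            vxh[:, -1] = np.linalg.solve(self._knyq, rhsn)
            if want_pressure:
                ph[:, -1] = _solve_gradient(grid, fyh[:, -1].real)
        # k = 0 block: v_y = 0, 1D viscous balance for v_x
        rhs0 = np.empty(n)
        rhs0[1:n - 1] = -fxh[1:n - 1, 0].real
        rhs0[0] = 0.0 if mb is None else -gbh[0].real
        rhs0[-1] = 0.0 if mt is None else -gth[0].real
        if mb == 0.0 and mt == 0.0:
            # singular block: constant slip is unconstrained; pin zero mean
            sol0, res, rank, _ = np.linalg.lstsq(self._k0, rhs0, rcond=None)
            resid = np.abs(self._k0 @ sol0 - rhs0).max()
            scale = max(np.abs(rhs0).max(), self.eta * np.abs(sol0).max()
                        / grid.h_y**2, 1e-300)
            # genuine nonzero-net-force violations are O(1); discrete
            # compatibility of consistent data holds to O(h^2)
            if resid / scale > 0.05:
                raise GaugeError(
                    "both walls stress-free and the mean x-force is incompatible "
                    f"with zero net stress (relative residual {resid / scale:.2e})")
            sol0 = sol0 - sol0.mean()
        else:
            sol0 = np.linalg.solve(self._k0, rhs0)
        vxh[:, 0] = sol0
        if want_pressure:
            # k = 0 pressure from the y-momentum quadrature: Dy1 P = f_y(k=0)
            ph[:, 0] = _solve_gradient(grid, fyh[:, 0].real)
        return vxh, vyh, ph


def _solve_gradient(grid: GridSpec, rhs: np.ndarray) -> np.ndarray:
    """Least-squares solve of Dy1 P = rhs with a zero-mean gauge row."""
    n = grid.n_y
    A = np.vstack([grid.Dy1, np.ones((1, n)) / n])
    b = np.concatenate([rhs, [0.0]])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


_SOLVER_CACHE: dict = {}


def get_solver(grid: GridSpec, eta: float, bc: StokesBC) -> StokesSolver:
    key = (grid.n_x, grid.n_y, grid.L_x, grid.L_y, eta, bc)
    solver = _SOLVER_CACHE.get(key)
    if solver is None:
        solver = StokesSolver(grid, eta, bc)
        _SOLVER_CACHE[key] = solver
    return solver


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------

def solve_flow_from_force(f_x: np.ndarray, f_y: np.ndarray, grid: GridSpec,
                          eta: float, bc: StokesBC,
                          g_bottom: np.ndarray | None = None,
                          g_top: np.ndarray | None = None) -> FlowState:
    """Solve the Stokes problem for an explicit body force and wall-stress data."""
    return get_solver(grid, eta, bc).solve(f_x, f_y, g_bottom, g_top)


def solve_flow(state: FieldState, params: MaterialParams, grid: GridSpec,
               bc: StokesBC | None = None,
               h: MolecularField | None = None) -> StokesSolution:
    """Solve the force balance for the flow slaved to a polarity state."""
    state.validate(anchoring=False, tol=1e-2)
    if bc is None:
        bc = StokesBC.from_params(params)
    if h is None:
        h = molecular_field(state, params, grid)
    f_x, f_y, g_b, g_t = body_force(state, h, params, grid)
    flow = solve_flow_from_force(f_x, f_y, grid, params.eta, bc, g_b, g_t)
    res = flow_residuals(flow, f_x, f_y, grid, params.eta, bc, g_b, g_t)
    return StokesSolution(flow, res)


def flow_residuals(flow: FlowState, f_x: np.ndarray, f_y: np.ndarray,
                   grid: GridSpec, eta: float, bc: StokesBC,
                   g_bottom: np.ndarray | None = None,
                   g_top: np.ndarray | None = None) -> dict:
    """Recompute PDE and BC residuals with the package's canonical operators.

    All residuals are relative max-norms; a converged solve reports ≤ 1e-8.
    """
    gb = np.zeros(grid.n_x) if g_bottom is None else g_bottom
    gt = np.zeros(grid.n_x) if g_top is None else g_top
    lap = lambda f: grid.d2dx2(f) + grid.d2dy2(f)
    r_x = eta * lap(flow.v_x) - grid.ddx(flow.P) + f_x
    r_y = eta * lap(flow.v_y) - grid.ddy(flow.P) + f_y
    vmax = max(np.abs(flow.v_x).max(), np.abs(flow.v_y).max())
    mom_scale = max(np.abs(f_x).max(), np.abs(f_y).max(),
                    eta * vmax / grid.h_y**2, 1e-300)
    div = divergence(flow.v_x, flow.v_y, grid)
    div_scale = max(vmax / grid.h_y, 1e-300)
    shear = eta * (grid.ddy(flow.v_x) + grid.ddx(flow.v_y))
    mb, mt = bc.mu_eff()
    if mb is None:
        r_b = np.abs(flow.v_x[0]).max() / max(vmax, 1e-300)
        b_scale = 1.0
    else:
        r_b = np.abs(shear[0] + gb - mb * flow.v_x[0]).max()
        b_scale = max(np.abs(gb).max(), mb * np.abs(flow.v_x[0]).max(),
                      eta * vmax / grid.h_y, 1e-300)
    if mt is None:
        r_t = np.abs(flow.v_x[-1]).max() / max(vmax, 1e-300)
        t_scale = 1.0
    else:
        r_t = np.abs(shear[-1] + gt + mt * flow.v_x[-1]).max()
        t_scale = max(np.abs(gt).max(), mt * np.abs(flow.v_x[-1]).max(),
                      eta * vmax / grid.h_y, 1e-300)
    return {
        "momentum_x": float(np.abs(r_x[1:-1]).max() / mom_scale),
        "momentum_y": float(np.abs(r_y[1:-1]).max() / mom_scale),
        "divergence": float(np.abs(div).max() / div_scale),
        "bc_bottom": float(r_b / b_scale) if mb is not None else float(r_b),
        "bc_top": float(r_t / t_scale) if mt is not None else float(r_t),
        "wall_penetration": float(max(np.abs(flow.v_y[0]).max(),
                                      np.abs(flow.v_y[-1]).max())),
    }
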