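"""Spontaneous-flow (active Fréedericksz) threshold of the quiescent film.

Linearizing around the anchored homogeneous state θ = 0, v = 0 in the
x-invariant sector gives a 1D problem across the film: the shear stress
σ_xy = η γ̇ + ((1+ν)/2) K θ'' + α θ is uniform in y, and

    ∂_t θ = K [1/γ + (1+ν)²/(4η)] θ'' + ((1+ν)/(2η)) (α θ − σ₀),

with σ₀ fixed by the wall friction.  The critical activity lies in the
closed-form interval

    α_c ∈ [1, 4] × (π² K / L²) [ 2η / (γ (1+ν)) + (1+ν)/2 ],

the lower bound being the stress-free-wall threshold (mode sin(πy/L)) and the
upper bound the no-slip threshold (mode with k L = 2π); finite friction
interpolates.  The lower bound is the α_c used to normalize activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .grid import GridSpec
from .params import MaterialParams


class RegimeError(ValueError):
    """Parameter regime without a positive spontaneous-flow threshold."""


@dataclass
class StabilityResult:
    alpha_c_lower: float
    alpha_c_upper: float
    alpha_c_numeric: float
    growth_rate_curve: np.ndarray  # columns (alpha, s)


def alpha_c_interval(params: MaterialParams, grid: GridSpec) -> tuple[float, float]:
    """Closed-form bounds on the critical activity (one-constant elasticity)."""
    K = params.K  # raises if K1 != K3
    if params.nu <= -1.0:
        raise RegimeError(
            "critical activity is non-positive for nu <= -1; the contractile "
            "spontaneous-flow regime requires nu > -1")
    L = grid.L_y
    base = (np.pi**2 * K / L**2) * (2.0 * params.eta / (params.gamma * (1.0 + params.nu))
                                    + 0.5 * (1.0 + params.nu))
    return base, 4.0 * base


def _linear_operator(alpha: float, params: MaterialParams, grid: GridSpec) -> np.ndarray:
    """Dense operator M with θ̇ = M θ on the interior y-nodes (θ = 0 at walls)."""
    K, nu, eta, gamma = params.K, params.nu, params.eta, params.gamma
    n, h, L = grid.n_y, grid.h_y, grid.L_y
    ni = n - 2
    A = K * (1.0 / gamma + (1.0 + nu)**2 / (4.0 * eta))
    B = (1.0 + nu) / (2.0 * eta)
    # interior second derivative with Dirichlet walls
    D2 = (np.diag(-2.0 * np.ones(ni)) + np.diag(np.ones(ni - 1), 1)
          + np.diag(np.ones(ni - 1), -1)) / h**2
    M = A * D2 + B * alpha * np.eye(ni)
    # uniform shear-stress constant sigma0 couples every node (wall friction):
    # sigma0 * (L + eta/mu_b + eta/mu_t)
    #   = ((1+nu) K / 2) (θ'(L) − θ'(0)) + alpha ∫θ dy
    denom = L
    for mu in (params.mu_bottom, params.mu_top):
        if mu == 0.0:
            denom = np.inf
            break
        denom += params.eta / mu
    if np.isfinite(denom):
        row = np.zeros(ni)
        # one-sided second-order θ'(0), θ'(L) using θ(wall) = 0
        c = (1.0 + nu) * K / (2.0 * h)
        row[0] += -c * 2.0
        row[1] += c * 0.5
        row[-1] += -c * 2.0
        row[-2] += c * 0.5
        # trapezoid integral of θ (wall values are zero)
        row += alpha * h
        M -= B * np.outer(np.ones(ni), row) / denom
    return M


def growth_rate(alpha: float, params: MaterialParams, grid: GridSpec) -> float:
    """Largest real part of the linearized x-invariant spectrum."""
    M = _linear_operator(alpha, params, grid)
    ev = np.linalg.eigvals(M)
    return float(ev.real.max())


def find_alpha_c(params: MaterialParams, grid: GridSpec,
                 rtol: float = 1e-4) -> float:
    """Bisected zero of the maximum growth rate; lies inside the analytic interval."""
    lo, hi = alpha_c_interval(params, grid)
    a, b = 0.5 * lo, 1.5 * hi
    sa = growth_rate(a, params, grid)
    sb = growth_rate(b, params, grid)
    if sa >= 0 or sb <= 0:
        raise RegimeError(
            f"no sign change of the growth rate in [{a:g}, {b:g}] "
            f"(s({a:g})={sa:g}, s({b:g})={sb:g})")
    return float(brentq(lambda x: growth_rate(x, params, grid), a, b,
                        rtol=rtol))


def stability_analysis(params: MaterialParams, grid: GridSpec,
                       alphas: np.ndarray | None = None) -> StabilityResult:
    lo, hi = alpha_c_interval(params, grid)
    ac = find_alpha_c(params, grid)
    if alphas is None:
        alphas = np.linspace(0.0, 2.0 * hi, 21)
    curve = np.array([[a, growth_rate(a, params, grid)] for a in alphas])
    return StabilityResult(lo, hi, ac, curve)
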