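"""Mixed periodic/wall grid and discrete differential operators.

The film is periodic along x and bounded by two walls along y.  Fields are
stored as arrays of shape ``(n_y, n_x)`` with row 0 the bottom wall (y = 0)
and row ``n_y - 1`` the top wall (y = L_y).  Along x the ``n_x`` columns are
the unique periodic nodes x_i = i * L_x / n_x (node n_x wraps to node 0), so
a "65 nodes in each direction" domain is ``GridSpec(n_x=64, n_y=65, ...)``.

Derivatives along x are spectral (FFT); derivatives along y use centered
second-order finite differences with one-sided second-order stencils on the
wall rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the periodic-channel domain.

    Parameters
    ----------
    n_x : int
        Number of unique nodes along the periodic x direction.
    n_y : int
        Number of wall-to-wall nodes along y, both boundary rows included.
    L_x : float
        Domain length along x (simulation length units).
    L_y : float
        Film thickness along y.
    """

    n_x: int
    n_y: int
    L_x: float
    L_y: float

    def __post_init__(self) -> None:
        if self.n_x < 8 or self.n_y < 8:
            raise ValueError(f"grid too coarse: n_x={self.n_x}, n_y={self.n_y} (need >= 8)")
        if self.L_x <= 0 or self.L_y <= 0:
            raise ValueError("domain lengths must be positive")

    @property
    def h_x(self) -> float:
        return self.L_x / self.n_x

    @property
    def h_y(self) -> float:
        return self.L_y / (self.n_y - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_x) * self.h_x

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, self.L_y, self.n_y)

    @property
    def kx(self) -> np.ndarray:
        """Angular wavenumbers along x matching ``np.fft.fft``."""
        return 2.0 * np.pi * np.fft.fftfreq(self.n_x, d=self.h_x)

    @property
    def ik_r(self) -> np.ndarray:
        """i·k for the rfft half-spectrum (spectral d/dx in hat space)."""
        return 1j * 2.0 * np.pi * np.fft.rfftfreq(self.n_x, d=self.h_x)

    # --- operator caches -------------------------------------------------

    def _ops(self) -> "_Operators":
        key = (self.n_x, self.n_y, self.L_x, self.L_y)
        op = _OP_CACHE.get(key)
        if op is None:
            op = _Operators(self)
            _OP_CACHE[key] = op
        return op

    # --- derivatives ------------------------------------------------------

    def ddx(self, f: np.ndarray) -> np.ndarray:
        """Spectral ∂/∂x along the periodic direction (last axis)."""
        fh = np.fft.fft(f, axis=-1)
        out = np.fft.ifft(1j * self.kx * fh, axis=-1)
        return out.real if np.isrealobj(f) else out

    def d2dx2(self, f: np.ndarray) -> np.ndarray:
        fh = np.fft.fft(f, axis=-1)
        out = np.fft.ifft(-(self.kx**2) * fh, axis=-1)
        return out.real if np.isrealobj(f) else out

    def ddy(self, f: np.ndarray) -> np.ndarray:
        """Second-order ∂/∂y; one-sided stencils on the wall rows."""
        return self._ops().Dy1 @ f

    def d2dy2(self, f: np.ndarray) -> np.ndarray:
        return self._ops().Dy2 @ f

    @property
    def Dy1(self) -> np.ndarray:
        return self._ops().Dy1

    @property
    def Dy2(self) -> np.ndarray:
        return self._ops().Dy2

    # --- quadrature -------------------------------------------------------

    def integrate(self, f: np.ndarray) -> float:
        """Domain integral: uniform weight in x, trapezoid in y."""
        w = np.ones(self.n_y)
        w[0] = w[-1] = 0.5
        return float(self.h_x * self.h_y * np.sum(w @ f))

    def mean(self, f: np.ndarray) -> float:
        return self.integrate(f) / (self.L_x * self.L_y)


class _Operators:
    """Dense y-differentiation matrices for one grid."""

    def __init__(self, grid: GridSpec) -> None:
        n, h = grid.n_y, grid.h_y
        D1 = np.zeros((n, n))
        D2 = np.zeros((n, n))
        for j in range(1, n - 1):
            D1[j, j - 1] = -0.5 / h
            D1[j, j + 1] = 0.5 / h
            D2[j, j - 1] = 1.0 / h**2
            D2[j, j] = -2.0 / h**2
            D2[j, j + 1] = 1.0 / h**2
        # third-order one-sided first-derivative rows at the walls so that
        # composed first derivatives (splay/bend -> molecular field) stay
        # second-order accurate up to the boundary
        D1[0, :4] = np.array([-11.0 / 6.0, 3.0, -1.5, 1.0 / 3.0]) / h
        D1[-1, -4:] = np.array([-1.0 / 3.0, 1.5, -3.0, 11.0 / 6.0]) / h
        D2[0, :4] = np.array([2.0, -5.0, 4.0, -1.0]) / h**2
        D2[-1, -4:] = np.array([-1.0, 4.0, -5.0, 2.0]) / h**2
        self.Dy1 = D1
        self.Dy2 = D2


_OP_CACHE: dict = {}


def divergence(vx: np.ndarray, vy: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Discrete ∇·v with the package's canonical operators."""
    return grid.ddx(vx) + grid.ddy(vy)
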