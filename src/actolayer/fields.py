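"""Field containers: polarity state, flow state, tensor and molecular fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, divergence


class ConstraintViolation(ValueError):
    """A field violates one of its declared invariants."""


@dataclass
class FieldState:
    """Unit-norm polarity field on the grid at one time point."""

    p_x: np.ndarray
    p_y: np.ndarray
    t: float = 0.0

    @property
    def theta(self) -> np.ndarray:
        """Polarity angle θ = atan2(p_y, p_x) (derived view)."""
        return np.arctan2(self.p_y, self.p_x)

    def copy(self) -> "FieldState":
        return FieldState(self.p_x.copy(), self.p_y.copy(), self.t)

    def validate(self, grid: GridSpec | None = None, *, anchoring: bool = True,
                 tol: float = 1e-10) -> None:
        """Check |p| = 1 everywhere and, optionally, wall anchoring p = (1, 0).

        Raises
        ------
        ConstraintViolation
            Naming the worst-offending node.
        """
        norm_err = np.abs(self.p_x**2 + self.p_y**2 - 1.0)
        worst = np.unravel_index(int(np.argmax(norm_err)), norm_err.shape)
        if norm_err[worst] > tol:
            raise ConstraintViolation(
                f"|p|^2 deviates from 1 by {norm_err[worst]:.3e} at node "
                f"(iy={worst[0]}, ix={worst[1]})"
            )
        if anchoring:
            for row, name in ((0, "bottom"), (-1, "top")):
                if not (np.all(self.p_x[row] == 1.0) and np.all(self.p_y[row] == 0.0)):
                    ix = int(np.argmax(np.abs(self.p_x[row] - 1.0) + np.abs(self.p_y[row])))
                    raise ConstraintViolation(
                        f"{name} wall row not anchored to (1, 0) at ix={ix}"
                    )

    @classmethod
    def from_theta(cls, theta: np.ndarray, t: float = 0.0) -> "FieldState":
        return cls(np.cos(theta), np.sin(theta), t)

    @classmethod
    def uniform(cls, grid: GridSpec, t: float = 0.0) -> "FieldState":
        return cls(np.ones(grid.shape), np.zeros(grid.shape), t)


@dataclass
class FlowState:
    """Velocity and pressure of the quasi-static Stokes solution."""

    v_x: np.ndarray
    v_y: np.ndarray
    P: np.ndarray

    @property
    def max_speed(self) -> float:
        return float(np.sqrt(self.v_x**2 + self.v_y**2).max())

    def validate(self, grid: GridSpec, tol: float = 1e-8) -> None:
        scale = max(np.abs(self.v_x).max(), np.abs(self.v_y).max(), 1e-300)
        div = divergence(self.v_x, self.v_y, grid)
        rel = np.abs(div).max() / (scale / grid.h_y)
        if rel > tol:
            raise ConstraintViolation(f"relative discrete divergence {rel:.3e} > {tol:g}")
        if np.abs(self.v_y[0]).max() > 0 or np.abs(self.v_y[-1]).max() > 0:
            raise ConstraintViolation("wall-normal velocity non-zero on a boundary row")

    @classmethod
    def zero(cls, grid: GridSpec) -> "FlowState":
        z = np.zeros(grid.shape)
        return cls(z.copy(), z.copy(), z.copy())


@dataclass
class TensorField:
    """Rank-2 tensor field with components per node."""

    xx: np.ndarray
    xy: np.ndarray
    yx: np.ndarray
    yy: np.ndarray

    def __add__(self, other: "TensorField") -> "TensorField":
        return TensorField(self.xx + other.xx, self.xy + other.xy,
                           self.yx + other.yx, self.yy + other.yy)

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "TensorField":
        return cls(*(np.zeros(shape) for _ in range(4)))


@dataclass
class MolecularField:
    """Distortion molecular field h = −δF/δp and its projections on p, p⊥.

    ``h_parallel = h·p``; ``h_perp`` is the component along (−p_y, p_x).
    """

    h_x: np.ndarray
    h_y: np.ndarray
    h_parallel: np.ndarray
    h_perp: np.ndarray
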