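"""Material parameters of the active polar fluid and the paper-style presets.

Units follow the simulation convention: length unit l = 1, stress unit
σ = K/l² and time unit τ = γ l²/K.  With the default K = γ = 1 all three
units are 1 and every quantity below is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class MaterialParams:
    """Constants of the sandwiched active-polar-fluid model.

    Attributes
    ----------
    eta : float
        Shear viscosity (stress·time).
    gamma : float
        Rotational friction of the polarity field (stress·time).
    K1, K3 : float
        Splay and bend Frank elastic constants (2D: energy/length... stress·length²).
    nu : float
        Flow-alignment parameter; |nu| > 1 flow-aligning, |nu| < 1 flow-tumbling.
    alpha : float
        Activity (stress); alpha > 0 is contractile.
    mu_bottom, mu_top : float
        Wall friction coefficients at y = 0 and y = L_y (stress·time/length).
    """

    eta: float = 1.0
    gamma: float = 1.0
    K1: float = 1.0
    K3: float = 1.0
    nu: float = 0.5
    alpha: float = 0.0
    mu_bottom: float = 0.01
    mu_top: float = 0.1

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.gamma <= 0:
            raise ValueError("eta and gamma must be positive")
        if self.K1 <= 0 or self.K3 <= 0:
            raise ValueError("elastic constants must be positive")
        if self.mu_bottom < 0 or self.mu_top < 0:
            raise ValueError("wall friction coefficients must be non-negative")

    @property
    def K(self) -> float:
        """One-constant elastic modulus (requires K1 == K3)."""
        if self.K1 != self.K3:
            raise ValueError("one-constant K requested but K1 != K3")
        return self.K1

    @property
    def contractile_spontaneous_flow(self) -> bool:
        """Validity flag for a contractile fluid with a positive critical activity.

        Contractile active stress along the polar direction requires alpha >= 0;
        a positive spontaneous-flow threshold requires nu > -1 (both terms of
        the critical-activity bounds are positive iff 1 + nu > 0).
        """
        return self.alpha >= 0.0 and self.nu > -1.0

    def with_alpha(self, alpha: float) -> "MaterialParams":
        return replace(self, alpha=alpha)

    def with_mu(self, mu: float) -> "MaterialParams":
        return replace(self, mu_bottom=mu, mu_top=mu)

    @property
    def tumbling(self) -> bool:
        return abs(self.nu) < 1.0


def preset(name: str, alpha: float = 0.0) -> MaterialParams:
    """Named parameter sets: ``tumbling`` (nu = 0.5) or ``aligning`` (nu = 1.5)."""
    if name == "tumbling":
        return MaterialParams(nu=0.5, alpha=alpha)
    if name == "aligning":
        return MaterialParams(nu=1.5, alpha=alpha)
    raise ValueError(f"unknown preset {name!r}; expected 'tumbling' or 'aligning'")


#: Default film geometry: square domain of thickness L = 10 length units,
#: "65 mesh nodes in each direction" (64 unique periodic x-nodes + wrap).
DEFAULT_L = 10.0
DEFAULT_DT = 0.0004
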