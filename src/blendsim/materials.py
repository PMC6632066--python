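"""DEM material parameters and derived contact properties.

Each material carries the measured particle sizes (D10/D50/D90), true
density, elastic constants (Poisson's ratio and shear modulus; Young's
modulus follows as E = 2G(1+nu)), JKR surface energy, and the
interaction coefficients (restitution, static friction, rolling
friction) for particle-particle and particle-wall pairings.  Particle
sizes are upscaled by a material-level ``size_scale`` (100x in the
reference workflow) so bulk behaviour is preserved while particle counts
stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["InteractionCoeffs", "MaterialParams", "pair_interaction"]


@dataclass(frozen=True)
class InteractionCoeffs:
    """Restitution / static friction / rolling friction for one pairing."""

    restitution: float
    static_friction: float
    rolling_friction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.restitution <= 1.0:
            raise ValueError(f"restitution {self.restitution} outside (0, 1]")
        if self.static_friction < 0 or self.rolling_friction < 0:
            raise ValueError("friction coefficients must be >= 0")


@dataclass(frozen=True)
class MaterialParams:
    """One powder (or wall) material.

    Sizes are in micrometres before scaling; density in g/cm^3; shear
    modulus in Pa; surface energy in J/m^2 (0 disables JKR cohesion).
    """

    name: str
    d10_um: float
    d50_um: float
    d90_um: float
    density_g_cm3: float
    poisson: float
    shear_modulus_pa: float
    surface_energy_pp: float = 0.0
    surface_energy_pw: float = 0.0
    pp: InteractionCoeffs = field(
        default_factory=lambda: InteractionCoeffs(0.3, 0.5, 0.3))
    pw: InteractionCoeffs = field(
        default_factory=lambda: InteractionCoeffs(0.3, 0.5, 0.3))
    size_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError(f"Poisson ratio {self.poisson} outside [0, 0.5)")
        if self.shear_modulus_pa <= 0:
            raise ValueError("shear modulus must be positive")
        if self.surface_energy_pp < 0 or self.surface_energy_pw < 0:
            raise ValueError("surface energy must be >= 0")
        if not 0 < self.d10_um <= self.d50_um <= self.d90_um:
            raise ValueError("require 0 < D10 <= D50 <= D90")

    # ----- derived quantities ---------------------------------------------
    @property
    def density(self) -> float:
        """Density in kg/m^3."""
        return self.density_g_cm3 * 1000.0

    @property
    def youngs_modulus(self) -> float:
        """E = 2G(1 + nu), Pa."""
        return 2.0 * self.shear_modulus_pa * (1.0 + self.poisson)

    def scaled_radii(self) -> np.ndarray:
        """Scaled D10/D50/D90 radii in metres."""
        d = np.array([self.d10_um, self.d50_um, self.d90_um]) * 1e-6
        return 0.5 * d * self.size_scale

    def sample_radii(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n particle radii from the three-point size approximation.

        D10/D50/D90 are drawn with probabilities 0.25/0.5/0.25 — a
        three-point quadrature of the size distribution.
        """
        radii = self.scaled_radii()
        idx = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
        return radii[idx]


def pair_interaction(a: MaterialParams, b: MaterialParams | None) -> InteractionCoeffs:
    """Interaction coefficients for a pair (``b=None`` means a wall).

    Particle-particle coefficients are combined conservatively as the
    pairwise minimum restitution and maximum frictions when the two
    materials differ; same-material and particle-wall pairings use the
    material's own tabulated values.
    """
    if b is None:
        return a.pw
    if a.name == b.name:
        return a.pp
    return InteractionCoeffs(
        restitution=min(a.pp.restitution, b.pp.restitution),
        static_friction=max(a.pp.static_friction, b.pp.static_friction),
        rolling_friction=max(a.pp.rolling_friction, b.pp.rolling_friction),
    )
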