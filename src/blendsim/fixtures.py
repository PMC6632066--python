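"""Reference tables and synthetic fixtures.

Everything a test or demo needs is generated here without downloads:
the amlodipine-formulation reference tables (risk register, the 15-run
Box-Behnken table, optimal settings, material parameters) shipped as
package data, synthetic response-surface tables with known ground-truth
coefficients, and miniature particle scenes sized for desk runs.

Desk-scale DEM fixtures deliberately depart from the reference
materials in two ways that are standard coarse-graining practice: the
particle size scale is raised so a scene holds hundreds to a few
thousand particles, and the shear modulus is reduced (1e5 Pa for bulk
tests, 4e4 Pa for blending scenes) to enlarge the stable time step.
Bulk responses driven by friction and gravity (repose angles, mixing)
are insensitive to both choices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .blending import Formulation
from .materials import InteractionCoeffs, MaterialParams
from .risk import RiskEntry, read_risk_register
from .rsm import FactorDef, build_bbd

__all__ = [
    "reference_factors",
    "reference_register",
    "reference_runs",
    "reference_optimal",
    "reference_materials",
    "reference_formulation",
    "paper_fixtures",
    "SyntheticDoeSpec",
    "synth_doe",
    "desk_material",
    "desk_blend_materials",
    "mini_scene",
]

_DATA = resources.files("blendsim.data")

#: desk-scale shear modulus (Pa); see module docstring
DESK_SHEAR = 1e5


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


def reference_factors() -> list[FactorDef]:
    """Filling level 30-70%, rotational speed 15-25 rpm, time 9-24 min."""
    return [
        FactorDef("filling_level", 30.0, 70.0),
        FactorDef("rotational_speed", 15.0, 25.0),
        FactorDef("blending_time", 9.0, 24.0),
    ]


def reference_register() -> list[RiskEntry]:
    """The 15-row scored FMEA register (5 parameters x 3 attributes)."""
    with resources.as_file(_DATA / "risk_register.csv") as path:
        return read_risk_register(path)


def reference_runs() -> pd.DataFrame:
    """The 15-run Box-Behnken table with measured responses."""
    return _read_csv("doe_runs.csv")


def reference_optimal() -> pd.DataFrame:
    """Optimal settings with model predictions and experimental checks."""
    return _read_csv("optimal_settings.csv")


def reference_materials(size_scale: float = 100.0) -> dict[str, MaterialParams]:
    """The five formulation materials with calibrated DEM parameters."""
    df = _read_csv("materials.csv")
    out = {}
    for _, r in df.iterrows():
        out[r["name"]] = MaterialParams(
            name=r["name"],
            d10_um=r["d10_um"], d50_um=r["d50_um"], d90_um=r["d90_um"],
            density_g_cm3=r["density_g_cm3"], poisson=r["poisson"],
            shear_modulus_pa=r["shear_modulus_pa"],
            surface_energy_pp=r["surface_energy"],
            surface_energy_pw=r["surface_energy"],
            pp=InteractionCoeffs(r["e_pp"], r["mus_pp"], r["mur_pp"]),
            pw=InteractionCoeffs(r["e_pw"], r["mus_pw"], r["mur_pw"]),
            size_scale=size_scale,
        )
    return out


def reference_formulation() -> Formulation:
    """Amlodipine formulation: 6.935% API with four excipients."""
    df = _read_csv("materials.csv")
    return Formulation(
        components=tuple(df["name"]),
        mass_fractions=tuple(df["mass_fraction"]),
        api="amlodipine besylate",
    )


def bulk_test_targets() -> pd.DataFrame:
    """Experimental bulk-test values (flow energy per material, mJ)."""
    return _read_csv("bulk_test_targets.csv")


def paper_fixtures() -> dict:
    """Bundle of the reference tables as typed objects."""
    return dict(
        register=reference_register(),
        runs=reference_runs(),
        optimal=reference_optimal(),
        materials=reference_materials(),
        factors=reference_factors(),
        formulation=reference_formulation(),
    )


# ---------------------------------------------------------------------------
# synthetic DoE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDoeSpec:
    """Ground truth for a synthetic Box-Behnken response table.

    ``coefficients`` maps terms ('intercept', 'x1', 'x1x2', ...) to
    coded-scale values; responses get Normal(0, noise_sd) noise.
    """

    factors: tuple[FactorDef, ...]
    coefficients: dict[str, float]
    noise_sd: float = 0.07
    center_runs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def synth_doe(spec: SyntheticDoeSpec, response_name: str = "y") -> pd.DataFrame:
    """Box-Behnken design evaluated at known coefficients plus noise."""
    from .rsm import _term_column

    rng = np.random.default_rng(spec.seed)
    design = build_bbd(list(spec.factors), spec.center_runs,
                       seed=int(rng.integers(2**31)))
    coded = design[[f"coded_{f.name}" for f in spec.factors]].to_numpy()
    y = np.zeros(len(coded))
    for term, b in spec.coefficients.items():
        y += b * _term_column(term, coded)
    y += rng.normal(0.0, spec.noise_sd, size=len(y))
    design[response_name] = y
    return design


# ---------------------------------------------------------------------------
# desk-scale DEM fixtures
# ---------------------------------------------------------------------------

def desk_material(name: str = "desk powder", radius_mm: float = 3.0,
                  density_g_cm3: float = 1.5, restitution: float = 0.35,
                  mu_s: float = 0.45, mu_r: float = 0.25,
                  surface_energy: float = 0.0, spread: float = 0.15,
                  shear_modulus_pa: float = DESK_SHEAR) -> MaterialParams:
    """A generic desk-scale powder with +-``spread`` three-point sizes."""
    d50 = 2.0 * radius_mm * 1e3   # um at scale 1
    return MaterialParams(
        name=name,
        d10_um=d50 * (1 - spread), d50_um=d50, d90_um=d50 * (1 + spread),
        density_g_cm3=density_g_cm3, poisson=0.25,
        shear_modulus_pa=shear_modulus_pa,
        surface_energy_pp=surface_energy, surface_energy_pw=surface_energy,
        pp=InteractionCoeffs(restitution, mu_s, mu_r),
        pw=InteractionCoeffs(restitution, mu_s, mu_r),
        size_scale=1.0,
    )


def desk_blend_materials(base_radius_mm: float = 2.0
                         ) -> dict[str, MaterialParams]:
    """The five formulation materials re-sized for desk blending scenes.

    Densities, frictions, restitution and surface energies keep their
    calibrated values; particle sizes are mapped to comparable desk
    radii (the lubricant stays the finest component so its small mass
    fraction is resolved by enough particles) and the shear modulus is
    reduced to the desk value.
    """
    ref = reference_materials()
    size_factor = {"amlodipine besylate": 0.90, "SMCC 90": 1.0,
                   "PVP K25": 0.95, "CCM-Na": 1.0, "St-Mg": 0.80}
    out = {}
    for name, mat in ref.items():
        d50 = 2.0 * base_radius_mm * size_factor[name] * 1e3
        out[name] = dataclasses.replace(
            mat,
            d10_um=d50 * 0.92, d50_um=d50, d90_um=d50 * 1.08,
            shear_modulus_pa=4e4, size_scale=1.0,
        )
    return out


def mini_scene(kind: str, budget: int = 500, seed: int = 0):
    """Deterministic miniature particle scene for desk runs.

    Kinds: ``two_body`` (head-on collision pair), ``heap`` (funnel
    discharge start state), ``drum``, ``vessel``, ``v_blender`` and
    ``double_cone`` (recipe-aware filled blenders).  Returns a
    :class:`~blendsim.dem.engine.ParticleSystem`.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    from .dem.engine import ParticleSystem

    rng = np.random.default_rng(seed)
    if kind == "two_body":
        mat = desk_material()
        r = mat.scaled_radii()[1]
        pos = np.array([[-4 * r, 0, 0], [4 * r, 0, 0]])
        vel = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        return ParticleSystem(pos=pos, vel=vel, omega=np.zeros((2, 3)),
                              radius=np.array([r, r]),
                              material_id=np.array([0, 0]), materials=[mat],
                              gravity=np.zeros(3))
    if kind == "heap":
        from .bulk_tests import _funnel_lattice, _mono_system
        from .dem.geometry import make_funnel, make_vessel
        mat = desk_material()
        radii = mat.sample_radii(budget, rng)
        r_max = radii.max()
        dish = make_vessel(diameter=80 * r_max, height=30 * r_max,
                           max_edge=3 * r_max)
        funnel = make_funnel(orifice_diameter=12 * r_max,
                             top_diameter=32 * r_max, height=12 * r_max,
                             elevation=15 * r_max, max_edge=3 * r_max)
        pos = _funnel_lattice(budget, radii, 6 * r_max, 15 * r_max,
                              15 * r_max, 12 * r_max, rng)
        return _mono_system(mat, pos, radii, [dish, funnel])
    if kind == "drum":
        from .bulk_tests import _drum_lattice, _mono_system
        from .dem.geometry import make_drum
        mat = desk_material()
        radii = mat.sample_radii(budget, rng)
        r_max = radii.max()
        v_solids = (4 / 3) * np.pi * np.sum(radii**3)
        depth = 8 * r_max
        diameter = max(2 * np.sqrt(v_solids / (0.58 * 0.3 * np.pi * depth)),
                       16 * r_max)
        drum = make_drum(diameter=diameter, depth=depth, rpm=25.0,
                         max_edge=3 * r_max)
        pos = _drum_lattice(budget, radii, diameter / 2, depth, rng)
        return _mono_system(mat, pos, radii, [drum])
    if kind == "vessel":
        from .bulk_tests import _mono_system, _vessel_lattice
        from .dem.geometry import make_vessel
        mat = desk_material()
        radii = mat.sample_radii(budget, rng)
        r_max = radii.max()
        vessel = make_vessel(diameter=28 * r_max, height=60 * r_max,
                             max_edge=3 * r_max)
        pos = _vessel_lattice(budget, radii, 14 * r_max, rng)
        return _mono_system(mat, pos, radii, [vessel])
    if kind in ("v_blender", "double_cone"):
        from .blending import BlenderSpec, build_blender, fill
        mats = desk_blend_materials()
        formulation = reference_formulation()
        # size the blender so ~`budget` particles fill 32% of it:
        # expected count per unit solids volume, recipe-weighted
        shares = np.array([formulation.fraction(c) / mats[c].density
                           for c in formulation.components])
        shares /= shares.sum()
        count_per_solid = 0.0
        for share, c in zip(shares, formulation.components):
            r3 = (mats[c].scaled_radii() ** 3) @ [0.25, 0.5, 0.25]
            count_per_solid += share / ((4 / 3) * np.pi * r3)
        solids = budget / count_per_solid
        nominal_l = solids / 0.58 / 0.32 * 1e3 * 1.15
        spec = BlenderSpec(kind="v" if kind == "v_blender" else "double_cone",
                           nominal_volume_l=nominal_l, rpm=24.0)
        r_big = max(m.scaled_radii().max() for m in mats.values())
        wall = build_blender(spec, max_edge=3 * r_big)
        return fill(wall, formulation, mats, fill_fraction=0.32,
                    particle_budget=budget, seed=seed)
    raise ValueError(f"unknown scene kind {kind!r}")
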