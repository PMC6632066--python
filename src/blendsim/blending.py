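"""Blending simulation and homogeneity analysis.

A formulation (component mass fractions with one API) is rain-filled
into a blender mesh, settled, and tumbled at a set rotational speed.
Homogeneity is scored from eight cylindrical sampling bins: per-bin
drug content (bin API mass fraction over the nominal API fraction,
x100, so a perfect mix reads 100%) and content uniformity (CU, the
percentage relative standard deviation of drug content across bins).
The T-index is the ordinal sampling time at fixed intervals; the first
T_i at which mean content lies in 95-105% and CU <= 5% marks the
required blending time.  Flowability enters through the Carr index
(tap vs bulk density).  Simulated and experimental metric series are
compared by ordinary least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dem.engine import ParticleSystem, Simulation
from .dem.geometry import WallMesh
from .materials import MaterialParams

__all__ = [
    "Formulation",
    "BlenderSpec",
    "SamplingBin",
    "BlendMetrics",
    "carr_index",
    "build_blender",
    "fill",
    "run_blending",
    "default_bins",
    "sample_bins",
    "content_uniformity",
    "t_index_series",
    "compare_series",
]

#: Acceptance window for mean drug content (%) and CU (%RSD)
CONTENT_LIMITS = (95.0, 105.0)
CU_LIMIT = 5.0

#: Random-loose packing fraction assumed when converting bed volume to solids
PACKING_FRACTION = 0.58


def carr_index(bulk_density: float, tap_density: float) -> float:
    """Carr compressibility index (tap - bulk)/tap x 100 (%)."""
    if not 0 < bulk_density <= tap_density:
        raise ValueError("require 0 < bulk density <= tap density")
    return (tap_density - bulk_density) / tap_density * 100.0


@dataclass(frozen=True)
class Formulation:
    """Component mass fractions; exactly one component is the API."""

    components: tuple[str, ...]
    mass_fractions: tuple[float, ...]
    api: str

    def __post_init__(self) -> None:
        if abs(sum(self.mass_fractions) - 1.0) > 1e-9:
            raise ValueError("mass fractions must sum to 1")
        if self.api not in self.components:
            raise ValueError(f"API {self.api!r} not among components")

    @property
    def api_fraction(self) -> float:
        return self.mass_fractions[self.components.index(self.api)]

    def fraction(self, name: str) -> float:
        return self.mass_fractions[self.components.index(name)]


@dataclass(frozen=True)
class BlenderSpec:
    """Blender type, nominal volume and rotation speed."""

    kind: str                     # 'v' or 'double_cone'
    nominal_volume_l: float
    rpm: float = 24.0
    arm_angle_deg: float = 80.0   # V-blender only
    aspect: float = 3.4           # V-blender arm length / radius
    cone_half_angle_deg: float = 40.0  # double-cone only
    cylinder_aspect: float = 0.4


def build_blender(spec: BlenderSpec, max_edge: float | None = None) -> WallMesh:
    """Watertight blender mesh rotating about the horizontal axis.

    ``max_edge`` bounds wall-triangle size (pass ~3 particle radii so
    contact broad-phase lists stay small).
    """
    from .dem.geometry import make_double_cone, make_v_blender

    if spec.kind == "v":
        return make_v_blender(spec.nominal_volume_l, spec.arm_angle_deg,
                              spec.aspect, rpm=spec.rpm, max_edge=max_edge)
    if spec.kind == "double_cone":
        return make_double_cone(spec.nominal_volume_l, spec.cone_half_angle_deg,
                                spec.cylinder_aspect, rpm=spec.rpm,
                                max_edge=max_edge)
    raise ValueError(f"unknown blender kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# filling
# ---------------------------------------------------------------------------

def _interior_points(wall: WallMesh, spacing: float, zmax: float | None = None
                     ) -> np.ndarray:
    """Jittered lattice of candidate centres strictly inside the mesh."""
    lo, hi = wall.mesh.bounds
    margin = spacing * 0.58
    xs = np.arange(lo[0] + margin, hi[0] - margin, spacing)
    ys = np.arange(lo[1] + margin, hi[1] - margin, spacing)
    zs = np.arange(lo[2] + margin, hi[2] - margin, spacing)
    if zmax is not None:
        zs = zs[zs <= zmax]
    if min(len(xs), len(ys), len(zs)) == 0:
        return np.empty((0, 3))
    g = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([a.ravel() for a in g])
    # keep points inside the mesh with enough clearance for the sphere
    return pts[wall.contains(pts, margin=margin)]


class InfeasibleRecipeError(ValueError):
    """Particle budget too small to honour the smallest component."""


def fill(
    wall: WallMesh,
    formulation: Formulation,
    materials: dict[str, MaterialParams],
    fill_fraction: float,
    particle_budget: int,
    seed: int,
    layered: bool = True,
    settle_time: float = 0.6,
    dt_fraction: float = 0.25,
) -> ParticleSystem:
    """Rain-fill a blender to a target fill level and settle under gravity.

    Per-component particle counts are chosen so realized mass fractions
    track the recipe (each component accumulates sampled particles until
    its mass target is met), and components are layered bottom-to-top in
    recipe order (``layered=False`` interleaves them at random, the
    pre-mixed control).
    """
    if not 0 < fill_fraction < 1:
        raise ValueError("fill fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    vol_target = fill_fraction * wall.volume           # m^3 bed volume
    solids_target = PACKING_FRACTION * vol_target

    mats = [materials[c] for c in formulation.components]
    # expected solids volume shares: f_i / rho_i normalised
    shares = np.array([formulation.fraction(c) / materials[c].density
                       for c in formulation.components])
    shares /= shares.sum()

    radii_all, mat_ids, comp_of = [], [], []
    masses = np.zeros(len(mats))
    for k, (comp, mat) in enumerate(zip(formulation.components, mats)):
        v_target = shares[k] * solids_target
        m_target = v_target * mat.density
        mean_r = mat.scaled_radii() @ [0.25, 0.5, 0.25]
        n_guess = int(np.ceil(v_target / ((4 / 3) * np.pi * mean_r**3)) * 1.3) + 8
        r = mat.sample_radii(n_guess, rng)
        m = mat.density * (4 / 3) * np.pi * r**3
        cum = np.cumsum(m)
        # nearest cumulative mass (not first-exceeding) halves the
        # one-particle granularity error on minor components
        hi = int(np.searchsorted(cum, m_target))
        cand = [k for k in (hi, hi + 1) if 1 <= k <= len(r)]
        if not cand:
            raise InfeasibleRecipeError(
                f"component {comp!r} receives no particles at this budget")
        n_keep = min(cand, key=lambda k: abs(cum[k - 1] - m_target))
        radii_all.append(r[:n_keep])
        mat_ids.append(np.full(n_keep, k))
        masses[k] = m[:n_keep].sum()
    radius = np.concatenate(radii_all)
    mat_id = np.concatenate(mat_ids)
    n = len(radius)
    if n > particle_budget * 1.6:
        raise InfeasibleRecipeError(
            f"fill needs {n} particles, exceeding budget {particle_budget}")

    # placement lattice from the bottom of the mesh upward
    spacing = 2.05 * radius.max()
    pts = _interior_points(wall, spacing)
    if len(pts) < n:
        raise InfeasibleRecipeError(
            f"only {len(pts)} lattice sites for {n} particles; "
            "increase particle size or reduce fill")
    pts = pts[np.argsort(pts[:, 2], kind="stable")][:n]
    jitter = rng.uniform(-0.10, 0.10, size=pts.shape) * spacing
    jitter[:, 2] = 0.0
    pts = pts + jitter

    if layered:
        particle_order = np.argsort(mat_id, kind="stable")
    else:
        particle_order = rng.permutation(n)
    pos = np.empty((n, 3))
    pos[particle_order] = pts  # lowest sites to first components in order

    system = ParticleSystem(
        pos=pos, vel=np.zeros((n, 3)), omega=np.zeros((n, 3)),
        radius=radius, material_id=mat_id, materials=mats, walls=[wall],
    )
    system.formulation = formulation
    # settle with the blender stationary
    omega_saved = wall.kin.omega
    wall.kin.omega = 0.0
    sim = Simulation(system)
    dt = system.rayleigh_dt(dt_fraction)
    sim.run(settle_time, dt)
    system.vel[:] = 0.0
    system.omega[:] = 0.0
    wall.kin.omega = omega_saved
    return system


def audit_fractions(system: ParticleSystem, formulation: Formulation
                    ) -> pd.DataFrame:
    """Realized vs recipe mass fractions per component."""
    rows = []
    total = system.mass.sum()
    for k, comp in enumerate(formulation.components):
        realized = system.mass[system.material_id == k].sum() / total
        rows.append(dict(component=comp, recipe=formulation.fraction(comp),
                         realized=realized,
                         rel_dev=abs(realized - formulation.fraction(comp))
                         / formulation.fraction(comp)))
    return pd.DataFrame(rows)


def bed_volume(system: ParticleSystem, cell: float | None = None) -> float:
    """Occupied-voxel estimate of the settled bed volume (m^3)."""
    if cell is None:
        cell = 2.2 * system.radius.max()
    cells = np.floor(system.pos / cell).astype(int)
    n_occ = len(np.unique(cells, axis=0))
    return n_occ * cell**3


# ---------------------------------------------------------------------------
# running and sampling
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    time: float
    pos: np.ndarray
    radius: np.ndarray
    material_id: np.ndarray
    mass: np.ndarray


def run_blending(
    system: ParticleSystem,
    duration: float,
    save_interval: float,
    dt_fraction: float = 0.25,
) -> list[Snapshot]:
    """Rotate the blender for ``duration`` seconds, saving snapshots.

    The blender's rpm is carried by its wall kinematics.  Raises on
    particle escape (tunnelling through the mesh).
    """
    sim = Simulation(system)
    dt = system.rayleigh_dt(dt_fraction)
    every = max(int(round(save_interval / dt)), 1)
    snaps = [Snapshot(system.time, system.pos.copy(), system.radius.copy(),
                      system.material_id.copy(), system.mass.copy())]
    bound = np.abs(system.walls[0].mesh.bounds).max() * 1.5 if system.walls else np.inf

    def grab(s):
        if np.any(np.linalg.norm(s.pos, axis=1) > bound):
            raise RuntimeError(
                "particle escaped the blender (tunnelling); reduce dt fraction")
        snaps.append(Snapshot(s.time, s.pos.copy(), s.radius.copy(),
                              s.material_id.copy(), s.mass.copy()))

    sim.run(duration, dt, callback=grab, callback_every=every)
    return snaps


@dataclass(frozen=True)
class SamplingBin:
    """A cylindrical sampling volume."""

    center: tuple[float, float, float]
    radius: float
    height: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        rel = points - c
        z = rel @ a
        r = np.linalg.norm(rel - z[:, None] * a, axis=1)
        return (np.abs(z) <= self.height / 2) & (r <= self.radius)


def default_bins(snapshot: Snapshot, n: int = 8) -> list[SamplingBin]:
    """Eight vertical sampling cylinders in a 4 x 2 grid over the bed.

    Bin radius and height default to fractions of the bed extent so the
    cylinders tile the bed without overlapping; the bed box uses
    position quantiles so stray particles do not stretch it.  Sampling
    instants should correspond to the blender's rest orientation (full
    revolutions) so the bed forms one contiguous body.
    """
    pos = snapshot.pos
    lo = np.quantile(pos, 0.03, axis=0)
    hi = np.quantile(pos, 0.97, axis=0)
    nx, ny = (4, 2) if n == 8 else (n, 1)
    dx = (hi[0] - lo[0]) / nx
    dy = (hi[1] - lo[1]) / ny
    radius = 0.45 * min(dx, dy)
    height = 0.7 * (hi[2] - lo[2])
    zc = 0.5 * (hi[2] + lo[2])
    bins = []
    for ix in range(nx):
        for iy in range(ny):
            bins.append(SamplingBin(
                center=(lo[0] + (ix + 0.5) * dx, lo[1] + (iy + 0.5) * dy, zc),
                radius=radius, height=height))
    return bins


def content_uniformity(contents: Sequence[float]) -> float:
    """CU as %RSD: 100 x sample SD / mean of per-bin drug contents."""
    c = np.asarray(contents, dtype=float)
    if len(c) < 2:
        raise ValueError("CU needs at least 2 bins")
    mean = c.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * c.std(ddof=1) / mean)


@dataclass
class BlendMetrics:
    time: float
    bin_contents: np.ndarray      # per-bin drug content, %
    mean_content: float
    cu: float
    n_bins: int

    @property
    def meets_spec(self) -> bool:
        lo, hi = CONTENT_LIMITS
        return (lo <= self.mean_content <= hi) and (self.cu <= CU_LIMIT)


def sample_bins(snapshot: Snapshot, bins: Sequence[SamplingBin],
                formulation: Formulation, api_material_id: int | None = None,
                min_bins: int = 4) -> BlendMetrics:
    """Per-bin drug content and CU for one snapshot.

    Drug content (%) is the bin's API mass fraction divided by the
    nominal API fraction, x100.  Empty bins are excluded with a warning;
    fewer than ``min_bins`` non-empty bins is an error.
    """
    if api_material_id is None:
        api_material_id = formulation.components.index(formulation.api)
    contents = []
    for b in bins:
        inside = b.contains(snapshot.pos)
        total = snapshot.mass[inside].sum()
        if total == 0:
            import warnings
            warnings.warn("empty sampling bin excluded")
            continue
        api_mass = snapshot.mass[inside & (snapshot.material_id
                                           == api_material_id)].sum()
        contents.append(api_mass / total / formulation.api_fraction * 100.0)
    if len(contents) < min_bins:
        raise ValueError(f"only {len(contents)} non-empty bins (need {min_bins})")
    contents = np.asarray(contents)
    cu = content_uniformity(contents) if len(contents) >= 2 else float("nan")
    return BlendMetrics(time=snapshot.time, bin_contents=contents,
                        mean_content=float(contents.mean()),
                        cu=cu, n_bins=len(contents))


def t_index_series(snapshots: Sequence[Snapshot], formulation: Formulation,
                   interval: float | None = None,
                   bins: Sequence[SamplingBin] | None = None) -> pd.DataFrame:
    """Metrics at T_i = 1, 2, ... sampling instants.

    ``interval`` defaults to the saved span / 7 so a full run yields
    T_i = 1..7.  The result carries the first spec-meeting T_i in
    ``attrs['t_spec']`` (None if never met).
    """
    t0, t1 = snapshots[0].time, snapshots[-1].time
    if interval is None:
        interval = (t1 - t0) / 7.0
    if interval <= 0:
        raise ValueError("interval must be positive")
    times = np.array([s.time for s in snapshots])
    rows = []
    t_spec = None
    i = 1
    while t0 + i * interval <= t1 + 0.05 * interval:
        target = t0 + i * interval
        snap = snapshots[int(np.argmin(np.abs(times - target)))]
        if bins is None:
            # place bins once, on the first sampled bed, and keep them
            # fixed so the metric series is not perturbed by bin motion
            bins = default_bins(snap)
        m = sample_bins(snap, bins, formulation)
        rows.append(dict(t_index=i, time=snap.time, mean_content=m.mean_content,
                         cu=m.cu, n_bins=m.n_bins,
                         meets_spec=m.meets_spec))
        if t_spec is None and m.meets_spec:
            t_spec = i
        i += 1
    df = pd.DataFrame(rows)
    df.attrs["t_spec"] = t_spec
    return df


def compare_series(simulated: Sequence[float], experimental: Sequence[float],
                   drop_first: int = 0) -> pd.Series:
    """OLS regression of experimental on simulated metric series.

    Returns slope, intercept, S (residual SD), R^2, adjusted R^2 and the
    slope p-value.  ``drop_first`` discards initial high-variability
    points before fitting.
    """
    x = np.asarray(simulated, dtype=float)[drop_first:]
    y = np.asarray(experimental, dtype=float)[drop_first:]
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in the simulated predictor")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    resid = y - yhat
    n = len(x)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    r2 = res.rvalue**2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return pd.Series(dict(slope=res.slope, intercept=res.intercept, S=s,
                          rsquared=r2, rsquared_adj=adj, pvalue=res.pvalue))
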