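"""Wall geometry for DEM: triangle meshes, kinematics, contact queries.

Walls are triangle meshes (read from STL or built parametrically) with
prescribed rigid-body motion (rotation about a fixed axis plus optional
translation, as for the rheometer blade).  Contact queries transform
particle positions into the mesh body frame, use a uniform grid over
triangle bounding boxes as the broad phase, and compute exact
closest-point distances per candidate triangle (face/edge/vertex cases).
Contacts are deduplicated per smooth surface patch so a particle resting
across several coplanar triangles feels one contact, while a wedge
yields two.

Parametric builders cover the rigs and blenders used in the workflow:
flat plate + conical funnel (static repose), rotating drum, cylindrical
vessel with impeller blade (flow-energy rig), V-blender (mitred swept
tube) and double-cone blender (surface of revolution).  Builders scale
to a nominal internal volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "Kinematics",
    "WallMesh",
    "closest_point_on_triangles",
    "load_stl",
    "make_plate",
    "make_funnel",
    "make_drum",
    "make_vessel",
    "make_blade",
    "make_v_blender",
    "make_double_cone",
]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass
class Kinematics:
    """Prescribed rigid motion: rotation about an axis plus translation.

    ``omega`` is the signed angular speed in rad/s about ``axis_dir``
    through ``axis_point`` (both in the body frame at t=0);
    ``v_translation`` is a constant linear velocity of the whole body.
    """

    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    omega: float = 0.0
    v_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angle: float = 0.0
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        self.axis_dir = self.axis_dir / np.linalg.norm(self.axis_dir)
        self.v_translation = np.asarray(self.v_translation, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)

    @classmethod
    def rotation(cls, rpm: float, axis_dir, axis_point=(0, 0, 0)) -> "Kinematics":
        return cls(axis_point=np.asarray(axis_point, dtype=float),
                   axis_dir=np.asarray(axis_dir, dtype=float),
                   omega=rpm * 2.0 * np.pi / 60.0)

    def advance(self, dt: float) -> None:
        self.angle += self.omega * dt
        self.offset = self.offset + self.v_translation * dt

    def world_to_body(self, points: np.ndarray) -> np.ndarray:
        R = _rotation_matrix(self.axis_dir, -self.angle)
        pivot = self.axis_point + self.offset
        return (points - pivot) @ R.T + self.axis_point

    def body_to_world(self, points: np.ndarray) -> np.ndarray:
        R = _rotation_matrix(self.axis_dir, self.angle)
        pivot = self.axis_point + self.offset
        return (points - self.axis_point) @ R.T + pivot

    def rotate_vec_to_world(self, vecs: np.ndarray) -> np.ndarray:
        R = _rotation_matrix(self.axis_dir, self.angle)
        return vecs @ R.T

    def surface_velocity(self, world_points: np.ndarray) -> np.ndarray:
        """v = v_trans + omega_vec x (p - pivot) at world points."""
        pivot = self.axis_point + self.offset
        w = self.omega * self.axis_dir
        return self.v_translation + np.cross(w, world_points - pivot)


# ---------------------------------------------------------------------------
# closest point on triangles (vectorised Ericson algorithm)
# ---------------------------------------------------------------------------

def closest_point_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point to ``p[k]`` on triangle ``tri[k]`` for each row k.

    ``tri`` has shape (M, 3, 3); handles face, edge and vertex regions.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                                   # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)                                  # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)                                  # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))                                # edge bc
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class WallMesh:
    """A triangle-mesh wall with kinematics and a broad-phase grid."""

    def __init__(self, mesh: trimesh.Trimesh, kinematics: Kinematics | None = None,
                 material: str = "stainless steel", name: str = "wall",
                 max_edge: float | None = None):
        if max_edge is not None:
            # bound triangle size so broad-phase candidate lists stay small
            v, f = trimesh.remesh.subdivide_to_size(
                mesh.vertices, mesh.faces, max_edge=max_edge)
            mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
        areas = mesh.area_faces
        if np.any(areas <= 0):
            import warnings
            warnings.warn(f"{name}: skipping {int((areas <= 0).sum())} degenerate triangles")
            mesh = mesh.submesh([areas > 0], append=True)
        self.mesh = mesh
        self.kin = kinematics or Kinematics()
        self.material = material
        self.name = name
        self.triangles = mesh.triangles.copy()          # (T, 3, 3) body frame
        self.face_normals = mesh.face_normals.copy()
        # centroid + bounding radius per triangle for cheap distance culling
        self.tri_centroid = self.triangles.mean(axis=1)
        self.tri_bound = np.linalg.norm(
            self.triangles - self.tri_centroid[:, None, :], axis=2).max(axis=1)
        # patch ids: group faces by (coarsely rounded) normal so coplanar
        # triangles deduplicate to one contact
        keys = np.round(self.face_normals * 8.0).astype(int)
        _, self.patch_id = np.unique(keys, axis=0, return_inverse=True)
        self._centroid_tree = None

    # ----- broad phase -----------------------------------------------------
    def _tree(self):
        if self._centroid_tree is None:
            from scipy.spatial import cKDTree
            self._centroid_tree = cKDTree(self.tri_centroid)
        return self._centroid_tree

    def candidates(self, body_points: np.ndarray, radius: float
                   ) -> tuple[np.ndarray, np.ndarray]:
        """(particle_idx, triangle_idx) pairs whose triangle may lie
        within ``radius`` of the point (centroid KD-tree superset)."""
        reach = radius + float(self.tri_bound.max())
        lists = self._tree().query_ball_point(body_points, reach)
        lens = np.fromiter((len(v) for v in lists), dtype=int,
                           count=len(lists))
        if lens.sum() == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        p_idx = np.repeat(np.arange(len(lists)), lens)
        t_idx = np.concatenate([v for v in lists if v])
        return p_idx, np.asarray(t_idx, dtype=int)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Points strictly inside the (watertight, outward-oriented) mesh
        by at least ``margin``, via the sign of the nearest-face offset."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(4, len(self.triangles))
        _, idx = self._tree().query(points, k=k)
        idx = np.atleast_2d(idx)
        best_d = np.full(len(points), np.inf)
        best_sign = np.zeros(len(points))
        for col in range(idx.shape[1]):
            t = idx[:, col]
            cp = closest_point_on_triangles(self.triangles[t], points)
            vec = points - cp
            d = np.linalg.norm(vec, axis=1)
            sign = np.einsum("ij,ij->i", vec, self.face_normals[t])
            better = d < best_d
            best_d[better] = d[better]
            best_sign[better] = sign[better]
        return (best_sign < 0) & (best_d > margin)

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)


def load_stl(path, kinematics: Kinematics | None = None, **kw) -> WallMesh:
    """Read an STL (binary or ASCII) file as a wall."""
    mesh = trimesh.load_mesh(path)
    return WallMesh(mesh, kinematics, **kw)


# ---------------------------------------------------------------------------
# parametric builders
# ---------------------------------------------------------------------------

def _lathe(profile_rz, sections: int = 48, step: float | None = None
           ) -> trimesh.Trimesh:
    """Surface of revolution about +z through an (r, z) profile polyline.

    Profile segments are densified to length <= ``step`` so the result
    has well-shaped quads (fan-triangulated caps become sliver storms
    under later subdivision).  Points on the axis (r = 0) become centre
    vertices; a profile that starts and ends on the axis is watertight.
    """
    profile = np.asarray(profile_rz, dtype=float)
    if step is not None:
        # keep circumferential edges at the same scale as the step
        sections = int(np.clip(np.ceil(2 * np.pi * profile[:, 0].max() / step),
                               sections, 128))
    pts = [profile[0]]
    for a, b in zip(profile[:-1], profile[1:]):
        seg = np.linalg.norm(b - a)
        k = max(int(np.ceil(seg / step)), 1) if step else 1
        for i in range(1, k + 1):
            pts.append(a + (b - a) * (i / k))
    prof = np.asarray(pts)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    cos, sin = np.cos(theta), np.sin(theta)
    verts: list = []
    rings: list = []          # ('c', idx) centre vertex or ('r', idx0)
    for r, z in prof:
        if r < 1e-12:
            rings.append(("c", len(verts)))
            verts.append([0.0, 0.0, z])
        else:
            rings.append(("r", len(verts)))
            verts.extend(np.column_stack([r * cos, r * sin,
                                          np.full(sections, z)]).tolist())
    faces = []
    for (ta, ia), (tb, ib) in zip(rings[:-1], rings[1:]):
        if ta == "r" and tb == "r":
            for k in range(sections):
                j = (k + 1) % sections
                faces.append([ia + k, ib + k, ia + j])
                faces.append([ia + j, ib + k, ib + j])
        elif ta == "c" and tb == "r":
            for k in range(sections):
                j = (k + 1) % sections
                faces.append([ia, ib + k, ib + j])
        elif ta == "r" and tb == "c":
            for k in range(sections):
                j = (k + 1) % sections
                faces.append([ib, ia + j, ia + k])
    mesh = trimesh.Trimesh(vertices=np.asarray(verts), faces=faces,
                           process=False)
    mesh.fix_normals()
    return mesh


def make_plate(diameter: float = 0.200, thickness: float = 0.004,
               center=(0.0, 0.0, 0.0), max_edge: float | None = None) -> WallMesh:
    """Flat circular plate (top face at z of ``center``)."""
    r = diameter / 2
    step = max_edge or r / 6
    m = _lathe([[0, 0], [r, 0], [r, -thickness], [0, -thickness]],
               step=step)
    m.apply_translation(center)
    return WallMesh(m, name="plate")


def make_funnel(orifice_diameter: float = 0.060, top_diameter: float = 0.160,
                height: float = 0.10, elevation: float = 0.08,
                max_edge: float | None = None) -> WallMesh:
    """Open conical funnel whose orifice sits at ``elevation`` above z=0."""
    r0, r1 = orifice_diameter / 2, top_diameter / 2
    step = max_edge or (r1 - r0) / 4
    m = _lathe([[r0, elevation], [r1, elevation + height]], step=step)
    return WallMesh(m, name="funnel")


def make_drum(diameter: float = 0.400, depth: float = 0.08,
              rpm: float = 25.0, max_edge: float | None = None) -> WallMesh:
    """Closed drum rotating about its own horizontal axis (+y)."""
    r = diameter / 2
    step = max_edge or r / 8
    m = _lathe([[0, -depth / 2], [r, -depth / 2], [r, depth / 2],
                [0, depth / 2]], sections=64, step=step)
    m.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0]))
    kin = Kinematics.rotation(rpm, axis_dir=[0, 1, 0])
    return WallMesh(m, kin, name="drum")


def make_vessel(diameter: float = 0.025, height: float = 0.050,
                max_edge: float | None = None) -> WallMesh:
    """Open-top cylindrical vessel (side wall + bottom) with base at z=0."""
    r = diameter / 2
    step = max_edge or r / 6
    m = _lathe([[0, 0], [r, 0], [r, height]], step=step)
    return WallMesh(m, name="vessel")


def make_blade(diameter: float = 0.0235, chord: float = 0.006,
               thickness: float = 0.0008, helix_angle_deg: float = -5.0,
               tip_z: float = 0.045) -> WallMesh:
    """Flat two-bladed impeller tilted at the helix angle.

    Modelled as a thin rectangular paddle spanning the blade diameter,
    rotated about its long axis by the helix angle; the driver sets the
    rotation/translation schedule on the returned kinematics.
    """
    m = trimesh.creation.box(extents=[diameter, chord, thickness])
    tilt = trimesh.transformations.rotation_matrix(
        np.deg2rad(helix_angle_deg), [1, 0, 0])
    m.apply_transform(tilt)
    m.apply_translation([0, 0, tip_z])
    kin = Kinematics(axis_point=np.array([0.0, 0.0, tip_z]),
                     axis_dir=np.array([0.0, 0.0, 1.0]))
    return WallMesh(m, kin, name="blade")


def _swept_tube(p0: np.ndarray, apex: np.ndarray, p1: np.ndarray,
                radius: float, sections: int = 32) -> trimesh.Trimesh:
    """Watertight tube swept along p0 -> apex -> p1 with a mitred joint."""
    d1 = (apex - p0) / np.linalg.norm(apex - p0)
    d2 = (p1 - apex) / np.linalg.norm(p1 - apex)
    # miter plane through apex with normal along the direction bisector
    n_m = d1 + d2
    n_m = n_m / np.linalg.norm(n_m)
    # shared in-plane basis: ey perpendicular to the arms' plane
    ey = np.cross(d1, d2)
    ey = ey / np.linalg.norm(ey)
    theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)

    def ring(center, d):
        w = np.cross(d, ey)
        return center + radius * (np.outer(np.cos(theta), ey)
                                  + np.outer(np.sin(theta), w))

    ring0 = ring(p0, d1)
    # project ring0 along d1 onto the miter plane
    t = ((apex - ring0) @ n_m) / (d1 @ n_m)
    ring_m = ring0 + t[:, None] * d1
    # continue along d2 to the far end plane (perpendicular to d2 at p1)
    t2 = ((p1 - ring_m) @ d2)
    ring1 = ring_m + t2[:, None] * d2

    # axial and cap ring counts chosen to keep quads near-square
    circ_edge = 2 * np.pi * radius / sections
    n_ax = max(int(np.ceil(np.linalg.norm(p0 - apex) / circ_edge)), 1)
    n_cap = max(int(np.ceil(radius / circ_edge)), 1)

    verts: list[np.ndarray] = []
    rings: list[np.ndarray] = []

    def add_ring(pts):
        start = sum(len(v) for v in verts)
        idx = np.arange(start, start + sections)
        verts.append(pts)
        rings.append(idx)
        return idx

    faces: list[list[int]] = []

    def connect(a_idx, b_idx):
        for k in range(sections):
            j = (k + 1) % sections
            faces.append([a_idx[k], b_idx[k], a_idx[j]])
            faces.append([a_idx[j], b_idx[k], b_idx[j]])

    # cap at p0: centre vertex + concentric rings out to ring0
    verts.append(np.array([p0]))          # vertex 0
    prev = None
    for c in np.linspace(1.0 / n_cap, 1.0, n_cap):
        pts = p0 + c * (ring0 - p0)
        idx = add_ring(pts)
        if prev is None:
            for k in range(sections):
                j = (k + 1) % sections
                faces.append([0, idx[k], idx[j]])
        else:
            connect(prev, idx)
        prev = idx
    # body of arm 1: interpolate from ring0 towards the mitre ring
    for s in np.linspace(1.0 / n_ax, 1.0, n_ax):
        pts = ring0 + s * t[:, None] * d1
        idx = add_ring(pts)
        connect(prev, idx)
        prev = idx
    # body of arm 2: from the mitre ring to ring1
    for s in np.linspace(1.0 / n_ax, 1.0, n_ax):
        pts = ring_m + s * t2[:, None] * d2
        idx = add_ring(pts)
        connect(prev, idx)
        prev = idx
    # cap at p1: concentric rings inward to the centre vertex
    for c in np.linspace(1.0 - 1.0 / n_cap, 1.0 / n_cap, max(n_cap - 1, 0)):
        pts = p1 + c * (ring1 - p1)
        idx = add_ring(pts)
        connect(prev, idx)
        prev = idx
    centre1 = sum(len(v) for v in verts)
    verts.append(np.array([p1]))
    for k in range(sections):
        j = (k + 1) % sections
        faces.append([centre1, prev[j], prev[k]])

    m = trimesh.Trimesh(vertices=np.vstack(verts), faces=np.asarray(faces),
                        process=False)
    m.fix_normals()
    return m


def make_v_blender(nominal_volume_l: float = 3.0, arm_angle_deg: float = 80.0,
                   aspect: float = 3.4, rpm: float = 0.0,
                   sections: int = 32, max_edge: float | None = None) -> WallMesh:
    """V-blender: two cylindrical arms meeting at the apex, opening upward.

    ``arm_angle_deg`` is the full angle between the arms and ``aspect``
    the arm length / arm radius ratio; dimensions are scaled so the mesh
    volume equals the nominal volume.  Rotation is about the horizontal
    +y axis through the centroid.
    """
    half = np.deg2rad(arm_angle_deg / 2.0)
    r = 1.0
    L = aspect * r
    up = np.array([np.sin(half), 0.0, np.cos(half)])
    up2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    apex = np.array([0.0, 0.0, 0.0])
    p0 = apex + up * L
    p1 = apex + up2 * L

    def build(n_sec):
        # drop the elbow slightly below the apex so the mitre sits
        # inside material
        return _swept_tube(p0, apex - 0.3 * (up + up2) / 2, p1, r, n_sec)

    m = build(sections)
    scale = (nominal_volume_l * 1e-3 / m.volume) ** (1.0 / 3.0)
    if max_edge is not None:
        n_sec = int(np.clip(np.ceil(2 * np.pi * r * scale / max_edge), 24, 96))
        m = build(n_sec)
        scale = (nominal_volume_l * 1e-3 / m.volume) ** (1.0 / 3.0)
    if not m.is_watertight:
        raise RuntimeError("generated V-blender mesh is not watertight")
    m.apply_scale(scale)
    m.apply_translation(-m.center_mass)
    kin = Kinematics.rotation(rpm, axis_dir=[0, 1, 0])
    wm = WallMesh(m, kin, name="v_blender")
    _check_volume(wm, nominal_volume_l)
    return wm


def make_double_cone(nominal_volume_l: float = 10.0,
                     cone_half_angle_deg: float = 40.0,
                     cylinder_aspect: float = 0.4, cap_frac: float = 0.25,
                     rpm: float = 0.0, sections: int = 48,
                     max_edge: float | None = None) -> WallMesh:
    """Double-cone blender: cylinder with conical ends, truncated caps.

    Built as a surface of revolution and scaled to the nominal volume;
    rotation is about the horizontal +y axis (the symmetry axis tumbles
    in the x-z plane).
    """
    R = 1.0
    hc = cylinder_aspect * R
    r_cap = cap_frac * R
    cone_h = (R - r_cap) / np.tan(np.deg2rad(cone_half_angle_deg))
    profile = np.array([
        [0.0, -(hc / 2 + cone_h)],
        [r_cap, -(hc / 2 + cone_h)],
        [R, -hc / 2],
        [R, hc / 2],
        [r_cap, hc / 2 + cone_h],
        [0.0, hc / 2 + cone_h],
    ])
    m = _lathe(profile, sections=sections, step=R / 6)
    scale = (nominal_volume_l * 1e-3 / m.volume) ** (1.0 / 3.0)
    if max_edge is not None:
        step = max_edge / scale
        n_sec = int(np.clip(np.ceil(2 * np.pi * R / step), 24, 96))
        m = _lathe(profile, sections=n_sec, step=step)
        scale = (nominal_volume_l * 1e-3 / m.volume) ** (1.0 / 3.0)
    if not m.is_watertight:
        raise RuntimeError("generated double-cone mesh is not watertight")
    m.apply_scale(scale)
    # symmetry axis along z; tumble about y through the centre
    m.apply_translation(-m.center_mass)
    kin = Kinematics.rotation(rpm, axis_dir=[0, 1, 0])
    wm = WallMesh(m, kin, name="double_cone")
    _check_volume(wm, nominal_volume_l)
    return wm


def _check_volume(wall: WallMesh, nominal_l: float, tol: float = 0.05) -> None:
    vol_l = wall.volume * 1e3
    if abs(vol_l - nominal_l) / nominal_l > tol:
        raise RuntimeError(
            f"{wall.name}: mesh volume {vol_l:.3f} L deviates more than "
            f"{tol:.0%} from nominal {nominal_l} L"
        )
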