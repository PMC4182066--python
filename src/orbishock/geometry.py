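"""Parametric shell mesh of an average adult orbit.

The bony orbit is modelled as a frustum-like cavity: four walls (floor,
medial, roof, lateral) converge from a rounded-rectangular anterior rim to
a truncated posterior apex that carries the optic-canal aperture.  A slit
between the posterior floor and lateral wall stands in for the inferior
orbital fissure.  Wall thickness is assigned per anatomical region, with
the orbital floor thinner anteriorly than posteriorly.

Coordinate convention (left orbit): the origin sits at the rim centroid,
``+x`` points posteriorly along the orbital axis toward the apex, ``+z``
is superior and ``+y`` medial.  Triangle winding is chosen so element
normals point into the orbital cavity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

REGIONS = ("floor_anterior", "floor_posterior", "medial", "roof", "lateral")

#: thickness map also carries a band of denser bone around the orbital entrance
THICKNESS_REGIONS = REGIONS + ("rim_band",)


class ParameterError(ValueError):
    """Raised when orbit parameters are inconsistent or anatomically infeasible."""


class GenerationError(RuntimeError):
    """Raised when a generated mesh fails its own quality requirements."""


@dataclass(frozen=True)
class OrbitParams:
    """Dimensions of the synthetic orbit (all lengths in mm).

    Defaults encode standard adult anatomical averages: a 40 x 35 mm orbital
    entrance, 45 mm rim-to-apex depth, a 2.5 mm optic-canal radius and a
    20 x 3 mm inferior-orbital-fissure slit.  Thicknesses follow the known
    regional pattern: a paper-thin medial wall (lamina papyracea), a thin
    anterior floor that thickens posteriorly, sturdier roof and lateral
    walls, and a dense band of bone at the rim.
    """

    rim_width: float = 40.0
    rim_height: float = 35.0
    depth: float = 45.0
    thickness_map: dict[str, float] = field(
        default_factory=lambda: {
            "floor_anterior": 0.5,
            "floor_posterior": 1.0,
            "medial": 0.3,
            "roof": 1.0,
            "lateral": 1.5,
            "rim_band": 3.0,
        }
    )
    optic_canal_radius: float = 2.5
    fissure_length: float = 20.0
    fissure_width: float = 3.0
    #: fractional retrobulbar widening of the cavity behind the rim: the
    #: orbit is widest a short way behind the entrance, so each wall bows
    #: outward between rim and apex rather than lying on a straight frustum
    bulge: float = 0.08
    target_elements: int = 969
    jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("rim_width", "rim_height", "depth", "optic_canal_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.fissure_length < 0 or self.fissure_width < 0:
            raise ParameterError("fissure dimensions must be non-negative")
        if self.target_elements < 100:
            raise ParameterError("target_elements must be at least 100")
        missing = set(THICKNESS_REGIONS) - set(self.thickness_map)
        if missing:
            raise ParameterError(f"thickness_map missing regions: {sorted(missing)}")
        for region, t in self.thickness_map.items():
            if not (0.05 < t < 5.0):
                raise ParameterError(
                    f"thickness for {region!r} is {t} mm, outside (0.05, 5.0)"
                )
        if 2.0 * self.optic_canal_radius >= 0.5 * min(self.rim_width, self.rim_height):
            raise ParameterError(
                "optic_canal_radius too large for the apex: the aperture must be "
                "much smaller than the orbital entrance"
            )
        if not (0.0 <= self.jitter <= 0.05):
            raise ParameterError("jitter must lie in [0, 0.05]")
        if not (0.0 <= self.bulge <= 0.3):
            raise ParameterError("bulge must lie in [0, 0.3]")

    def scaled(self, factor: float) -> "OrbitParams":
        """Return a copy with every in-plane length multiplied by ``factor``.

        The thickness map is left unchanged: wall thickness is a shell
        parameter with its own anatomical validity range, not part of the
        midsurface geometry.
        """
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        return dataclasses.replace(
            self,
            rim_width=self.rim_width * factor,
            rim_height=self.rim_height * factor,
            depth=self.depth * factor,
            optic_canal_radius=self.optic_canal_radius * factor,
            fissure_length=self.fissure_length * factor,
            fissure_width=self.fissure_width * factor,
        )


@dataclass
class ShellMesh:
    """Triangulated orbital-wall surface with per-element attributes.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    triangles : (n_elements, 3) int array
        Winding is consistent; normals point into the orbital cavity.
    thickness : (n_elements,) float array, mm
    region : (n_elements,) str array
        One of :data:`REGIONS` per element.
    fixed_nodes : int array
        Nodes with all six generalized displacements constrained.
    load_nodes : int array
        Ordered strike-point nodes on the free inferior rim.
    probe_A : int
        Anterior-floor node whose displacement trace is reported.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    thickness: np.ndarray
    region: np.ndarray
    fixed_nodes: np.ndarray
    load_nodes: np.ndarray
    probe_A: int

    @property
    def num_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def num_elements(self) -> int:
        return int(self.triangles.shape[0])

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def element_normals(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return cross / np.linalg.norm(cross, axis=1, keepdims=True)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def node_normals(self) -> np.ndarray:
        """Area-weighted average of adjacent element normals, unit length."""
        p = self.nodes[self.triangles]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*normal
        acc = np.zeros_like(self.nodes)
        for k in range(3):
            np.add.at(acc, self.triangles[:, k], cross)
        norms = np.linalg.norm(acc, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return acc / norms

    def region_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.region, labels)

    def copy(self) -> "ShellMesh":
        return ShellMesh(
            nodes=self.nodes.copy(),
            triangles=self.triangles.copy(),
            thickness=self.thickness.copy(),
            region=self.region.copy(),
            fixed_nodes=self.fixed_nodes.copy(),
            load_nodes=self.load_nodes.copy(),
            probe_A=int(self.probe_A),
        )


@dataclass
class MeshQualityReport:
    min_angle_deg: float
    max_angle_deg: float
    aspect_ratios: np.ndarray
    boundary_loop_count: int
    euler_characteristic: int
    orientation_consistent: bool


# ---------------------------------------------------------------------------
# cross-section curve


def _cross_section(
    s: float, params: OrbitParams, n_phi: int, n_dense: int = 1024
) -> np.ndarray:
    """(y, z) points of the wall cross-section at depth fraction ``s``.

    The section morphs from a rounded rectangle (superellipse, exponent 4)
    at the rim to the circular optic-canal aperture at the apex, and is
    resampled to ``n_phi`` points equally spaced by arc length, starting at
    the inferior midline and proceeding toward the medial side.
    """
    widen = 1.0 + params.bulge * 4.0 * s * (1.0 - s)
    a = ((1.0 - s) * 0.5 * params.rim_width + s * params.optic_canal_radius) * widen
    b = ((1.0 - s) * 0.5 * params.rim_height + s * params.optic_canal_radius) * widen
    p = 4.0 - 2.0 * s  # exponent: rounded rectangle -> circle

    phi = -0.5 * np.pi + np.linspace(0.0, 2.0 * np.pi, n_dense, endpoint=False)
    c, sn = np.cos(phi), np.sin(phi)
    y = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    z = b * np.sign(sn) * np.abs(sn) ** (2.0 / p)
    pts = np.column_stack([y, z])

    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])  # length n_dense+1, closed
    total = arc[-1]
    targets = np.arange(n_phi) * total / n_phi
    closed = np.vstack([pts, pts[:1]])
    out = np.empty((n_phi, 2))
    for k in range(2):
        out[:, k] = np.interp(targets, arc, closed[:, k])
    return out


def _section_perimeter(params: OrbitParams, s: float = 0.0) -> float:
    pts = _cross_section(s, params, 512)
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


def _ring_layout(params: OrbitParams) -> tuple[np.ndarray, int]:
    """Depth fractions of the mesh rings, plus the sector count.

    The cross-section perimeter shrinks by a factor of ~8 from rim to apex,
    so rings are graded — band height proportional to the local perimeter —
    which keeps element aspect ratios near one over the whole surface.
    """
    s_samp = np.linspace(0.0, 1.0, 33)
    perim = np.array([_section_perimeter(params, s) for s in s_samp])
    # tau = integral of depth/P ds : dimensionless "aspect-one" ring count
    dtau = params.depth / perim
    tau = np.concatenate([[0.0], np.cumsum(0.5 * (dtau[1:] + dtau[:-1]) * np.diff(s_samp))])
    # at least 16 sectors so the free inferior rim can carry the 6-point strike
    n_phi = max(16, int(round(np.sqrt(params.target_elements / (2.0 * tau[-1])))))
    n_s = max(4, int(round(params.target_elements / (2.0 * n_phi))))
    targets = np.linspace(0.0, tau[-1], n_s + 1)
    s_rings = np.interp(targets, tau, s_samp)
    return s_rings, n_phi


# ---------------------------------------------------------------------------
# generator


def generate_orbit(params: OrbitParams | None = None) -> ShellMesh:
    """Generate the synthetic average-orbit shell mesh.

    Builds a structured ring/sector grid between the rim and the apex
    aperture, opens the inferior-orbital-fissure slit, labels the four
    walls, assigns regional thickness, fixes the skull-attached boundary
    (apex aperture plus the superior rim) and selects six evenly spread
    strike nodes on the free inferior rim.  Deterministic for a fixed seed.
    """
    if params is None:
        params = OrbitParams()
    params.validate()

    s_rings, n_phi = _ring_layout(params)
    n_s = len(s_rings) - 1

    rings = np.array(
        [_cross_section(s, params, n_phi) for s in s_rings]
    )  # (n_s+1, n_phi, 2)
    nodes = np.empty(((n_s + 1) * n_phi, 3))
    for i in range(n_s + 1):
        sl = slice(i * n_phi, (i + 1) * n_phi)
        nodes[sl, 0] = params.depth * s_rings[i]
        nodes[sl, 1:] = rings[i]

    def nid(i: int, j: int) -> int:
        return i * n_phi + (j % n_phi)

    # seeded jitter along the local surface tangents (interior rings only)
    if params.jitter > 0.0:
        rng = np.random.default_rng(params.seed)
        alpha = rng.uniform(-params.jitter, params.jitter, size=((n_s + 1), n_phi, 2))
        jittered = nodes.copy()
        for i in range(1, n_s):
            for j in range(n_phi):
                t_phi = 0.5 * (nodes[nid(i, j + 1)] - nodes[nid(i, j - 1)])
                t_s = 0.5 * (nodes[nid(i + 1, j)] - nodes[nid(i - 1, j)])
                jittered[nid(i, j)] += alpha[i, j, 0] * t_phi + alpha[i, j, 1] * t_s
        nodes = jittered

    # fissure slit: remove a band of quads at the inferolateral junction
    removed = np.zeros((n_s, n_phi), dtype=bool)
    if params.fissure_width > 0.0 and params.fissure_length > 0.0:
        i_hi = n_s - 2  # keep the apex-adjacent quad row intact
        x_rows = params.depth * 0.5 * (s_rings[:-1] + s_rings[1:])
        x_end = x_rows[i_hi] + 1e-9
        i_lo = i_hi
        while i_lo > 1 and x_end - x_rows[i_lo - 1] <= params.fissure_length:
            i_lo -= 1
        s_mid = 0.5 * (s_rings[i_lo] + s_rings[i_hi + 1])
        arc_spacing = _section_perimeter(params, s_mid) / n_phi
        n_cols = max(1, int(round(params.fissure_width / arc_spacing)))
        if i_lo > i_hi:
            raise ParameterError("fissure_length leaves no interior rows to open")
        # inferolateral corner: -y (lateral, left orbit), -z (inferior)
        corner = np.array([-np.sqrt(0.5), -np.sqrt(0.5)])
        ring_mid = rings[(i_lo + i_hi) // 2]
        ang = ring_mid / np.linalg.norm(ring_mid, axis=1, keepdims=True)
        j_mid = int(np.argmax(ang @ corner))
        j0 = j_mid - (n_cols - 1) // 2
        for i in range(i_lo, i_hi + 1):
            for dj in range(n_cols):
                removed[i, (j0 + dj) % n_phi] = True

    tris: list[tuple[int, int, int]] = []
    quad_of: list[tuple[int, int]] = []
    for i in range(n_s):
        for j in range(n_phi):
            if removed[i, j]:
                continue
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            # winding gives normals pointing toward the cavity axis
            tris.append((n00, n01, n11))
            tris.append((n00, n11, n10))
            quad_of.extend([(i, j), (i, j)])
    triangles = np.asarray(tris, dtype=np.int64)
    quad_rows = np.asarray([q[0] for q in quad_of], dtype=np.int64)

    # drop orphaned nodes and remap
    used = np.unique(triangles)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes_kept = nodes[used]
    triangles = remap[triangles]

    mesh = ShellMesh(
        nodes=nodes_kept,
        triangles=triangles,
        thickness=np.zeros(len(triangles)),
        region=np.empty(len(triangles), dtype="<U16"),
        fixed_nodes=np.empty(0, dtype=np.int64),
        load_nodes=np.empty(0, dtype=np.int64),
        probe_A=-1,
    )

    _assign_regions(mesh, params)
    mesh.thickness = np.array(
        [params.thickness_map[r] for r in mesh.region], dtype=float
    )
    mesh.thickness[quad_rows == 0] = params.thickness_map["rim_band"]

    _orient_into_cavity(mesh)

    # boundary classification for constraints
    rim_ring = {int(remap[nid(0, j)]) for j in range(n_phi) if remap[nid(0, j)] >= 0}
    apex_ring = {
        int(remap[nid(n_s, j)]) for j in range(n_phi) if remap[nid(n_s, j)] >= 0
    }
    z = mesh.nodes[:, 2]
    fixed = sorted(apex_ring | {n for n in rim_ring if z[n] > 0.0})
    mesh.fixed_nodes = np.asarray(fixed, dtype=np.int64)

    mesh.load_nodes = select_load_nodes(mesh, 6)
    mesh.probe_A = _select_probe(mesh, params)

    report = mesh_quality(mesh)
    if report.min_angle_deg <= 10.0:
        worst = int(np.argmin(_internal_angles(mesh).min(axis=1)))
        raise GenerationError(
            f"triangle {worst} has minimum internal angle "
            f"{report.min_angle_deg:.2f} deg (<= 10 deg)"
        )
    if not report.orientation_consistent:
        raise GenerationError("generated surface is not consistently oriented")
    return mesh


def _assign_regions(mesh: ShellMesh, params: OrbitParams) -> None:
    cent = mesh.element_centroids()
    s = np.clip(cent[:, 0] / params.depth, 0.0, 1.0)
    a = (1.0 - s) * 0.5 * params.rim_width + s * params.optic_canal_radius
    b = (1.0 - s) * 0.5 * params.rim_height + s * params.optic_canal_radius
    u = cent[:, 1] / a  # +: medial
    w = cent[:, 2] / b  # +: superior
    region = np.where(u > np.abs(w), "medial", "lateral").astype("<U16")
    region[w >= np.abs(u)] = "roof"
    floor = -w >= np.abs(u)
    region[floor & (s <= 0.5)] = "floor_anterior"
    region[floor & (s > 0.5)] = "floor_posterior"
    mesh.region = region


def _orient_into_cavity(mesh: ShellMesh) -> None:
    """Flip the whole surface if normals point away from the cavity axis."""
    normals = mesh.element_normals()
    cent = mesh.element_centroids()
    inward = -cent.copy()
    inward[:, 0] = 0.0  # toward the x-axis
    if np.median(np.einsum("ij,ij->i", normals, inward)) < 0.0:
        mesh.triangles = mesh.triangles[:, [0, 2, 1]]


def _select_probe(mesh: ShellMesh, params: OrbitParams) -> int:
    """Anterior-floor probe: ~25% depth, midway between the inferomedial
    corner (nasolacrimal region) and the inferior midline."""
    floor_nodes = np.unique(mesh.triangles[mesh.region_mask("floor_anterior")])
    floor_nodes = np.setdiff1d(floor_nodes, mesh.fixed_nodes)
    xyz = mesh.nodes[floor_nodes]
    ang = np.arctan2(xyz[:, 2], xyz[:, 1])  # -pi/2 inferior midline, 0 medial
    target_ang = -3.0 * np.pi / 8.0
    score = ((xyz[:, 0] / params.depth) - 0.25) ** 2 + (ang - target_ang) ** 2
    return int(floor_nodes[np.argmin(score)])


# ---------------------------------------------------------------------------
# load-node selection


class SelectionError(ValueError):
    """Raised when the requested strike nodes cannot be placed."""


def _free_inferior_rim(mesh: ShellMesh) -> tuple[np.ndarray, np.ndarray]:
    """Free rim-boundary nodes ordered along the inferior arc, with their
    cumulative arc-length positions."""
    loops = _boundary_loops(mesh)
    if not loops:
        raise SelectionError("mesh has no boundary at all")
    fixed = set(int(n) for n in mesh.fixed_nodes)
    # the entrance rim is the boundary loop nearest the anterior (x=0) plane
    loop = min(loops, key=lambda lp: float(mesh.nodes[lp, 0].mean()))
    if not [n for n in loop if n not in fixed]:
        raise SelectionError("mesh has no free rim arc")
    # rotate the loop so the fixed stretch comes first, free arc contiguous
    is_free = [n not in fixed for n in loop]
    if all(is_free):
        arc_nodes = loop
    else:
        k = next(i for i in range(len(loop)) if not is_free[i])
        rotated = loop[k:] + loop[:k]
        arc_nodes = [n for n in rotated if n not in fixed]
    pts = mesh.nodes[arc_nodes]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return np.asarray(arc_nodes, dtype=np.int64), arclen


def select_load_nodes(mesh: ShellMesh, n: int) -> np.ndarray:
    """Pick ``n`` approximately equally spaced strike nodes on the free
    inferior rim arc, ordered along the arc.  Deterministic."""
    if n < 1:
        raise SelectionError("need at least one load node")
    arc_nodes, arclen = _free_inferior_rim(mesh)
    if len(arc_nodes) < n:
        raise SelectionError(
            f"only {len(arc_nodes)} free rim nodes available, {n} requested"
        )
    if len(arc_nodes) == n:
        return arc_nodes.copy()
    # dynamic program: choose increasing indices minimizing deviation of the
    # consecutive arc gaps (and end margins) from perfectly even spacing
    total = arclen[-1]
    step = total / n
    m = len(arc_nodes)
    INF = np.inf
    cost = np.full((n, m), INF)
    back = np.zeros((n, m), dtype=np.int64)
    margin_w = 0.01  # end margins only break ties between equally even gap sets
    cost[0] = margin_w * (arclen - 0.5 * step) ** 2
    for k in range(1, n):
        for i in range(k, m):
            prev = cost[k - 1, : i] + (arclen[i] - arclen[:i] - step) ** 2
            j = int(np.argmin(prev))
            cost[k, i] = prev[j]
            back[k, i] = j
    final = cost[n - 1] + margin_w * (total - arclen - 0.5 * step) ** 2
    idx = [int(np.argmin(final))]
    for k in range(n - 1, 0, -1):
        idx.append(int(back[k, idx[-1]]))
    return arc_nodes[np.array(idx[::-1])]


# ---------------------------------------------------------------------------
# quality report


def _internal_angles(mesh: ShellMesh) -> np.ndarray:
    p = mesh.nodes[mesh.triangles]
    angles = np.empty((len(mesh.triangles), 3))
    for k in range(3):
        v1 = p[:, (k + 1) % 3] - p[:, k]
        v2 = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angles[:, k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles


def _edge_incidence(mesh: ShellMesh) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """undirected edge -> list of (element, direction) incidences"""
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for e, tri in enumerate(mesh.triangles):
        for k in range(3):
            a, b = int(tri[k]), int(tri[(k + 1) % 3])
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, []).append((e, 1 if a < b else -1))
    return edges


def _boundary_loops(mesh: ShellMesh) -> list[list[int]]:
    """Closed loops of boundary nodes, traversed by edge adjacency."""
    edges = _edge_incidence(mesh)
    boundary = [e for e, inc in edges.items() if len(inc) == 1]
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    seen: set[tuple[int, int]] = set()
    loops: list[list[int]] = []
    for a0, b0 in boundary:
        if (a0, b0) in seen:
            continue
        loop = [a0]
        prev, cur = a0, b0
        seen.add((a0, b0))
        while cur != a0:
            loop.append(cur)
            nxts = [n for n in adj[cur] if n != prev]
            nxt = nxts[0] if nxts else prev
            key = (cur, nxt) if cur < nxt else (nxt, cur)
            seen.add(key)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


def mesh_quality(mesh: ShellMesh) -> MeshQualityReport:
    """Pure report: angle extrema, aspect ratios, topology and orientation."""
    angles = _internal_angles(mesh)
    p = mesh.nodes[mesh.triangles]
    edge_len = np.stack(
        [np.linalg.norm(p[:, (k + 1) % 3] - p[:, k], axis=1) for k in range(3)],
        axis=1,
    )
    # longest edge over inradius-equivalent (2*area/perimeter)
    areas = mesh.element_areas()
    perim = edge_len.sum(axis=1)
    aspect = edge_len.max(axis=1) * perim / (4.0 * np.maximum(areas, 1e-300))

    edges = _edge_incidence(mesh)
    interior = [inc for inc in edges.values() if len(inc) == 2]
    oriented = all(inc[0][1] != inc[1][1] for inc in interior) and all(
        len(inc) <= 2 for inc in edges.values()
    )
    loops = _boundary_loops(mesh)
    euler = mesh.num_nodes - len(edges) + mesh.num_elements
    return MeshQualityReport(
        min_angle_deg=float(angles.min()),
        max_angle_deg=float(angles.max()),
        aspect_ratios=aspect,
        boundary_loop_count=len(loops),
        euler_characteristic=int(euler),
        orientation_consistent=bool(oriented),
    )
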