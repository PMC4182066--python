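"""Post-processing of the transient run: the outward/retrograde wall wave.

The physical question: after a blunt strike on the inferior orbital rim,
the orbital floor first bulges outward toward the maxillary sinus, then a
"retrograde" (recurring) wave carries previously outward-displaced regions
back toward the orbital interior — the proposed suction mechanism for
posttraumatic orbital emphysema.  This module reduces the displacement
history to the quantities behind that narrative: a signed wall-displacement
field (positive = toward the orbital interior), the reversal-onset time,
probe extrema, von Mises surface stresses and the first time the floor
stress exceeds a configurable fracture-threshold surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import REGIONS, ShellMesh
from .shell import (
    Material,
    element_curvature,
    element_membrane_strain,
    dof_indices,
)
from .dynamics import STRIKE_END_TIME_S, DisplacementHistory

FLOOR_BASE_REGIONS = ("floor_anterior", "floor_posterior", "medial")
DEFAULT_EPSILON_MM = 0.1
DEFAULT_STRESS_LIMIT_MPA = 80.0

AxisMode = Literal["wall_normal", "orbital_axis"]


@dataclass
class SignedDisplacementField:
    """Per-snapshot, per-node scalar wall displacement in mm.

    Positive values point toward the orbital interior, negative toward the
    adjacent sinus / exterior.
    """

    times: np.ndarray
    values: np.ndarray  # (n_snapshots, n_nodes)
    axis_mode: str
    node_regions: np.ndarray  # (n_nodes,) str, region of the adjacent wall


@dataclass
class StressField:
    """Element surface stresses per snapshot.

    ``membrane`` holds the midsurface stress (sigma_xx, sigma_yy, tau_xy)
    and ``von_mises_top`` / ``von_mises_bottom`` the equivalent stress at
    the two outer fibers z = +-t/2, all in MPa.
    """

    times: np.ndarray
    membrane: np.ndarray  # (n_snap, n_elem, 3)
    von_mises_top: np.ndarray  # (n_snap, n_elem)
    von_mises_bottom: np.ndarray
    stress_limit: float = DEFAULT_STRESS_LIMIT_MPA


@dataclass
class WaveReport:
    """Summary metrics of the outward-then-retrograde wall motion."""

    peak_outward_mm: float
    peak_outward_time_s: float
    peak_outward_region: str
    peak_inward_mm: float
    peak_inward_time_s: float
    peak_inward_region: str
    reversal_onset_s: float | None
    reversal_regions: tuple[str, ...]
    probe_A_outward_mm: float
    probe_A_inward_mm: float
    probe_A_peak_to_peak_mm: float
    stress_first_exceedance_s: float | None
    #: area-weighted mean floor displacement over in-load-window snapshots
    #: (negative = net outward bulge toward the sinus)
    load_window_floor_mean_mm: float = 0.0
    #: fraction of floor area moving outward, averaged over the window
    load_window_floor_outward_area_fraction: float = 0.0
    region_extrema: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "peak_outward_mm": self.peak_outward_mm,
            "peak_outward_time_s": self.peak_outward_time_s,
            "peak_outward_region": self.peak_outward_region,
            "peak_inward_mm": self.peak_inward_mm,
            "peak_inward_time_s": self.peak_inward_time_s,
            "peak_inward_region": self.peak_inward_region,
            "reversal_onset_s": self.reversal_onset_s,
            "reversal_regions": list(self.reversal_regions),
            "probe_A_outward_mm": self.probe_A_outward_mm,
            "probe_A_inward_mm": self.probe_A_inward_mm,
            "probe_A_peak_to_peak_mm": self.probe_A_peak_to_peak_mm,
            "stress_first_exceedance_s": self.stress_first_exceedance_s,
            "load_window_floor_mean_mm": self.load_window_floor_mean_mm,
            "load_window_floor_outward_area_fraction": (
                self.load_window_floor_outward_area_fraction
            ),
            "region_extrema": self.region_extrema,
        }


def nodal_areas(mesh: ShellMesh) -> np.ndarray:
    """Tributary surface area per node (one third of each adjacent element)."""
    areas = mesh.element_areas()
    na = np.zeros(mesh.num_nodes)
    for k in range(3):
        np.add.at(na, mesh.triangles[:, k], areas / 3.0)
    return na


def floor_sweep(
    field: SignedDisplacementField,
    mesh: ShellMesh,
    regions: tuple[str, ...] = ("floor_anterior", "floor_posterior"),
) -> dict[str, np.ndarray]:
    """Area-weighted floor motion per snapshot.

    ``swept_volume_mm3`` is the integral of the signed wall displacement
    over the floor surface — the volume displaced toward the orbit
    (positive) or toward the maxillary sinus (negative), the quantity
    behind the pressure-swing interpretation of the wall motion.
    ``outward_area_fraction`` is the fraction of floor area moving outward.
    Area weighting, rather than node counting, makes the statistic
    independent of local mesh grading.
    """
    na = nodal_areas(mesh)
    free = np.setdiff1d(np.arange(mesh.num_nodes), mesh.fixed_nodes)
    sel = free[np.isin(field.node_regions[free], regions)]
    w = na[sel]
    vals = field.values[:, sel]
    swept = (vals * w[None, :]).sum(axis=1)
    out_frac = np.where(
        w.sum() > 0, (w[None, :] * (vals < 0)).sum(axis=1) / w.sum(), 0.0
    )
    return {
        "times": field.times.copy(),
        "swept_volume_mm3": swept,
        "outward_area_fraction": out_frac,
    }


def node_region_map(mesh: ShellMesh) -> np.ndarray:
    """Assign each node the region of the majority of its adjacent elements
    (ties broken by the order of :data:`REGIONS`)."""
    counts = {r: np.zeros(mesh.num_nodes, dtype=int) for r in REGIONS}
    for e, tri in enumerate(mesh.triangles):
        for n in tri:
            counts[str(mesh.region[e])][n] += 1
    stacked = np.stack([counts[r] for r in REGIONS])
    return np.array(REGIONS, dtype="<U16")[np.argmax(stacked, axis=0)]


def signed_wall_displacement(
    history: DisplacementHistory,
    mesh: ShellMesh,
    axis_mode: AxisMode = "wall_normal",
) -> SignedDisplacementField:
    """Project nodal translations onto the wall-displacement axis.

    ``wall_normal`` projects onto the node's reference (undeformed) wall
    normal, which points into the orbital cavity by mesh construction;
    ``orbital_axis`` projects onto the anteroposterior x-axis and signs the
    result by the wall side, reproducing the alternative convention of
    measuring displacement along the orbit's sagittal axis.
    """
    if history.displacements.shape[1] != mesh.num_nodes:
        raise ValueError("history and mesh disagree on the number of nodes")
    tr = history.translations()
    if axis_mode == "wall_normal":
        normals = mesh.node_normals()
        vals = np.einsum("snk,nk->sn", tr, normals)
    elif axis_mode == "orbital_axis":
        # x-displacement, signed so that motion whose x-component carries
        # the node toward the cavity interior counts positive
        normals = mesh.node_normals()
        side = np.sign(normals[:, 0])
        side[side == 0.0] = 1.0
        vals = tr[:, :, 0] * side[None, :]
    else:
        raise ValueError(f"unknown axis_mode {axis_mode!r}")
    vals = vals.copy()
    vals[:, mesh.fixed_nodes] = 0.0
    return SignedDisplacementField(
        times=history.snapshot_times.copy(),
        values=vals,
        axis_mode=axis_mode,
        node_regions=node_region_map(mesh),
    )


def detect_retrograde(
    field: SignedDisplacementField,
    epsilon: float = DEFAULT_EPSILON_MM,
    regions: tuple[str, ...] = FLOOR_BASE_REGIONS,
) -> tuple[float | None, tuple[str, ...]]:
    """Earliest reversal: a node in the floor or medial base passing from
    below -epsilon (outward) to above +epsilon (inward).

    Returns (onset time s or None, regions participating at onset).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mask = np.isin(field.node_regions, regions)
    vals = field.values[:, mask]
    node_regions = field.node_regions[mask]
    been_out = np.zeros(vals.shape[1], dtype=bool)
    for i, t in enumerate(field.times):
        reversed_now = been_out & (vals[i] > epsilon)
        if np.any(reversed_now):
            regs = tuple(sorted(set(node_regions[reversed_now])))
            return float(t), regs
        been_out |= vals[i] < -epsilon
    return None, ()


def probe_metrics(
    field: SignedDisplacementField, probe: int, fixed_nodes: np.ndarray | None = None
) -> dict[str, float]:
    """Outward/inward extrema of one node's signed trace, exact on the
    snapshot grid.  ``peak_to_peak`` is their sum."""
    if fixed_nodes is not None and probe in set(int(n) for n in fixed_nodes):
        raise ValueError(f"probe node {probe} is a fixed node")
    trace = field.values[:, probe]
    outward = float(max(0.0, -trace.min()))
    inward = float(max(0.0, trace.max()))
    return {
        "outward_mm": outward,
        "outward_time_s": float(field.times[int(np.argmin(trace))]),
        "inward_mm": inward,
        "inward_time_s": float(field.times[int(np.argmax(trace))]),
        "peak_to_peak_mm": outward + inward,
    }


def von_mises_2d(sigma: np.ndarray) -> np.ndarray:
    """Equivalent stress of a plane-stress state (s_xx, s_yy, t_xy),
    broadcast over leading axes."""
    sx, sy, txy = sigma[..., 0], sigma[..., 1], sigma[..., 2]
    return np.sqrt(sx * sx - sx * sy + sy * sy + 3.0 * txy * txy)


def recover_stress(
    history: DisplacementHistory,
    mesh: ShellMesh,
    material: Material,
    stress_limit: float = DEFAULT_STRESS_LIMIT_MPA,
) -> StressField:
    """Element surface stresses over the history.

    Per element: constant membrane strain plus centroid curvature from the
    bending interpolation; surface strain at the fibers z = +-t/2 is
    eps_m -+ (t/2) kappa, pushed through the plane-stress law; von Mises
    from the resulting 2D stress tensor.  Stresses are in MPa.
    """
    C = material.plane_stress_matrix()
    n_snap = history.num_snapshots
    n_elem = mesh.num_elements
    membrane = np.zeros((n_snap, n_elem, 3))
    vm_top = np.zeros((n_snap, n_elem))
    vm_bot = np.zeros((n_snap, n_elem))
    flat = history.displacements.reshape(n_snap, -1)
    for e, tri in enumerate(mesh.triangles):
        p = mesh.nodes[tri]
        edofs = dof_indices(tri)
        t_half = 0.5 * float(mesh.thickness[e])
        for i in range(n_snap):
            u = flat[i, edofs]
            eps_m = element_membrane_strain(p, u)
            kappa = element_curvature(p, u)
            sig_m = C @ eps_m
            sig_top = C @ (eps_m - t_half * kappa)
            sig_bot = C @ (eps_m + t_half * kappa)
            membrane[i, e] = sig_m
            vm_top[i, e] = von_mises_2d(sig_top)
            vm_bot[i, e] = von_mises_2d(sig_bot)
    return StressField(
        times=history.snapshot_times.copy(),
        membrane=membrane,
        von_mises_top=vm_top,
        von_mises_bottom=vm_bot,
        stress_limit=stress_limit,
    )


def first_exceedance(
    stress: StressField,
    mesh: ShellMesh,
    limit: float | None = None,
    regions: tuple[str, ...] = ("floor_anterior", "floor_posterior"),
) -> tuple[float | None, int | None, str | None]:
    """Earliest snapshot at which any floor-region element's von Mises
    stress (either fiber) exceeds ``limit``.

    Returns (time s, element id, region) or (None, None, None).
    """
    if limit is None:
        limit = stress.stress_limit
    if not limit > 0:
        raise ValueError("stress limit must be positive")
    mask = np.isin(mesh.region, regions)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None, None, None
    vm = np.maximum(stress.von_mises_top[:, idx], stress.von_mises_bottom[:, idx])
    for i, t in enumerate(stress.times):
        over = vm[i] > limit
        if np.any(over):
            local = idx[int(np.argmax(vm[i]))]
            return float(t), int(local), str(mesh.region[local])
    return None, None, None


def wave_report(
    history: DisplacementHistory,
    mesh: ShellMesh,
    material: Material,
    axis_mode: AxisMode = "wall_normal",
    epsilon: float = DEFAULT_EPSILON_MM,
    stress_limit: float = DEFAULT_STRESS_LIMIT_MPA,
    stress: StressField | None = None,
    load_end_s: float = STRIKE_END_TIME_S,
) -> WaveReport:
    """Assemble the full wave report from a transient run."""
    fieldv = signed_wall_displacement(history, mesh, axis_mode)
    free = np.setdiff1d(np.arange(mesh.num_nodes), mesh.fixed_nodes)
    vals = fieldv.values[:, free]
    regs = fieldv.node_regions[free]

    i_out = np.unravel_index(np.argmin(vals), vals.shape)
    onset, onset_regions = detect_retrograde(fieldv, epsilon)
    # the reported inward peak is the amplitude of the retrograde (recurring)
    # wave, i.e. the maximum over the post-reversal phase; during the strike
    # itself parts of the wall may transiently move inward as the flexural
    # wave passes, but that early motion is not the recurring wave
    if onset is not None:
        in_window = fieldv.times >= onset
    else:
        in_window = np.ones(len(fieldv.times), dtype=bool)
    sub = vals[in_window]
    i_in_sub = np.unravel_index(np.argmax(sub), sub.shape)
    i_in = (int(np.flatnonzero(in_window)[i_in_sub[0]]), i_in_sub[1])
    probe = probe_metrics(fieldv, int(mesh.probe_A), mesh.fixed_nodes)

    if stress is None:
        stress = recover_stress(history, mesh, material, stress_limit)
    t_exc, _, _ = first_exceedance(stress, mesh, stress_limit)

    sweep = floor_sweep(fieldv, mesh)
    na = nodal_areas(mesh)
    floor_sel = free[np.isin(regs, ("floor_anterior", "floor_posterior"))]
    floor_area = float(na[floor_sel].sum())
    in_window = (fieldv.times > 0.0) & (fieldv.times <= load_end_s)
    if np.any(in_window) and floor_area > 0:
        window_mean = float(
            sweep["swept_volume_mm3"][in_window].mean() / floor_area
        )
        window_frac = float(sweep["outward_area_fraction"][in_window].mean())
    else:
        window_mean = 0.0
        window_frac = 0.0

    extrema: dict[str, dict[str, float]] = {}
    for r in REGIONS:
        m = regs == r
        if not np.any(m):
            continue
        sub = vals[:, m]
        extrema[r] = {
            "outward_mm": float(max(0.0, -sub.min())),
            "inward_mm": float(max(0.0, sub.max())),
        }

    return WaveReport(
        peak_outward_mm=float(max(0.0, -vals[i_out])),
        peak_outward_time_s=float(fieldv.times[i_out[0]]),
        peak_outward_region=str(regs[i_out[1]]),
        peak_inward_mm=float(max(0.0, vals[i_in])),
        peak_inward_time_s=float(fieldv.times[i_in[0]]),
        peak_inward_region=str(regs[i_in[1]]),
        reversal_onset_s=onset,
        reversal_regions=onset_regions,
        probe_A_outward_mm=probe["outward_mm"],
        probe_A_inward_mm=probe["inward_mm"],
        probe_A_peak_to_peak_mm=probe["peak_to_peak_mm"],
        stress_first_exceedance_s=t_exc,
        load_window_floor_mean_mm=window_mean,
        load_window_floor_outward_area_fraction=window_frac,
        region_extrema=extrema,
    )
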