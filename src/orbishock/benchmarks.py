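"""Analytic verification benchmarks for the shell solver.

Every benchmark compares the finite-element result against an independent
closed-form oracle: the constant-strain patch test, the Navier series for
a simply supported Kirchhoff plate, the classical plate fundamental
frequency, the harmonic-oscillator period, the discrete energy balance of
an undamped impact run, explicit-vs-implicit integrator agreement, and the
divergence guard of the explicit stepper.  Each returns a
:class:`BenchmarkResult` with the measured dimensionless error and its
tolerance; :func:`run_all` executes the suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .geometry import OrbitParams, ShellMesh, generate_orbit
from .shell import GlobalSystem, Material, assemble, static_solve, element_membrane_strain, dof_indices
from .dynamics import (
    InstabilityError,
    LoadCase,
    TimeIntegrationConfig,
    default_strike_load,
    integrate,
    stable_dt,
)


@dataclass
class BenchmarkResult:
    name: str
    metric: float  # dimensionless error (relative, unless noted)
    tolerance: float
    passed: bool
    detail: str = ""


# ---------------------------------------------------------------------------
# mesh builders (also used by the test suite)


def rectangle_mesh(
    nx: int,
    ny: int,
    lx: float,
    ly: float,
    thickness: float,
    fixed: str = "none",
) -> ShellMesh:
    """Flat rectangular strip in the z=0 plane, alternating diagonals.

    ``fixed``: "none", "left" (clamp the x=0 edge) or "boundary".
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    nodes = np.array([[x, y, 0.0] for y in ys for x in xs])
    idx = lambda i, j: j * (nx + 1) + i  # noqa: E731
    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i + 1, j + 1), idx(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.asarray(tris, dtype=np.int64)
    if fixed == "left":
        fixed_nodes = np.array([idx(0, j) for j in range(ny + 1)], dtype=np.int64)
    elif fixed == "boundary":
        fixed_nodes = np.array(
            sorted(
                idx(i, j)
                for j in range(ny + 1)
                for i in range(nx + 1)
                if i in (0, nx) or j in (0, ny)
            ),
            dtype=np.int64,
        )
    else:
        fixed_nodes = np.empty(0, dtype=np.int64)
    return ShellMesh(
        nodes=nodes,
        triangles=tris,
        thickness=np.full(len(tris), thickness),
        region=np.full(len(tris), "roof", dtype="<U16"),
        fixed_nodes=fixed_nodes,
        load_nodes=np.empty(0, dtype=np.int64),
        probe_A=idx(nx // 2, ny // 2),
    )


def navier_center_deflection(q: float, a: float, D: float, terms: int = 39) -> float:
    """Center deflection of a simply supported square Kirchhoff plate under
    uniform pressure q: the alternating double sine series."""
    tot = 0.0
    for m in range(1, terms + 1, 2):
        for n in range(1, terms + 1, 2):
            sign = (-1.0) ** ((m - 1) // 2 + (n - 1) // 2)
            tot += sign / (m * n * (m * m + n * n) ** 2)
    return 16.0 * q * a**4 / (np.pi**6 * D) * tot


def plate_fundamental_omega(a: float, D: float, rho_t: float) -> float:
    """omega_11 of a simply supported square Kirchhoff plate, rad/s."""
    return np.pi**2 * (2.0 / a**2) * np.sqrt(D / rho_t)


def _simply_supported(mesh: ShellMesh, nx: int, ny: int) -> dict[int, float]:
    """Hard simple support: w=0 on the boundary plus the tangential-slope
    rotation; membrane pinned on the boundary."""
    idx = lambda i, j: j * (nx + 1) + i  # noqa: E731
    pres: dict[int, float] = {}
    for j in range(ny + 1):
        for i in range(nx + 1):
            n = idx(i, j)
            if i in (0, nx) or j in (0, ny):
                pres[6 * n + 0] = 0.0
                pres[6 * n + 1] = 0.0
                pres[6 * n + 2] = 0.0
                if j in (0, ny):
                    pres[6 * n + 4] = 0.0  # edge along x: theta_y = 0
                if i in (0, nx):
                    pres[6 * n + 3] = 0.0  # edge along y: theta_x = 0
    return pres


# ---------------------------------------------------------------------------
# individual benchmarks


def patch_test(material: Material | None = None) -> BenchmarkResult:
    """Constant-strain membrane patch test on an irregular flat patch."""
    material = material or Material()
    rng = np.random.default_rng(7)
    mesh = rectangle_mesh(4, 4, 4.0, 4.0, 0.5)
    interior = np.setdiff1d(
        np.arange(mesh.num_nodes),
        [j * 5 + i for j in range(5) for i in range(5) if i in (0, 4) or j in (0, 4)],
    )
    mesh.nodes[interior, :2] += rng.uniform(-0.2, 0.2, size=(len(interior), 2))
    system = assemble(mesh, material)
    # arbitrary linear in-plane field: u = a0 + a1 x + a2 y, v = b0 + ...
    a_c, b_c = (0.3, 1.2e-3, -0.7e-3), (-0.1, 0.4e-3, 2.1e-3)
    exact = np.array([a_c[1], b_c[2], a_c[2] + b_c[1]])
    pres: dict[int, float] = {}
    for n in range(mesh.num_nodes):
        x, y, _ = mesh.nodes[n]
        is_boundary = n not in interior
        if is_boundary:
            pres[6 * n + 0] = a_c[0] + a_c[1] * x + a_c[2] * y
            pres[6 * n + 1] = b_c[0] + b_c[1] * x + b_c[2] * y
        pres[6 * n + 2] = 0.0  # keep the patch flat
        pres[6 * n + 3] = 0.0
        pres[6 * n + 4] = 0.0
    u = static_solve(system, np.zeros(system.num_dofs), prescribed=pres)
    err = 0.0
    from .shell import local_frame

    for e, tri in enumerate(mesh.triangles):
        eps = element_membrane_strain(mesh.nodes[tri], u[dof_indices(tri)])
        # element strains live in the element frame: rotate the exact
        # global-plane strain tensor to each element's axes before comparing
        R, _ = local_frame(mesh.nodes[tri])
        c, s = R[0, 0], R[0, 1]
        ex, ey, g = exact
        exact_loc = np.array(
            [
                c * c * ex + s * s * ey + c * s * g,
                s * s * ex + c * c * ey - c * s * g,
                2.0 * c * s * (ey - ex) + (c * c - s * s) * g,
            ]
        )
        err = max(err, float(np.abs(eps - exact_loc).max() / np.abs(exact).max()))
    return BenchmarkResult("membrane_patch_test", err, 1e-8, err <= 1e-8)


def plate_deflection(n: int = 32, material: Material | None = None) -> BenchmarkResult:
    """Simply supported square plate, uniform pressure, vs Navier series."""
    material = material or Material()
    a_len, t = 10.0, 0.1
    mesh = rectangle_mesh(n, n, a_len, a_len, t)
    system = assemble(mesh, material)
    q = 1.0e-3
    f = np.zeros(system.num_dofs)
    areas = mesh.element_areas()
    for e, tri in enumerate(mesh.triangles):
        for node in tri:
            f[6 * node + 2] += q * areas[e] / 3.0
    u = static_solve(system, f, prescribed=_simply_supported(mesh, n, n))
    idx = lambda i, j: j * (n + 1) + i  # noqa: E731
    wc = u[6 * idx(n // 2, n // 2) + 2]
    D = material.E_mpa * t**3 / (12.0 * (1.0 - material.poisson_ratio**2))
    ref = navier_center_deflection(q, a_len, D)
    err = abs(wc - ref) / ref
    return BenchmarkResult(
        "plate_deflection", err, 0.02, err <= 0.02, f"w_c={wc:.4e} ref={ref:.4e}"
    )


def plate_frequency(n: int = 24, material: Material | None = None) -> BenchmarkResult:
    """Fundamental frequency of the simply supported plate vs pi^2(2/a^2)sqrt(D/rho t)."""
    material = material or Material()
    a_len, t = 10.0, 0.1
    mesh = rectangle_mesh(n, n, a_len, a_len, t)
    pres = _simply_supported(mesh, n, n)
    mesh.fixed_nodes = np.empty(0, dtype=np.int64)
    system = assemble(mesh, material)
    con = np.array(sorted(pres.keys()), dtype=np.int64)
    mask = np.ones(system.num_dofs, dtype=bool)
    mask[con] = False
    free = np.flatnonzero(mask)
    K = system.stiffness[np.ix_(free, free)].tocsc()
    m = system.mass[free]
    inv_sqrt = 1.0 / np.sqrt(m)
    import scipy.sparse as sp

    A = sp.diags(inv_sqrt) @ K @ sp.diags(inv_sqrt)
    vals = spla.eigsh(A, k=1, sigma=0.0, return_eigenvectors=False)
    omega = float(np.sqrt(vals[0]))
    D = material.E_mpa * t**3 / (12.0 - 12.0 * material.poisson_ratio**2)
    ref = plate_fundamental_omega(a_len, D, material.rho_tonne_mm3 * t)
    err = abs(omega - ref) / ref
    return BenchmarkResult(
        "plate_frequency", err, 0.03, err <= 0.03, f"omega={omega:.4e} ref={ref:.4e}"
    )


def oscillator_period(material: Material | None = None) -> BenchmarkResult:
    """Single-dof oscillator (k = 1 N/mm, m = 1 tonne): period vs 2 pi."""
    import scipy.sparse as sp

    K = sp.csr_matrix(np.eye(6))
    system = GlobalSystem(
        stiffness=K, mass=np.ones(6), constrained_dofs=np.arange(1, 6), num_nodes=1
    )
    dt = stable_dt(system) / 20.0
    case = LoadCase(load_nodes=(0,), peak_force_per_node=0.0)
    cfg = TimeIntegrationConfig(dt=dt, t_end=4.0 * 2.0 * np.pi, snapshot_interval=dt)
    u0 = np.zeros(6)
    u0[0] = 1.0
    hist = integrate(system, case, cfg, initial_displacement=u0)
    trace = hist.displacements[:, 0, 0]
    times = hist.snapshot_times
    # period from zero-downcrossings with linear interpolation
    crossings = []
    for i in range(1, len(trace)):
        if trace[i - 1] > 0.0 >= trace[i]:
            frac = trace[i - 1] / (trace[i - 1] - trace[i])
            crossings.append(times[i - 1] + frac * (times[i] - times[i - 1]))
    period = float(np.mean(np.diff(crossings)))
    ref = 2.0 * np.pi
    err = abs(period - ref) / ref
    return BenchmarkResult(
        "oscillator_period", err, 0.005, err <= 0.005, f"T={period:.6f} ref={ref:.6f}"
    )


def energy_balance(
    target_elements: int = 300, material: Material | None = None
) -> BenchmarkResult:
    """Undamped strike on a reduced orbit: |work - (kinetic + strain)| as a
    fraction of peak external work, worst snapshot."""
    material = material or Material()
    mesh = generate_orbit(dataclasses.replace(OrbitParams(), target_elements=target_elements))
    system = assemble(mesh, material)
    hist = integrate(system, default_strike_load(mesh), TimeIntegrationConfig())
    E = hist.energy_trace
    peak = float(np.abs(E[:, 0]).max())
    err = float(np.abs(E[:, 0] - E[:, 1] - E[:, 2]).max() / peak)
    return BenchmarkResult("energy_balance", err, 0.01, err <= 0.01)


def cross_integrator(
    target_elements: int = 300, material: Material | None = None
) -> BenchmarkResult:
    """Explicit central difference vs implicit Newmark on the same strike:
    max probe-trace difference as a fraction of peak amplitude."""
    material = material or Material()
    mesh = generate_orbit(dataclasses.replace(OrbitParams(), target_elements=target_elements))
    system = assemble(mesh, material)
    case = default_strike_load(mesh)
    dt = stable_dt(system) / 2.0
    h1 = integrate(system, case, TimeIntegrationConfig(method="central_difference", dt=dt))
    h2 = integrate(
        system,
        case,
        TimeIntegrationConfig(method="newmark_average_acceleration", dt=dt),
    )
    t1 = h1.probe_trace(mesh.probe_A)
    t2 = h2.probe_trace(mesh.probe_A)
    peak = float(np.abs(t1).max())
    err = float(np.abs(t1 - t2).max() / peak)
    return BenchmarkResult("cross_integrator", err, 0.05, err <= 0.05)


def instability_guard(material: Material | None = None) -> BenchmarkResult:
    """Deliberately exceed the stable step: the explicit solver must detect
    the divergence and abort with the step index, not crash or return junk."""
    material = material or Material()
    mesh = generate_orbit(dataclasses.replace(OrbitParams(), target_elements=150))
    system = assemble(mesh, material)
    dt = 1.5 * stable_dt(system)
    try:
        integrate(
            system,
            default_strike_load(mesh),
            TimeIntegrationConfig(dt=dt, snapshot_interval=1e-3),
        )
    except InstabilityError as err:
        detected = "step" in str(err)
        return BenchmarkResult("instability_guard", 0.0, 1.0, detected, str(err))
    return BenchmarkResult(
        "instability_guard", 1.0, 1.0, False, "divergence was not detected"
    )


def run_all(material: Material | None = None) -> list[BenchmarkResult]:
    """Execute the whole verification suite; failures are reported in the
    table, never raised."""
    suite = (
        patch_test,
        plate_deflection,
        plate_frequency,
        oscillator_period,
        energy_balance,
        cross_integrator,
        instability_guard,
    )
    results = []
    for bench in suite:
        try:
            results.append(bench(material=material))
        except Exception as err:  # pragma: no cover - defensive
            results.append(BenchmarkResult(bench.__name__, float("nan"), 0.0, False, repr(err)))
    return results
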