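"""Wave post-processing: sign conventions, reversal detection, stress."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import orbishock as ob
from orbishock.analysis import (
    FLOOR_BASE_REGIONS,
    SignedDisplacementField,
    detect_retrograde,
    first_exceedance,
    floor_sweep,
    node_region_map,
    probe_metrics,
    recover_stress,
    signed_wall_displacement,
    von_mises_2d,
    wave_report,
)
from orbishock.benchmarks import rectangle_mesh
from orbishock.dynamics import DisplacementHistory
from orbishock.shell import static_solve


def synthetic_history(mesh, translations_by_snapshot):
    """Wrap a list of (n_nodes, 3) translation arrays as a history."""
    n_snap = len(translations_by_snapshot)
    disp = np.zeros((n_snap, mesh.num_nodes, 6))
    for i, tr in enumerate(translations_by_snapshot):
        disp[i, :, :3] = tr
    return DisplacementHistory(
        snapshot_times=np.arange(n_snap) * 1e-3,
        displacements=disp,
        velocities=np.zeros_like(disp),
        energy_trace=np.zeros((n_snap, 4)),
    )


class TestSignConvention:
    def test_translation_toward_sinus_is_negative_on_floor(self, coarse_mesh):
        """A rigid -z translation moves the floor away from the orbit:
        its signed displacement must be negative there."""
        tr = np.tile([0.0, 0.0, -1.0], (coarse_mesh.num_nodes, 1))
        hist = synthetic_history(coarse_mesh, [np.zeros_like(tr), tr])
        f = signed_wall_displacement(hist, coarse_mesh)
        floor = np.isin(f.node_regions, ("floor_anterior", "floor_posterior"))
        floor &= ~np.isin(np.arange(coarse_mesh.num_nodes), coarse_mesh.fixed_nodes)
        assert np.all(f.values[1, floor] < 0.0)
        assert np.all(f.values[0] == 0.0)

    def test_zero_history_gives_zero_field(self, coarse_mesh):
        hist = synthetic_history(coarse_mesh, [np.zeros((coarse_mesh.num_nodes, 3))])
        f = signed_wall_displacement(hist, coarse_mesh)
        assert np.all(f.values == 0.0)

    def test_orbital_axis_mode_is_signed_x_component(self, coarse_mesh):
        """Direct componentwise oracle for the sagittal-axis projection."""
        rng = np.random.default_rng(4)
        tr = rng.normal(size=(coarse_mesh.num_nodes, 3))
        hist = synthetic_history(coarse_mesh, [tr])
        f = signed_wall_displacement(hist, coarse_mesh, axis_mode="orbital_axis")
        normals = coarse_mesh.node_normals()
        side = np.sign(normals[:, 0])
        side[side == 0] = 1.0
        expected = tr[:, 0] * side
        expected[coarse_mesh.fixed_nodes] = 0.0
        np.testing.assert_allclose(f.values[0], expected, atol=1e-12)

    def test_orientation_flip_negates_the_field(self, coarse_mesh):
        mesh2 = coarse_mesh.copy()
        mesh2.triangles = mesh2.triangles[:, [0, 2, 1]]
        rng = np.random.default_rng(8)
        tr = rng.normal(size=(coarse_mesh.num_nodes, 3))
        hist = synthetic_history(coarse_mesh, [tr])
        f1 = signed_wall_displacement(hist, coarse_mesh)
        f2 = signed_wall_displacement(hist, mesh2)
        np.testing.assert_allclose(f2.values, -f1.values, atol=1e-12)


def _field_from_traces(times, values, regions):
    return SignedDisplacementField(
        times=np.asarray(times),
        values=np.asarray(values),
        axis_mode="wall_normal",
        node_regions=np.asarray(regions, dtype="<U16"),
    )


class TestRetrogradeDetection:
    def brute_force_onset(self, times, values, eps):
        """Exhaustive snapshot-scan oracle."""
        n_nodes = values.shape[1]
        been_out = [False] * n_nodes
        for i, t in enumerate(times):
            for n in range(n_nodes):
                if been_out[n] and values[i, n] > eps:
                    return t
            for n in range(n_nodes):
                if values[i, n] < -eps:
                    been_out[n] = True
        return None

    def test_sinusoid_matches_scan_oracle(self):
        times = np.arange(11) * 1e-3
        trace = -np.sin(2 * np.pi * 100.0 * times)  # mm
        values = trace[:, None]
        field = _field_from_traces(times, values, ["floor_anterior"])
        for eps in (0.05, 0.1, 0.5, 0.9):
            onset, regions = detect_retrograde(field, epsilon=eps)
            assert onset == self.brute_force_onset(times, values, eps)
            if onset is not None:
                assert regions == ("floor_anterior",)

    def test_random_traces_match_scan_oracle(self):
        rng = np.random.default_rng(13)
        times = np.arange(11) * 1e-3
        regions = rng.choice(FLOOR_BASE_REGIONS, size=7)
        for _ in range(20):
            values = rng.normal(scale=0.4, size=(11, 7))
            field = _field_from_traces(times, values, regions)
            onset, _ = detect_retrograde(field, epsilon=0.1)
            assert onset == self.brute_force_onset(times, values, 0.1)

    def test_monotone_outward_has_no_reversal(self):
        times = np.arange(5) * 1e-3
        values = -np.linspace(0, 3, 5)[:, None]
        field = _field_from_traces(times, values, ["medial"])
        assert detect_retrograde(field)[0] is None

    def test_epsilon_above_amplitude_sees_nothing(self):
        times = np.arange(11) * 1e-3
        values = -np.sin(2 * np.pi * 100 * times)[:, None] * 0.3
        field = _field_from_traces(times, values, ["floor_posterior"])
        assert detect_retrograde(field, epsilon=0.5)[0] is None

    def test_non_floor_regions_are_ignored(self):
        times = np.arange(3) * 1e-3
        values = np.array([[-1.0], [1.0], [0.0]])
        field = _field_from_traces(times, values, ["roof"])
        assert detect_retrograde(field, epsilon=0.1)[0] is None


class TestProbeMetrics:
    def test_reference_trace_arithmetic(self):
        """The printed point-A extrema: 4.37 mm out + 1.55 mm in = 5.92 mm."""
        trace = np.array([[0.0], [-4.37], [-2.0], [1.55], [0.0]])
        field = _field_from_traces(np.arange(5) * 1e-3, trace, ["floor_anterior"])
        m = probe_metrics(field, 0)
        assert m["outward_mm"] == pytest.approx(4.37)
        assert m["inward_mm"] == pytest.approx(1.55)
        assert m["peak_to_peak_mm"] == pytest.approx(5.92)

    def test_zero_trace(self):
        field = _field_from_traces(np.arange(3) * 1e-3, np.zeros((3, 1)), ["medial"])
        m = probe_metrics(field, 0)
        assert m["outward_mm"] == m["inward_mm"] == m["peak_to_peak_mm"] == 0.0

    def test_constant_outward_trace(self):
        field = _field_from_traces(
            np.arange(4) * 1e-3, np.full((4, 1), -2.5), ["medial"]
        )
        m = probe_metrics(field, 0)
        assert m["outward_mm"] == pytest.approx(2.5)
        assert m["inward_mm"] == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-50.0, max_value=50.0, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    def test_probe_invariants_hold_for_any_trace(self, trace):
        """Peaks are non-negative, peak-to-peak is their sum, and negating
        the trace swaps the outward and inward roles."""
        arr = np.array(trace)[:, None]
        times = np.arange(len(trace)) * 1e-3
        f_pos = _field_from_traces(times, arr, ["medial"])
        f_neg = _field_from_traces(times, -arr, ["medial"])
        m, mn = probe_metrics(f_pos, 0), probe_metrics(f_neg, 0)
        assert m["outward_mm"] >= 0 and m["inward_mm"] >= 0
        assert m["peak_to_peak_mm"] == pytest.approx(
            m["outward_mm"] + m["inward_mm"]
        )
        assert mn["outward_mm"] == pytest.approx(m["inward_mm"])
        assert mn["inward_mm"] == pytest.approx(m["outward_mm"])

    def test_fixed_probe_rejected(self, coarse_mesh):
        field = _field_from_traces(
            np.arange(2) * 1e-3,
            np.zeros((2, coarse_mesh.num_nodes)),
            node_region_map(coarse_mesh),
        )
        fixed = int(coarse_mesh.fixed_nodes[0])
        with pytest.raises(ValueError):
            probe_metrics(field, fixed, coarse_mesh.fixed_nodes)


class TestStressRecovery:
    def test_von_mises_closed_forms(self):
        assert von_mises_2d(np.array([7.0, 0.0, 0.0])) == pytest.approx(7.0)
        assert von_mises_2d(np.array([0.0, 0.0, 3.0])) == pytest.approx(3 * np.sqrt(3))
        assert von_mises_2d(np.array([0.0, 0.0, 0.0])) == 0.0

    def test_undeformed_state_has_zero_stress(self, coarse_mesh, material):
        hist = synthetic_history(coarse_mesh, [np.zeros((coarse_mesh.num_nodes, 3))])
        s = recover_stress(hist, coarse_mesh, material)
        assert np.all(s.von_mises_top == 0.0)
        assert np.all(s.von_mises_bottom == 0.0)

    def test_cantilever_root_bending_stress(self, material):
        """Root surface stress of a tip-loaded strip vs beam theory Mc/I,
        within 10% (the CST/DKT facet recovers stress at centroids)."""
        L, W, t, P = 10.0, 1.0, 0.2, 1.0
        mesh = rectangle_mesh(40, 4, L, W, t, fixed="left")
        system = ob.assemble(mesh, material)
        f = np.zeros(system.num_dofs)
        tip = np.flatnonzero(np.abs(mesh.nodes[:, 0] - L) < 1e-12)
        for n in tip:
            f[6 * n + 2] = P / len(tip)
        u = static_solve(system, f)
        hist = DisplacementHistory(
            snapshot_times=np.array([0.0]),
            displacements=u.reshape(1, -1, 6),
            velocities=np.zeros((1, mesh.num_nodes, 6)),
            energy_trace=np.zeros((1, 4)),
        )
        stress = recover_stress(hist, mesh, material)
        cent = mesh.element_centroids()
        root = np.argsort(cent[:, 0])[:8]
        got = stress.von_mises_top[0, root].max()
        x_c = cent[root, 0].min()
        M = P * (L - x_c)
        ref = M * (t / 2) / (W * t**3 / 12.0)
        assert got == pytest.approx(ref, rel=0.10)


class TestFirstExceedance:
    def _stress_field(self, mesh, vm):
        from orbishock.analysis import StressField

        n_snap, n_elem = vm.shape
        return StressField(
            times=np.arange(n_snap) * 1e-3,
            membrane=np.zeros((n_snap, n_elem, 3)),
            von_mises_top=vm,
            von_mises_bottom=np.zeros_like(vm),
        )

    def test_infinite_limit_never_exceeded(self, coarse_mesh):
        vm = np.ones((3, coarse_mesh.num_elements))
        s = self._stress_field(coarse_mesh, vm)
        assert first_exceedance(s, coarse_mesh, limit=np.inf)[0] is None

    def test_tiny_limit_hits_first_nonzero_snapshot(self, coarse_mesh):
        vm = np.zeros((4, coarse_mesh.num_elements))
        vm[2:, :] = 1.0
        s = self._stress_field(coarse_mesh, vm)
        t, _, _ = first_exceedance(s, coarse_mesh, limit=1e-12)
        assert t == pytest.approx(2e-3)

    def test_known_single_exceeding_element(self, coarse_mesh):
        """Exhaustive scan oracle: plant one floor element above the limit."""
        floor_elems = np.flatnonzero(
            coarse_mesh.region_mask("floor_anterior", "floor_posterior")
        )
        target = int(floor_elems[3])
        vm = np.zeros((5, coarse_mesh.num_elements))
        vm[3, target] = 99.0
        vm[4, :] = 99.0
        s = self._stress_field(coarse_mesh, vm)
        t, elem, region = first_exceedance(s, coarse_mesh, limit=50.0)
        assert t == pytest.approx(3e-3)
        assert elem == target
        assert region in ("floor_anterior", "floor_posterior")

    def test_roof_stress_does_not_trigger_floor_limit(self, coarse_mesh):
        roof = np.flatnonzero(coarse_mesh.region_mask("roof"))
        vm = np.zeros((2, coarse_mesh.num_elements))
        vm[1, roof] = 1e6
        s = self._stress_field(coarse_mesh, vm)
        assert first_exceedance(s, coarse_mesh, limit=10.0)[0] is None


class TestDefaultRunReport:
    def test_report_consistency(self, default_report):
        r = default_report
        assert r.probe_A_peak_to_peak_mm == pytest.approx(
            r.probe_A_outward_mm + r.probe_A_inward_mm, abs=1e-12
        )
        assert r.peak_outward_mm >= 0 and r.peak_inward_mm >= 0
        assert r.reversal_onset_s is not None
        assert (
            r.peak_outward_time_s <= r.reversal_onset_s <= r.peak_inward_time_s
        )

    def test_paper_sequence_properties(self, default_report):
        """Outward-dominated floor motion during the strike, a reversal
        afterwards, and a weaker inward rebound than the outward excursion."""
        r = default_report
        assert r.load_window_floor_mean_mm < 0.0
        assert r.load_window_floor_outward_area_fraction > 0.5
        assert r.reversal_onset_s > r.peak_outward_time_s
        assert r.peak_inward_mm < r.peak_outward_mm

    def test_floor_sweep_shapes(self, default_history, default_mesh):
        f = signed_wall_displacement(default_history, default_mesh)
        sweep = floor_sweep(f, default_mesh)
        assert len(sweep["swept_volume_mm3"]) == default_history.num_snapshots
        assert np.all(sweep["outward_area_fraction"] >= 0.0)
        assert np.all(sweep["outward_area_fraction"] <= 1.0)
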