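import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlyfmt.fem_assembly import assemble_system
from earlyfmt.forward_born import (
    DegenerateSystemError,
    MeasurementSet,
    add_noise,
    build_weight_matrix,
    convolve_rows,
    emission_source_series,
    normalized_born,
    simulate_measurements,
    temporal_convolve,
)
from earlyfmt.greens_solver import (
    GreensField,
    Propagator,
    lifetime_kernel,
    make_time_grid,
    point_source_vector,
)
from earlyfmt.mesh_model import FluorophoreMap
from .oracles import direct_convolve


class TestTemporalConvolve:
    def test_matches_direct_double_sum_exactly(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            T = int(rng.integers(1, 65))
            a = rng.standard_normal(T)
            b = rng.standard_normal(T)
            dt = float(rng.choice([0.5, 2.0, 10.0]))
            assert np.array_equal(temporal_convolve(a, b, dt), direct_convolve(a, b, dt))

    def test_discrete_identity_element(self):
        rng = np.random.default_rng(22)
        a = rng.standard_normal(16)
        dt = 2.0  # power of two keeps dt * (1/dt) exact
        delta = np.zeros(16)
        delta[0] = 1.0 / dt
        assert np.array_equal(temporal_convolve(a, delta, dt), a)

    def test_rectangles_make_triangle(self):
        T, dt = 16, 1.0
        rect = np.zeros(T)
        rect[:5] = 1.0
        out = temporal_convolve(rect, rect, dt)
        assert np.array_equal(out, direct_convolve(rect, rect, dt))
        assert out[4] == pytest.approx(5.0 * dt)  # triangle apex at 4*dt
        assert np.argmax(out) == 4

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_commutative_and_bilinear(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 33))
        a, b, c = rng.standard_normal((3, T))
        dt = 3.0
        ab = temporal_convolve(a, b, dt)
        assert np.allclose(ab, temporal_convolve(b, a, dt), rtol=1e-13, atol=1e-13)
        assert np.allclose(
            temporal_convolve(a, b + c, dt),
            ab + temporal_convolve(a, c, dt),
            rtol=1e-12,
            atol=1e-12,
        )

    def test_length_mismatch_rejected(self):
        from earlyfmt.greens_solver import ConfigurationError

        with pytest.raises(ConfigurationError):
            temporal_convolve(np.ones(4), np.ones(5), 1.0)

    def test_batched_rows_match_scalar_path(self):
        rng = np.random.default_rng(23)
        A = rng.standard_normal((7, 20))
        e = rng.standard_normal(20)
        out = convolve_rows(A, e, 10.0)
        for i in range(7):
            ref = temporal_convolve(A[i], e, 10.0)
            assert np.allclose(out[i], ref, rtol=1e-12, atol=1e-14)


def _tiny_forward(small_phantom, eta_value=1e-3, backend="accelerated"):
    mesh, props, _ = small_phantom
    tg = make_time_grid(10.0, 200.0, 200.0)
    system = assemble_system(mesh, props)
    prop = Propagator(system, tg.dt)
    src_pts = [np.array([1.2, 0.0, 1.5]), np.array([-1.2, 0.0, 1.5])]
    srcs = [point_source_vector(mesh, p, props, tg) for p in src_pts]
    # point-like target: a single interior node
    center = np.array([0.3, 0.0, 1.5])
    node = int(np.argmin(np.linalg.norm(mesh.node_coords - center, axis=1)))
    eta = np.zeros(mesh.n_nodes)
    eta[node] = eta_value
    fluor = FluorophoreMap(eta=eta, tau=560.0)
    det_sets = [
        [int(i) for i in np.unique(mesh.boundary_faces)[::9][:6]],
        [int(i) for i in np.unique(mesh.boundary_faces)[3::9][:6]],
    ]
    ms, gs_fields = simulate_measurements(
        prop, tg, system.C, props.c, srcs, det_sets, fluor
    )
    return mesh, props, tg, system, prop, srcs, det_sets, fluor, ms, gs_fields


class TestForwardSimulation:
    def test_zero_yield_zero_fluorescence(self, small_phantom):
        mesh, props, _ = small_phantom
        tg = make_time_grid(10.0, 100.0, 100.0)
        system = assemble_system(mesh, props)
        prop = Propagator(system, tg.dt)
        src = point_source_vector(mesh, np.array([1.2, 0, 1.5]), props, tg)
        fluor = FluorophoreMap(eta=np.zeros(mesh.n_nodes), tau=560.0)
        ms, _ = simulate_measurements(
            prop, tg, system.C, props.c, [src], [[0, 5]], fluor
        )
        assert np.all(ms.phim == 0)
        assert np.any(ms.phix != 0)

    def test_fluorescence_linear_in_yield(self, small_phantom):
        out1 = _tiny_forward(small_phantom, eta_value=1e-3)
        out2 = _tiny_forward(small_phantom, eta_value=2e-3)
        assert np.allclose(2.0 * out1[8].phim, out2[8].phim, rtol=1e-12)

    def test_emission_source_scaling(self, small_phantom):
        mesh, props, _ = small_phantom
        tg = make_time_grid(10.0, 100.0, 100.0)
        system = assemble_system(mesh, props)
        prop = Propagator(system, tg.dt)
        src = point_source_vector(mesh, np.array([1.2, 0, 1.5]), props, tg)
        from earlyfmt.greens_solver import propagate

        gx = propagate(prop, tg, src)
        E = lifetime_kernel(560.0, tg)
        eta = np.zeros(mesh.n_nodes)
        eta[10] = 1.0
        s1 = emission_source_series(
            FluorophoreMap(eta, 560.0), gx, E, system.C, props.c, tg
        )
        s2 = emission_source_series(
            FluorophoreMap(2 * eta, 560.0), gx, E, system.C, props.c, tg
        )
        assert np.allclose(s2.values, 2 * s1.values, rtol=1e-14)
        # direct hand evaluation at one time node
        U = convolve_rows(gx.values, E, tg.dt)
        expect = system.C @ ((props.c / 560.0) * eta * U[:, 2])
        assert np.allclose(s1.values[:, 2], expect, rtol=1e-12)

    def test_zero_yield_zero_emission_series(self, small_phantom):
        mesh, props, _ = small_phantom
        tg = make_time_grid(10.0, 50.0, 50.0)
        system = assemble_system(mesh, props)
        prop = Propagator(system, tg.dt)
        from earlyfmt.greens_solver import propagate

        src = point_source_vector(mesh, np.array([1.2, 0, 1.5]), props, tg)
        gx = propagate(prop, tg, src)
        E = lifetime_kernel(560.0, tg)
        s = emission_source_series(
            FluorophoreMap(np.zeros(mesh.n_nodes), 560.0), gx, E, system.C, props.c, tg
        )
        assert np.all(s.values == 0)


class TestWeightMatrix:
    def test_born_prediction_matches_coupled_simulation(self, small_phantom):
        """W @ eta reproduces the two-stage forward model at the gate."""
        (mesh, props, tg, system, prop, srcs, det_sets, fluor, ms, gs_fields) = (
            _tiny_forward(small_phantom)
        )
        from earlyfmt.greens_solver import batched_detector_fields

        E = lifetime_kernel(fluor.tau, tg)
        rows = []
        for i, dets in enumerate(det_sets):
            gd = batched_detector_fields(prop, tg, dets)
            rows.append(
                build_weight_matrix(
                    gs_fields[i], gd, E, tg, system.C, props.c, fluor.tau
                )
            )
        W = np.vstack(rows)
        pred = W @ fluor.eta
        meas = ms.phim_gate
        assert np.allclose(pred, meas, rtol=5e-2)
        # the discrete model is exactly linear in eta, so far tighter:
        assert np.allclose(pred, meas, rtol=1e-9)

    def test_reference_backend_equivalent(self, small_phantom):
        (mesh, props, tg, system, prop, srcs, det_sets, fluor, ms, gs_fields) = (
            _tiny_forward(small_phantom)
        )
        from earlyfmt.greens_solver import batched_detector_fields

        E = lifetime_kernel(fluor.tau, tg)
        gd = batched_detector_fields(prop, tg, det_sets[0][:2])
        args = (gs_fields[0], gd, E, tg, system.C, props.c, fluor.tau)
        acc = build_weight_matrix(*args, backend="accelerated")
        ref = build_weight_matrix(*args, backend="reference")
        assert np.allclose(acc, ref, rtol=1e-12, atol=1e-30)

    def test_zero_kernel_zero_weights(self, small_phantom):
        (mesh, props, tg, system, prop, srcs, det_sets, fluor, ms, gs_fields) = (
            _tiny_forward(small_phantom)
        )
        from earlyfmt.greens_solver import batched_detector_fields

        gd = batched_detector_fields(prop, tg, det_sets[0][:2])
        W = build_weight_matrix(
            gs_fields[0], gd, np.zeros(tg.n_nodes), tg, system.C, props.c, fluor.tau
        )
        assert np.all(W == 0)

    def test_single_node_entry_is_scalar_triple_convolution(self):
        tg = make_time_grid(2.0, 20.0, 20.0)
        rng = np.random.default_rng(31)
        gs = rng.random((1, tg.n_nodes))
        gd = rng.random((1, tg.n_nodes))
        E = rng.random(tg.n_nodes)
        import scipy.sparse as sp

        C = sp.csc_matrix(np.array([[0.37]]))
        gsf = GreensField(gs, tg, "excitation")
        gdf = GreensField(gd, tg, "detector_adjoint")
        W = build_weight_matrix(gsf, [gdf], E, tg, C, c=0.02, tau=500.0)
        # oracle: (gs * E) by direct sum, then the exact discrete pairing
        gse = direct_convolve(gs[0], E, tg.dt)
        K = tg.gate_index
        expect = (0.02 / 500.0) * sum(
            gse[j] * 0.37 * gd[0, K - j] for j in range(K + 1)
        )
        assert W[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_swapping_source_and_detector_roles(self):
        tg = make_time_grid(2.0, 20.0, 20.0)
        rng = np.random.default_rng(32)
        gs = rng.random((1, tg.n_nodes))
        gd = rng.random((1, tg.n_nodes))
        E = rng.random(tg.n_nodes)
        import scipy.sparse as sp

        C = sp.csc_matrix(np.array([[1.0]]))
        a = build_weight_matrix(
            GreensField(gs, tg, "excitation"),
            [GreensField(gd, tg, "detector_adjoint")],
            E, tg, C, 1.0, 1.0,
        )
        b = build_weight_matrix(
            GreensField(gd, tg, "excitation"),
            [GreensField(gs, tg, "detector_adjoint")],
            E, tg, C, 1.0, 1.0,
        )
        assert a[0, 0] == pytest.approx(b[0, 0], rel=1e-12)


class TestNormalizedBorn:
    def _measurements(self, tg, phix_gate, phim_gate):
        P = len(phix_gate)
        T = tg.n_nodes
        phix = np.zeros((P, T))
        phim = np.zeros((P, T))
        phix[:, tg.gate_index] = phix_gate
        phim[:, tg.gate_index] = phim_gate
        return MeasurementSet(
            pairs=[(0, i) for i in range(P)], phix=phix, phim=phim, time_grid=tg
        )

    def test_equal_channels_give_unit_rhs(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        ms = self._measurements(tg, np.array([2.0, 3.0]), np.array([2.0, 3.0]))
        sysm = normalized_born(np.ones((2, 5)), ms)
        assert np.allclose(sysm.rhs, 1.0)

    def test_source_strength_cancels(self, small_phantom):
        out1 = _tiny_forward(small_phantom)
        mesh, props, tg, system, prop, srcs, det_sets, fluor, ms1, gs1 = out1
        # scale source 0's impulse magnitude by 10
        srcs[0].values *= 10.0
        ms2, gs2 = simulate_measurements(
            prop, tg, system.C, props.c, srcs, det_sets, fluor
        )
        W = np.ones((ms1.n_pairs, mesh.n_nodes))
        s1 = normalized_born(W, ms1)
        s2 = normalized_born(W, ms2)
        assert np.allclose(s1.rhs, s2.rhs, rtol=1e-9)

    def test_dead_pair_excluded_others_kept(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        ms = self._measurements(tg, np.array([2.0, 0.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        sysm = normalized_born(np.ones((3, 4)), ms)
        assert sysm.n_rows == 2
        assert sysm.excluded == [(0, 1)]

    def test_all_pairs_dead_raises(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        ms = self._measurements(tg, np.zeros(2), np.ones(2))
        with pytest.raises(DegenerateSystemError):
            normalized_born(np.ones((2, 4)), ms)


class TestNoise:
    def test_zero_level_identity(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        ms = MeasurementSet(
            pairs=[(0, 0)], phix=np.ones((1, tg.n_nodes)),
            phim=np.ones((1, tg.n_nodes)), time_grid=tg,
        )
        out = add_noise(ms, 0.0, seed=1)
        assert np.array_equal(out.phix_gate, ms.phix_gate)
        assert np.array_equal(out.phim_gate, ms.phim_gate)

    def test_fixed_seed_reproducible(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        ms = MeasurementSet(
            pairs=[(0, i) for i in range(8)], phix=np.ones((8, tg.n_nodes)),
            phim=np.ones((8, tg.n_nodes)), time_grid=tg,
        )
        a = add_noise(ms, 0.1, seed=42)
        b = add_noise(ms, 0.1, seed=42)
        assert np.array_equal(a.phim_gate, b.phim_gate)
        assert not np.array_equal(a.phim_gate, ms.phim_gate)

    def test_noise_statistics(self):
        tg = make_time_grid(10.0, 100.0, 100.0)
        n = 10_000
        ms = MeasurementSet(
            pairs=[(0, i) for i in range(n)], phix=np.ones((n, tg.n_nodes)),
            phim=np.ones((n, tg.n_nodes)), time_grid=tg,
        )
        out = add_noise(ms, 0.1, seed=0)
        assert out.phim_gate.mean() == pytest.approx(1.0, abs=0.004)
        assert out.phim_gate.std() == pytest.approx(0.1, abs=0.005)
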