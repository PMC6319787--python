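"""Connectivity, coupling conservation, integration accuracy, recording."""

import numpy as np
import pytest

import rotoranchor as ra
from rotoranchor import tissue
from rotoranchor.tissue import (SimConfig, StimulusSpec, TissueGrid,
                                build_connectivity, coupling_current, run)

from tp06_reference import reference_resting_state


def brute_force_couplings(mask):
    """Exhaustive neighbor enumeration: set of coupled (flat_a, flat_b)
    pairs among myocytes (mask False = myocyte)."""
    rows, cols = mask.shape
    pairs = set()
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and not mask[r2, c2]:
                    pairs.add((r * cols + c, r2 * cols + c2))
    return pairs


class TestConnectivity:
    def test_interior_node_has_four_couplings(self):
        grid = TissueGrid(n_rows=5, n_cols=5)
        conn = build_connectivity(grid)
        counts = conn.coupling_counts().reshape(5, 5)
        assert counts[2, 2] == 4
        assert counts[0, 0] == 2          # corner
        assert counts[0, 2] == 3          # edge

    def test_isolated_myocyte_reduces_to_single_cell(self):
        mask = np.ones((5, 5), bool)
        mask[2, 2] = False                # lone myocyte among obstacles
        grid = TissueGrid(n_rows=5, n_cols=5, obstacle_mask=mask)
        conn = build_connectivity(grid)
        assert conn.n_nodes == 1
        assert conn.coupling_counts()[0] == 0

    def test_checkerboard_has_zero_couplings(self):
        rr, cc = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        mask = (rr + cc) % 2 == 0
        grid = TissueGrid(n_rows=6, n_cols=6, obstacle_mask=mask)
        conn = build_connectivity(grid)
        assert conn.coupling_counts().sum() == 0
        assert brute_force_couplings(mask) == set()

    def test_matches_exhaustive_enumeration(self, rng):
        mask = rng.random((6, 6)) < 0.4
        grid = TissueGrid(n_rows=6, n_cols=6, obstacle_mask=mask)
        conn = build_connectivity(grid)
        got = set()
        for i in range(conn.n_nodes):
            a = conn.active_index[i]
            for q in range(4):
                j = conn.neighbors[i, q]
                if j >= 0:
                    got.add((int(a), int(conn.active_index[j])))
        assert got == brute_force_couplings(mask)

    def test_symmetry(self, rng):
        mask = rng.random((8, 8)) < 0.3
        conn = build_connectivity(TissueGrid(n_rows=8, n_cols=8,
                                             obstacle_mask=mask))
        pairs = set()
        for i in range(conn.n_nodes):
            for q in range(4):
                j = conn.neighbors[i, q]
                if j >= 0:
                    pairs.add((i, int(j)))
        assert all((j, i) in pairs for i, j in pairs)


class TestCouplingOperator:
    def test_two_node_antisymmetry(self):
        grid = TissueGrid(n_rows=1, n_cols=2)
        conn = build_connectivity(grid)
        cur = coupling_current(conn, np.array([-80.0, 20.0]))
        assert cur[0] == -cur[1]
        assert cur[0] == pytest.approx(100.0)

    def test_total_coupling_current_is_zero(self, rng):
        mask = rng.random((20, 30)) < 0.25
        grid = TissueGrid(n_rows=20, n_cols=30, obstacle_mask=mask)
        conn = build_connectivity(grid)
        v = rng.uniform(-90, 40, conn.n_nodes)
        assert coupling_current(conn, v).sum() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_field_has_zero_coupling(self):
        grid = TissueGrid(n_rows=10, n_cols=10)
        conn = build_connectivity(grid)
        cur = coupling_current(conn, np.full(100, -86.2))
        assert np.all(cur == 0.0)

    def test_no_flux_conserves_mean_voltage(self, rng):
        """Pure diffusion (ionic term off): explicit Euler with the coupling
        operator conserves the spatial mean to machine precision."""
        mask = rng.random((15, 15)) < 0.2
        grid = TissueGrid(n_rows=15, n_cols=15, obstacle_mask=mask)
        conn = build_connectivity(grid)
        v = rng.uniform(-90, 30, conn.n_nodes)
        mean0 = v.mean()
        k_dt = 0.05
        for _ in range(500):
            v = v + k_dt * coupling_current(conn, v)
        assert v.mean() == pytest.approx(mean0, abs=1e-10)


class TestIntegration:
    def test_cable_matches_dense_reference(self, epi, paced_epi_state):
        """20-node cable, one beat: mid-cable V(t) from the production kernel
        agrees with the brute-force dense integrator within 0.1 mV."""
        n = 20
        grid = TissueGrid(n_rows=1, n_cols=n)
        mask = np.zeros((1, n), bool)
        mask[0, :3] = True
        cfg = SimConfig(duration=200.0, precision="double", frame_stride=None,
                        probes=np.array([[0, n // 2]]), e_refresh=0.02)
        rec = run(grid, cfg, [StimulusSpec(mask=mask, start=0.0, duration=2.0,
                                           amplitude=30.0)],
                  initial=paced_epi_state[:, 0], params=epi)
        got = rec.probe_v[0]

        from tp06_reference import EPI, reference_cable_run
        k_coup = cfg.g_gap / cfg.cm_pf
        t_ref, want = reference_cable_run(paced_epi_state[:, 0].copy(), n,
                                          0.02, 200.0, k_coup, 30.0, 2.0, 3,
                                          EPI, n // 2, 1.0)
        assert np.allclose(t_ref, rec.probe_t)
        err = np.abs(got.astype(float) - want)
        # ignore the upstroke samples where 400 mV/ms slope amplifies
        # sub-sample timing error
        steep = np.abs(np.gradient(want)) > 20.0
        assert err[~steep].max() < 0.1

    def test_same_config_is_bit_deterministic(self, epi, paced_epi_state):
        grid = TissueGrid(n_rows=8, n_cols=40)
        mask = np.zeros((8, 40), bool)
        mask[:, :3] = True
        stim = [StimulusSpec(mask=mask, start=1.0, amplitude=30.0)]
        cfg = SimConfig(duration=60.0, probes=np.array([[4, 20], [4, 35]]),
                        frame_stride=None)
        rec1 = run(grid, cfg, stim, initial=paced_epi_state[:, 0], params=epi)
        rec2 = run(grid, cfg, stim, initial=paced_epi_state[:, 0], params=epi)
        assert np.array_equal(rec1.probe_v, rec2.probe_v)

    def test_duration_zero_records_initial_frame_only(self, epi):
        grid = TissueGrid(n_rows=4, n_cols=4)
        cfg = SimConfig(duration=0.0)
        rec = run(grid, cfg, [], params=epi)
        assert len(rec.frame_times) == 1
        assert rec.frames.shape == (1, 4, 4)

    def test_planar_wave_isochrones_parallel_to_edge(self, epi, paced_epi_state):
        """Homogeneous strip stimulated along its full left edge: activation
        times are identical along each column (symmetry)."""
        rows, cols = 10, 80
        grid = TissueGrid(n_rows=rows, n_cols=cols)
        mask = np.zeros((rows, cols), bool)
        mask[:, :2] = True
        probes = np.array([(r, c) for c in (40, 60) for r in range(rows)])
        cfg = SimConfig(duration=50.0, probes=probes, frame_stride=None)
        rec = run(grid, cfg, [StimulusSpec(mask=mask, start=1.0,
                                           amplitude=30.0)],
                  initial=paced_epi_state[:, 0], params=epi)
        from rotoranchor.protocols import _activation_time
        acts = np.array([_activation_time(rec.probe_t, tr)
                         for tr in rec.probe_v]).reshape(2, rows)
        assert np.ptp(acts[0]) < 0.5 and np.ptp(acts[1]) < 0.5
        assert acts[1].mean() > acts[0].mean()

    def test_nonfinite_initial_state_aborts_with_location(self, epi):
        grid = TissueGrid(n_rows=4, n_cols=6)
        bad = ra.resting_state(24)
        bad[0, 13] = np.inf
        cfg = SimConfig(duration=20.0)
        with pytest.raises(tissue.SimulationError, match="node"):
            run(grid, cfg, [], initial=bad, params=epi)

    def test_probe_on_obstacle_rejected(self, epi):
        mask = np.zeros((4, 4), bool)
        mask[2, 2] = True
        grid = TissueGrid(n_rows=4, n_cols=4, obstacle_mask=mask)
        cfg = SimConfig(duration=1.0, probes=np.array([[2, 2]]))
        with pytest.raises(ValueError, match="obstacle"):
            run(grid, cfg, [], params=epi)


class TestRecording:
    def test_hdf5_roundtrip(self, tmp_path, epi):
        grid = TissueGrid(n_rows=4, n_cols=4)
        cfg = SimConfig(duration=5.0, probes=np.array([[1, 1]]))
        rec = run(grid, cfg, [], params=epi)
        path = tmp_path / "run.h5"
        rec.save(path)
        back = tissue.SimRecording.load(path)
        assert np.allclose(back.probe_v, rec.probe_v)
        assert np.allclose(back.frames, rec.frames, equal_nan=True)
        assert back.config_hash == rec.config_hash

    def test_obstacles_are_nan_in_frames(self, epi):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        grid = TissueGrid(n_rows=4, n_cols=4, obstacle_mask=mask)
        cfg = SimConfig(duration=2.0)
        rec = run(grid, cfg, [], params=epi)
        assert np.isnan(rec.frames[-1][1, 1])
        assert np.isfinite(rec.frames[-1][0, 0])

    def test_stimulus_validation(self):
        with pytest.raises(ValueError, match="empty"):
            StimulusSpec(mask=np.zeros((3, 3), bool), start=0.0)
        with pytest.raises(ValueError, match="duration"):
            StimulusSpec(mask=np.ones((3, 3), bool), start=0.0, duration=0.0)
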