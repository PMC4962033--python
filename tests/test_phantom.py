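"""Phantom generator: tree construction, RC mechanics, rendering."""

import numpy as np
import pytest

from lungflow4d import (
    Compartment,
    DiseaseConfig,
    VentilationProtocol,
    compartment_flow,
    compartment_volume,
    find_endpoints,
    generate_tree,
    simulate_compartments,
)
from lungflow4d.errors import ConfigurationError, DegenerateTreeError, ParameterError
from lungflow4d.phantom import render_volumes

DOMAIN = ((0.0, 0.0, 0.0), (2560.0, 2560.0, 2560.0))


class TestGenerateTree:
    @pytest.mark.parametrize("n_gen,n_seg,n_eps", [(1, 3, 2), (3, 15, 8)])
    def test_full_binary_counts(self, n_gen, n_seg, n_eps):
        tree = generate_tree(n_gen, domain=DOMAIN, seed=0)
        assert len(tree.segments) == n_seg
        assert len(find_endpoints(tree)) == n_eps

    def test_zero_generations_degenerate(self):
        with pytest.raises(DegenerateTreeError):
            generate_tree(0, domain=DOMAIN, seed=0)

    def test_structure_matches_independent_traversal(self):
        """Endpoint set and parent-daughter links re-derived by a direct
        recursive walk of the stored graph (the oracle) agree with the
        package's accessors."""
        tree = generate_tree(4, domain=DOMAIN, seed=7)

        children = {sid: [] for sid in tree.segments}
        for seg in tree.segments.values():
            if seg.parent is not None:
                children[seg.parent].append(seg.id)

        def walk(sid):
            leaves = []
            kids = children[sid]
            if not kids and tree.segments[sid].parent is not None:
                leaves.append(sid)
            for k in kids:
                leaves.extend(walk(k))
            return leaves

        assert sorted(walk(tree.root)) == sorted(find_endpoints(tree))
        assert len(find_endpoints(tree)) == 2**4
        for seg in tree.segments.values():
            kids = children[seg.id]
            assert len(kids) in (0, 2)  # binary tree
        # every node position inside the domain
        lo, hi = np.array(DOMAIN[0]), np.array(DOMAIN[1])
        for node in tree.nodes.values():
            assert np.all(node.position >= lo) and np.all(node.position <= hi)

    def test_domain_too_small(self):
        with pytest.raises(ConfigurationError):
            generate_tree(4, domain=((0, 0, 0), (2560.0, 2560.0, 400.0)), seed=0)


class TestCompartments:
    def test_tau_is_rc(self):
        c = Compartment(0, R=1.0, C=0.1, obstructed=False,
                        center=np.zeros(3), rest_volume=1.0)
        assert c.tau == pytest.approx(0.1)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ParameterError):
            Compartment(0, R=-1.0, C=0.1, obstructed=False,
                        center=np.zeros(3), rest_volume=1.0)

    def test_square_pressure_wave(self):
        p = VentilationProtocol()
        assert p.airway_pressure(0.05) == 12.0
        assert p.airway_pressure(0.2) == 2.0
        assert p.t_insp + p.t_exp == pytest.approx(p.period)

    def test_steady_state_matches_fine_ode(self):
        """Closed-form periodic cycle vs an explicit fine-step integrator
        run to periodic convergence (independent oracle)."""
        proto = VentilationProtocol()
        c = Compartment(0, R=0.12 / 1.5, C=1.5, obstructed=False,
                        center=np.zeros(3), rest_volume=50.0)
        dt = 1e-5
        t = 0.0
        v = c.rest_volume
        for _ in range(20):  # warm-up cycles
            for _ in range(int(round(proto.period / dt))):
                p_aw = 12.0 if (t % proto.period) < proto.t_insp else 2.0
                v += dt * ((p_aw - 2.0) - (v - c.rest_volume) / c.C) / c.R
                t += dt
        # one more cycle, tracking extremes
        vmin, vmax = v, v
        for _ in range(int(round(proto.period / dt))):
            p_aw = 12.0 if (t % proto.period) < proto.t_insp else 2.0
            v += dt * ((p_aw - 2.0) - (v - c.rest_volume) / c.C) / c.R
            t += dt
            vmin, vmax = min(vmin, v), max(vmax, v)
        tv_ode = vmax - vmin
        times = np.linspace(0, proto.period, 4001)
        vc = compartment_volume(c, proto, times)
        tv_closed = vc.max() - vc.min()
        assert tv_closed == pytest.approx(tv_ode, rel=1e-3)

    def test_periodicity(self):
        proto = VentilationProtocol()
        c = Compartment(0, R=0.08, C=1.5, obstructed=False,
                        center=np.zeros(3), rest_volume=50.0)
        assert compartment_volume(c, proto, 0.0) == pytest.approx(
            float(compartment_volume(c, proto, proto.period - 1e-12)), rel=1e-9)

    def test_obstructed_zero_flow_constant_volume(self):
        proto = VentilationProtocol()
        tree = generate_tree(3, domain=DOMAIN, seed=0)
        sim = simulate_compartments(tree, proto,
                                    DiseaseConfig(blockage_fraction=0.5, seed=3))
        blocked = [i for i, c in enumerate(sim.compartments) if c.obstructed]
        assert blocked, "expected some obstructed endpoints"
        for i in blocked:
            assert np.all(sim.midpoint_flows[i] == 0.0)
            assert np.ptp(sim.frame_volumes[i]) == 0.0

    def test_volume_conservation(self):
        proto = VentilationProtocol()
        tree = generate_tree(3, domain=DOMAIN, seed=1)
        sim = simulate_compartments(tree, proto, DiseaseConfig.healthy(seed=1))
        assert np.allclose(sim.frame_volumes.sum(axis=0), sim.total_frame_volumes())
        # trachea flow truth = discrete derivative of total volume
        tot = sim.total_frame_volumes()
        dtot = (np.roll(tot, -1) - tot) / proto.dt
        assert np.allclose(sim.midpoint_flows.sum(axis=0), dtot)

    def test_tau_population_statistics(self):
        """Drawn tau values reproduce the configured mean/sd within
        standard error at 256 endpoints."""
        proto = VentilationProtocol()
        tree = generate_tree(8, domain=((0, 0, 0), (1e6, 1e6, 1e6)), seed=0)
        dis = DiseaseConfig.healthy(seed=11)
        sim = simulate_compartments(tree, proto, dis)
        n = len(sim.taus)
        assert n == 256
        se_mean = dis.healthy_tau_sd / np.sqrt(n)
        assert abs(sim.taus.mean() - dis.healthy_tau_mean) < 3 * se_mean
        se_sd = dis.healthy_tau_sd / np.sqrt(2 * (n - 1))
        assert abs(sim.taus.std(ddof=1) - dis.healthy_tau_sd) < 3 * se_sd

    def test_diseased_volume_fraction_selection(self):
        proto = VentilationProtocol()
        tree = generate_tree(6, domain=((0, 0, 0), (1e6, 1e6, 1e6)), seed=0)
        sim = simulate_compartments(
            tree, proto, DiseaseConfig(diseased_volume_fraction=0.4,
                                       seed=5))
        rest = np.array([c.rest_volume for c in sim.compartments])
        frac = rest[sim.diseased].sum() / rest.sum()
        assert 0.35 < frac < 0.5  # meets the target, overshoot < one endpoint


class TestRender:
    GRID = (96, 96, 96)
    H = 20.0

    def _tree_sim(self, disease=None):
        m = 6.0 * self.H
        domain = ((m, m, m), (96 * self.H - m,) * 3)
        tree = generate_tree(2, domain=domain, seed=0)
        sim = simulate_compartments(tree, VentilationProtocol(),
                                    disease or DiseaseConfig.healthy(seed=0))
        return tree, sim

    def test_constant_volumes_render_identical_frames(self):
        tree, sim = self._tree_sim(DiseaseConfig(blockage_fraction=1.0, seed=0))
        series, truth = render_volumes(tree, sim, self.GRID, self.H, texture_seed=1)
        for f in range(1, series.n_frames):
            assert np.array_equal(series.data[f], series.data[0])
        pts = truth.centers_vox + [[2.0, 1.0, 0.0]]
        assert np.allclose(truth.displacement_vox(pts, 0), 0.0)

    def test_prescribed_volume_ratio_is_ground_truth_expansion(self, small_phantom):
        tree, sim, series, truth = small_phantom
        f = 2
        exp = truth.interval_expansion(f)
        ratio = sim.frame_volumes[:, f + 1] / sim.frame_volumes[:, f]
        assert np.allclose(exp, ratio - 1.0)

    def test_warp_against_independent_backward_mapping(self, small_phantom):
        """Rendered intensities vs an independent high-resolution backward
        mapping of the reference texture (bisection inversion of the
        radial profile, linear interpolation on an 8x upsampled texture)."""
        from scipy import ndimage as ndi
        from scipy.optimize import brentq

        tree, sim, series, truth = small_phantom
        e, f = 0, 4  # one ball, mid-inflation frame
        lam = truth.scales[e, f]
        c = truth.centers_vox[e]
        R0 = truth.radii_vox[e]
        r1 = R0 * truth.scales[e].max() + 3.0
        fall = 4.0

        def forward(r0):  # independent re-statement of the radial profile
            t = np.clip((r0 - r1) / fall, 0.0, 1.0)
            m = 1.0 + (lam - 1.0) * (1.0 - (t * t * (3 - 2 * t)))
            return r0 * m

        # reference texture == frame at the reference frame index outside
        # the lumen; reconstruct it from the rendered reference frame
        ref = series.data[truth.reference_frame].astype(float)
        zoom = 8
        lo = (c - R0 + 2).astype(int)
        hi = (c + R0 - 2).astype(int)
        block_ref = ref[lo[0] - 4:hi[0] + 5, lo[1] - 4:hi[1] + 5, lo[2] - 4:hi[2] + 5]
        up = ndi.zoom(block_ref, zoom, order=1, grid_mode=False)

        rng = np.random.default_rng(0)
        pts = rng.uniform(lo + 1, hi - 1, size=(200, 3))
        keep = np.linalg.norm(pts - c, axis=1) < R0 - 2  # interior, no rim/lumen
        pts = pts[keep]
        rendered = ndi.map_coordinates(series.data[f].astype(float), pts.T, order=1)
        diffs = []
        for p in pts:
            rho = np.linalg.norm(p - c)
            r0 = brentq(lambda r: forward(r) - rho, 0.0, 2.0 * R0 + fall + 5)
            src = c + (p - c) * (r0 / rho)
            src_up = (src - (lo - 4)) * zoom
            val = ndi.map_coordinates(up, src_up[:, None], order=1)[0]
            diffs.append(rendered[len(diffs)] - val)
        mad = np.mean(np.abs(diffs))
        assert mad < 10.0  # well below the texture sd of 25

    def test_overlapping_compartments_rejected(self):
        tree, _ = self._tree_sim()
        sim = simulate_compartments(tree, VentilationProtocol(),
                                    DiseaseConfig.healthy(seed=0),
                                    rest_volume_mean=2.0)  # huge balls
        with pytest.raises(ConfigurationError):
            render_volumes(tree, sim, self.GRID, self.H, texture_seed=1)

    def test_lumen_is_floodfillable_and_masked_out(self, small_phantom):
        tree, sim, series, truth = small_phantom
        assert truth.lumen_mask.any()
        assert not (truth.lung_mask & truth.lumen_mask).any()
        vals = series.data[0][truth.lumen_mask]
        assert np.all(vals < 50.0)
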