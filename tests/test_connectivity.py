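"""Potential-synapse estimators: closed forms, geometry, consistency."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_morphology
from hypothesis import given, settings
from hypothesis import strategies as st

from mdfconn.connectivity import (CANONICAL_AXES, ConnectivityGrid,
                                  Displacement, SynapseParams,
                                  assign_channels, build_template,
                                  connectivity_map, count_potential_synapses,
                                  interpolate_k, k_kernel, k_template,
                                  k_uniform, segment_pair_distances)
from mdfconn.mdf import CylindricalGrid, _lattice_counts
from mdfconn.morphology import APICAL, AXON, segment_inventory


def uniform_cylinder_grid(value=0.01, R=10, half_height=5, h=1.0):
    nr = int(R / h)
    nz = int(2 * half_height / h)
    _, counts = _lattice_counts(nr, h)
    return CylindricalGrid(np.arange(nr + 1) * h,
                           -half_height + np.arange(nz + 1) * h,
                           np.full((nr, nz), value), counts, 1, h)


class TestDisplacement:
    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            Displacement(-1.0, 0.0)

    def test_from_vector_canonicalizes(self):
        d = Displacement.from_vector(3.0, 4.0, -2.0)
        assert d.rho == pytest.approx(5.0)
        assert d.zeta == -2.0


class TestKUniform:
    def test_closed_form_uniform_cylinders(self):
        """Uniform 0.01 um^-2 fields on the cylinder r<=10, |z|<=5 at zero
        displacement: K = (pi/4) * 2s * rho^2 * V = 0.1 pi^2."""
        g = uniform_cylinder_grid()
        K = k_uniform(g, g, Displacement(0, 0), SynapseParams(2.0, 1.0))
        assert K == pytest.approx(0.1 * np.pi ** 2, rel=0.05)

    def test_disjoint_supports_zero(self):
        g = uniform_cylinder_grid()
        assert k_uniform(g, g, Displacement(30, 0)) == 0.0
        assert k_uniform(g, g, Displacement(0, 200)) == 0.0

    def test_integration_step_stability(self, mdf_pair):
        ga, gd = mdf_pair
        d = Displacement(30, 0)
        k2 = k_uniform(ga, gd, d, SynapseParams(2.0, 4.0))
        k1 = k_uniform(ga, gd, d, SynapseParams(2.0, 2.0))
        assert k2 == pytest.approx(k1, rel=0.01)

    def test_decays_to_zero_far_away(self, mdf_pair):
        ga, gd = mdf_pair
        assert k_uniform(ga, gd, Displacement(2000, 0)) == 0.0


class TestCountPotentialSynapses:
    def _crossing_pair(self):
        m_a = make_morphology([((-5, 0, 0), (5, 0, 0))])
        m_d = make_morphology([((0, 1, -5), (0, 1, 5))], kinds=[APICAL])
        return m_a, m_d

    def test_single_crossing(self):
        m_a, m_d = self._crossing_pair()
        assert count_potential_synapses(m_a, m_d, Displacement(0, 0),
                                        SynapseParams(s=2.0)) == 1

    def test_threshold_excludes(self):
        m_a, m_d = self._crossing_pair()
        assert count_potential_synapses(m_a, m_d, Displacement(0, 0),
                                        SynapseParams(s=0.5)) == 0

    def test_three_disjoint_crossings(self):
        m_a = make_morphology([((-5, 0, 100 * k), (5, 0, 100 * k)) for k in range(3)],
                              parents=[-1, -1, -1])
        m_d = make_morphology([((0, 1, 100 * k - 5), (0, 1, 100 * k + 5))
                               for k in range(3)],
                              kinds=[APICAL] * 3, parents=[-1, -1, -1])
        assert count_potential_synapses(m_a, m_d, Displacement(0, 0),
                                        SynapseParams(s=2.0)) == 3

    def test_contiguous_run_is_one_site_many_pairs(self):
        """An axon chain passing near a dendrite chain is one contact site
        even though several short segment pairs qualify."""
        xs = np.linspace(-4, 4, 9)
        m_a = make_morphology([((x0, 0, 0), (x1, 0, 0))
                               for x0, x1 in zip(xs[:-1], xs[1:])])
        m_d = make_morphology([((0, 1, z0), (0, 1, z1))
                               for z0, z1 in zip(xs[:-1], xs[1:])],
                              kinds=[APICAL] * 8)
        d, p = Displacement(0, 0), SynapseParams(s=2.0)
        assert count_potential_synapses(m_a, m_d, d, p, mode="pairs") > 1
        assert count_potential_synapses(m_a, m_d, d, p, mode="sites") == 1

    def test_displacement_translates_post(self):
        m_a, m_d = self._crossing_pair()
        assert count_potential_synapses(m_a, m_d, Displacement(50, 0),
                                        SynapseParams(s=2.0)) == 0


class TestSegmentDistances:
    def test_known_configurations(self):
        # crossing skew segments
        d = segment_pair_distances([(-5, 0, 0)], [(5, 0, 0)],
                                   [(0, 1, -5)], [(0, 1, 5)])
        assert d[0] == pytest.approx(1.0)
        # parallel offset
        d = segment_pair_distances([(0, 0, 0)], [(10, 0, 0)],
                                   [(0, 3, 0)], [(10, 3, 0)])
        assert d[0] == pytest.approx(3.0)
        # endpoint-to-endpoint
        d = segment_pair_distances([(0, 0, 0)], [(1, 0, 0)],
                                   [(5, 0, 0)], [(9, 0, 0)])
        assert d[0] == pytest.approx(4.0)

    @given(st.lists(st.floats(-10, 10), min_size=12, max_size=12))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_properties_hold_for_arbitrary_segments(self, coords):
        p1, q1, p2, q2 = (np.array(coords[i:i + 3]) for i in (0, 3, 6, 9))
        d = segment_pair_distances([p1], [q1], [p2], [q2])[0]
        # symmetry under swapping the two segments
        d_sym = segment_pair_distances([p2], [q2], [p1], [q1])[0]
        assert d == pytest.approx(d_sym, abs=1e-9)
        # never exceeds any endpoint-to-endpoint distance
        ends = [np.linalg.norm(a - b) for a in (p1, q1) for b in (p2, q2)]
        assert d <= min(ends) + 1e-9
        # lower-bounded by the distance of the enclosing point sets' hulls: 0
        assert d >= 0

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(4)
        p1, q1 = rng.uniform(-5, 5, (2, 40, 3))
        p2, q2 = rng.uniform(-5, 5, (2, 40, 3))
        fast = segment_pair_distances(p1, q1, p2, q2)
        t = np.linspace(0, 1, 201)
        for k in range(40):
            a = p1[k] + t[:, None] * (q1[k] - p1[k])
            b = p2[k] + t[:, None] * (q2[k] - p2[k])
            dense = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min()
            assert fast[k] <= dense + 1e-9
            assert fast[k] == pytest.approx(dense, abs=5e-3)


class TestTemplates:
    def test_all_vertical_segments_in_ez_channel(self):
        m = make_morphology([((3, 4, float(z)), (3, 4, float(z + 2)))
                             for z in range(0, 10, 2)],
                            kinds=[APICAL] * 5)
        t = build_template([m], "dendritic", h=2.0, r_max=20, z_range=(-20, 20))
        masses = t.channel_masses()
        assert masses[0] == pytest.approx(10.0, rel=1e-9)
        assert masses[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_channel_sum_equals_plain_mdf(self, ensemble100, mdf_pair):
        from mdfconn.morphogen import covering_extent, GrowthParams
        ga, _ = mdf_pair
        t = build_template(ensemble100, "axonal", h=2.0,
                           r_max=ga.r_edges[-1],
                           z_range=(ga.z_edges[0], ga.z_edges[-1]))
        rel = np.abs(t.plain().values - ga.values).max() / ga.values.max()
        assert rel < 1e-9

    def test_isotropic_channel_masses_match_voronoi_weights(self):
        """Channel masses of an isotropic-orientation ensemble are
        proportional to the solid-angle Voronoi weights of the 7 axes."""
        from mdfconn.morphogen import grow_ensemble, isotropic_params
        ens = grow_ensemble(isotropic_params(), 60, seed=5)
        t = build_template(ens, "dendritic", h=4.0, r_max=320, z_range=(-320, 320))
        cm = t.channel_masses()
        cm = cm / cm.sum()
        rng = np.random.default_rng(0)
        v = rng.normal(size=(1_000_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        best = np.argmax(np.abs(v @ CANONICAL_AXES.T), axis=1)
        wts = np.bincount(best, minlength=7) / len(v)
        assert np.max(np.abs(cm - wts) / wts) < 0.05

    def test_assign_channels_uses_local_frame(self):
        """A segment along +y at azimuth 90 deg points along the local
        radial axis, not the global equatorial one."""
        mid = np.array([[0.0, 10.0, 0.0]])
        u = np.array([[0.0, 1.0, 0.0]])
        ch = assign_channels(mid, u)
        # local e_rho at azimuth 90deg is +y: channel of the first
        # equatorial axis (index 1)
        assert ch[0] == 1


class TestKTemplate:
    def _template_from(self, m, kind="axonal", h=2.0):
        return build_template([m], kind, h=h, r_max=20, z_range=(-20, 20))

    def test_parallel_vertical_templates_give_zero(self):
        m_a = make_morphology([((1, 1, float(z)), (1, 1, float(z + 2)))
                               for z in range(-4, 4, 2)])
        m_d = make_morphology([((1, 1, float(z)), (1, 1, float(z + 2)))
                               for z in range(-4, 4, 2)], kinds=[APICAL] * 4)
        t_a = self._template_from(m_a, "axonal")
        t_d = self._template_from(m_d, "dendritic")
        K = k_template(t_a, t_d, Displacement(0, 0), SynapseParams(2.0, 1.0))
        assert K == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_matches_uniform_estimator(self):
        """With isotropic orientations the 7-axis estimator reproduces the
        uniform-orientation estimator within 10% (the pi/4 constant
        emerges as the mean |sin| over axis pairs)."""
        from mdfconn.mdf import estimate_mdf
        from mdfconn.morphogen import grow_ensemble, isotropic_params
        ens = grow_ensemble(isotropic_params(), 100, seed=5)
        kw = dict(h=2.0, r_max=320, z_range=(-320, 320))
        ga = estimate_mdf(ens, "axonal", **kw)
        gd = estimate_mdf(ens, "dendritic", **kw)
        ta = build_template(ens, "axonal", **kw)
        td = build_template(ens, "dendritic", **kw)
        for d in (Displacement(30, 0), Displacement(60, 0)):
            ku = k_uniform(ga, gd, d, SynapseParams(2.0, 4.0))
            ko = k_template(ta, td, d, SynapseParams(2.0, 4.0))
            assert ko == pytest.approx(ku, rel=0.10)


class TestKKernel:
    def _inv(self, rows):
        return pd.DataFrame(rows, columns=["x", "y", "z", "length",
                                           "ux", "uy", "uz"])

    def test_closed_form_orthogonal_coincident(self):
        """Unit-length orthogonal segments with coincident midpoints:
        K = 2s * g(0) = 4 (2 pi 2 sigma^2)^{-3/2} at s=2, sigma=10."""
        inv_a = self._inv([[0, 0, 0, 1.0, 1, 0, 0]])
        inv_d = self._inv([[0, 0, 0, 1.0, 0, 1, 0]])
        K = k_kernel(inv_a, inv_d, Displacement(0, 0), SynapseParams(2.0), sigma=10.0)
        assert K == pytest.approx(4.0 * (2 * np.pi * 200) ** -1.5, rel=1e-12)

    def test_parallel_orientations_zero(self):
        inv_a = self._inv([[0, 0, 0, 1.0, 1, 0, 0]])
        inv_d = self._inv([[0, 0, 5, 1.0, 1, 0, 0]])
        assert k_kernel(inv_a, inv_d, Displacement(0, 0), sigma=10.0) == 0.0

    def test_empty_inventory_zero(self):
        inv_a = self._inv([[0, 0, 0, 1.0, 1, 0, 0]])
        empty = self._inv([])
        assert k_kernel(inv_a, empty, Displacement(0, 0), sigma=10.0) == 0.0

    def test_pool_mean_strictly_decreasing_in_sigma(self, ensemble100):
        """Wider kernels dilute the density product: the pooled mean of K_S
        over a neuron pool drops with sigma."""
        d = Displacement(30, 0)
        means = []
        for s in (10.0, 20.0, 30.0):
            ks = []
            for m in ensemble100[:10]:
                inv = segment_inventory(m)
                ks.append(k_kernel(inv[inv["kind"] == "axon"],
                                   inv[inv["kind"] != "axon"], d, sigma=s))
            means.append(np.mean(ks))
        assert means[0] > means[1] > means[2]

    def test_invalid_sigma(self):
        inv = self._inv([[0, 0, 0, 1.0, 1, 0, 0]])
        with pytest.raises(ValueError):
            k_kernel(inv, inv, Displacement(0, 0), sigma=0.0)


class TestConnectivityMapInterpolation:
    @pytest.fixture(scope="class")
    def cmap(self, mdf_pair):
        ga, gd = mdf_pair
        return connectivity_map(ga, gd, [0.0, 30.0, 60.0], [-30.0, 0.0, 30.0],
                                SynapseParams(2.0, 4.0))

    def test_lattice_point_exact(self, cmap):
        assert interpolate_k(cmap, Displacement(30, 0)) == cmap.K[1, 1]

    def test_midpoint_is_mean(self, cmap):
        v = interpolate_k(cmap, Displacement(45, 0))
        assert v == pytest.approx(0.5 * (cmap.K[1, 1] + cmap.K[2, 1]))

    def test_outside_hull_zero(self, cmap):
        assert interpolate_k(cmap, Displacement(500, 0)) == 0.0

    def test_negative_rho_error(self, cmap):
        from mdfconn.connectivity import interpolate_k_many
        with pytest.raises(ValueError):
            interpolate_k_many(cmap, np.array([-1.0]), np.array([0.0]))

    def test_radial_decay(self, cmap):
        """K decreases with horizontal displacement away from the soma."""
        row = cmap.K[:, 1]
        assert row[1] >= row[2]

    def test_roundtrip_frame(self, cmap):
        back = ConnectivityGrid.from_frame(cmap.to_frame())
        assert np.allclose(back.K, cmap.K)


class TestTemplateIO:
    def test_hdf5_roundtrip(self, tmp_path):
        from mdfconn.connectivity import load_template, save_template
        m = make_morphology([((3, 4, float(z)), (3, 4, float(z + 2)))
                             for z in range(0, 10, 2)],
                            kinds=[APICAL] * 5)
        t = build_template([m], "dendritic", h=2.0, r_max=20, z_range=(-20, 20))
        path = tmp_path / "t.h5"
        save_template(t, path)
        back = load_template(path)
        assert np.array_equal(back.values, t.values)
        assert back.n_neurons == t.n_neurons
        assert back.h == t.h
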