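import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mcgpath import forcefield as ff
from mcgpath.structures import CaTrace
from mcgpath import toybuilder

from conftest import random_rotation

PARAMS = ff.DEFAULT_PARAMS


class TestAngleStiffness:
    # frozen by direct evaluation of k = [B·(sin(βθ)/(βθ))² + k0]/sin²θ
    @pytest.mark.parametrize("theta0_deg, expected", [
        (np.degrees(np.pi / 1.667), 11.0530),   # sinc zero: k0/sin²θ0
        (90.0, 119.1848),
        (120.0, 51.8669),
    ])
    def test_frozen_values(self, theta0_deg, expected):
        k = ff.angle_stiffness(np.radians(theta0_deg))
        assert k == pytest.approx(expected, rel=1e-4)

    def test_helix_stiffer_than_strand(self):
        # the damped-sinc law makes helices (θ0 ~ 90°) stiffer than strands
        assert ff.angle_stiffness(np.radians(90)) > \
            2 * ff.angle_stiffness(np.radians(115))

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            k = ff.angle_stiffness(np.radians(2.0))
        assert np.isfinite(k) and k > 0

    def test_always_positive(self):
        thetas = np.radians(np.linspace(5, 175, 200))
        assert all(ff.angle_stiffness(t) > 0 for t in thetas)


class TestDihedralAmplitude:
    @pytest.mark.parametrize("phi0_deg, expected", [
        (50.0, 25.0),      # helical regime
        (120.0, 5.0),      # strand regime
        (80.0, 25.0),      # boundary included
        (-50.0, 25.0),     # absolute-value convention
        (-120.0, 5.0),
    ])
    def test_rule(self, phi0_deg, expected):
        assert ff.dihedral_amplitude(np.radians(phi0_deg)) == expected


class TestLocalMorseParams:
    # frozen by direct evaluation of ε = 3.8·e^{−(r0/6.1)⁸}+0.05 etc.
    @pytest.mark.parametrize("r0, eps, alpha", [
        (3.8, 3.76479, 2.85067),
        (8.4, 0.05001, 0.70001),
        (1e-9, 3.85, 2.90),
    ])
    def test_frozen_values(self, r0, eps, alpha):
        e, a = ff.local_morse_params(r0)
        assert e == pytest.approx(eps, abs=2e-5)
        assert a == pytest.approx(alpha, abs=2e-5)

    def test_nonlocal_distance_rejected(self):
        with pytest.raises(ValueError, match="non-local"):
            ff.local_morse_params(8.5)

    def test_monotone_decay_with_floors(self):
        r = np.linspace(0.1, 8.49, 300)
        pairs = [ff.local_morse_params(x) for x in r]
        eps = np.array([p[0] for p in pairs])
        alpha = np.array([p[1] for p in pairs])
        assert np.all(np.diff(eps) <= 0) and np.all(np.diff(alpha) <= 0)
        assert np.all(eps >= PARAMS.local_eps_floor)
        assert np.all(alpha >= PARAMS.local_alpha_floor)


def _random_trace(rng, n):
    """Self-avoiding-ish random chain with physical bond lengths."""
    x = np.zeros((n, 3))
    d = rng.uniform(3.6, 4.0, n - 1)
    step = rng.standard_normal((n - 1, 3))
    step /= np.linalg.norm(step, axis=1)[:, None]
    # limit sharp turns so consecutive beads don't fold onto each other
    for i in range(1, n - 1):
        if np.dot(step[i], step[i - 1]) < -0.3:
            step[i] = -step[i]
    x[1:] = np.cumsum(step * d[:, None], axis=0)
    return CaTrace(list(range(1, n + 1)), ["ALA"] * n, x)


class TestBuildTopology:
    def test_helix_term_counts(self, helix30_topology):
        t = helix30_topology
        assert len(t.bond_d0) == 29
        assert len(t.ang_k) == 28
        assert len(t.dih_amp) == 27
        # all (i, i+4) helix contacts (≈ 6.2 Å) are local pairs
        i4 = {(i, i + 4) for i in range(26)}
        assert i4 <= {tuple(p) for p in t.loc_idx}

    def test_straight_rod_pairs_nonlocal(self):
        # near-straight rod: a tiny alternating zig keeps dihedrals defined
        x = np.arange(8)[:, None] * np.array([3.8, 0, 0.0])
        x[::2, 1] = 0.01
        t = ff.build_topology(CaTrace(list(range(1, 9)), ["ALA"] * 8, x))
        pairs = {tuple(p) for p in t.bond_idx}
        assert (0, 4) not in pairs            # not a bonded term
        assert (0, 4) in {tuple(p) for p in t.nl_idx}  # 15.2 Å → non-local
        assert len(t.loc_idx) == 0

    def test_partition_property_on_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(8, 25))
            t = ff.build_topology(_random_trace(rng, n))
            expected = n * (n - 1) // 2 - (3 * n - 6)  # pairs with |i−j| > 3
            loc = {tuple(p) for p in t.loc_idx}
            nl = {tuple(p) for p in t.nl_idx}
            assert len(loc) + len(nl) == expected
            assert not loc & nl
            assert all(j - i > 3 for i, j in loc | nl)
            assert np.all(t.loc_r0 < PARAMS.r_cut)

    def test_rigid_motion_gives_identical_topology(self, helix30):
        rng = np.random.default_rng(5)
        t0 = ff.build_topology(helix30)
        moved = helix30.with_coords(
            helix30.coords @ random_rotation(rng).T + rng.uniform(-9, 9, 3))
        t1 = ff.build_topology(moved)
        np.testing.assert_allclose(t0.bond_d0, t1.bond_d0, atol=1e-9)
        np.testing.assert_allclose(t0.ang_theta0, t1.ang_theta0, atol=1e-9)
        np.testing.assert_allclose(t0.dih_phi0, t1.dih_phi0, atol=1e-9)
        np.testing.assert_allclose(t0.loc_r0, t1.loc_r0, atol=1e-9)
        assert np.array_equal(t0.nl_idx, t1.nl_idx)

    def test_json_round_trip(self, helix30_topology, tmp_path):
        p = tmp_path / "topo.json"
        helix30_topology.to_json(p)
        back = ff.BiasedTopology.from_json(p)
        np.testing.assert_allclose(back.ang_k, helix30_topology.ang_k)
        np.testing.assert_allclose(back.loc_eps, helix30_topology.loc_eps)
        assert np.array_equal(back.nl_idx, helix30_topology.nl_idx)


def _single_nonlocal_pair_topology() -> ff.BiasedTopology:
    """Minimal two-bead topology carrying one generic non-local pair."""
    z2 = np.zeros((0, 2), dtype=np.int64)
    return ff.BiasedTopology(
        bond_idx=z2, bond_d0=np.zeros(0),
        ang_idx=np.zeros((0, 3), dtype=np.int64), ang_theta0=np.zeros(0),
        ang_k=np.zeros(0),
        dih_idx=np.zeros((0, 4), dtype=np.int64), dih_phi0=np.zeros(0),
        dih_amp=np.zeros(0),
        loc_idx=z2, loc_r0=np.zeros(0), loc_eps=np.zeros(0),
        loc_alpha=np.zeros(0),
        nl_idx=np.array([[0, 1]], dtype=np.int64), n_beads=2)


class TestEnergy:
    def test_reference_is_minimum_of_biased_terms(self, helix30,
                                                  helix30_topology):
        e = ff.energy(helix30.coords, helix30_topology)
        assert e["angle"] == pytest.approx(0.0, abs=1e-10)
        assert e["dihedral"] == pytest.approx(0.0, abs=1e-10)
        assert e["local"] == pytest.approx(-helix30_topology.loc_eps.sum(),
                                           abs=1e-9)
        assert e["bond_penalty"] == 0.0

    def test_nonlocal_pair_at_equilibrium(self):
        # generic well: depth 0.05 kcal/mol at 9.5 Å
        t = _single_nonlocal_pair_topology()
        x = np.array([[0, 0, 0], [9.5, 0, 0.0]])
        assert ff.energy(x, t)["nonlocal"] == pytest.approx(-0.05, abs=1e-5)
        far = np.array([[0, 0, 0], [80.0, 0, 0.0]])
        assert ff.energy(far, t)["nonlocal"] == 0.0  # beyond the eval cutoff

    def test_morse_dissociation_limit(self):
        r = np.linspace(20, 200, 50)
        u = ff.morse(r, PARAMS.nl_eps, PARAMS.nl_alpha, PARAMS.nl_r0)
        assert abs(u[-1]) < 1e-12
        assert np.all(np.abs(u) < 1e-3)

    def test_each_local_pair_minimum(self, helix30_topology):
        t = helix30_topology
        for r0, eps, alpha in zip(t.loc_r0, t.loc_eps, t.loc_alpha):
            res = minimize_scalar(lambda r: ff.morse(r, eps, alpha, r0),
                                  bounds=(0.5, 20.0), method="bounded")
            assert res.x == pytest.approx(r0, abs=1e-4)
            assert res.fun == pytest.approx(-eps, abs=1e-9)

    def test_rigid_motion_invariance(self, helix30, helix30_topology):
        rng = np.random.default_rng(13)
        x = helix30.coords + rng.normal(0, 0.2, helix30.coords.shape)
        e0 = ff.energy(x, helix30_topology)["total"]
        for _ in range(10):
            moved = x @ random_rotation(rng).T + rng.uniform(-30, 30, 3)
            assert ff.energy(moved, helix30_topology)["total"] == \
                pytest.approx(e0, abs=1e-9)

    def test_overlap_error_names_pair(self, helix30, helix30_topology):
        x = helix30.coords.copy()
        x[10] = x[20] + 0.01
        with pytest.raises(ValueError, match="overlap"):
            ff.energy(x, helix30_topology)

    def test_shape_mismatch_rejected(self, helix30_topology):
        with pytest.raises(ValueError, match="shape"):
            ff.energy(np.zeros((5, 3)), helix30_topology)


class TestForces:
    def test_finite_difference_agreement(self, helix30, helix30_topology):
        """−∇U matches central differences on 50 random conformations."""
        rng = np.random.default_rng(42)
        x0 = helix30.coords[:20]
        topo = ff.build_topology(
            CaTrace(list(range(1, 21)), ["ALA"] * 20, x0))
        h = 1e-5
        for _ in range(50):
            x = x0 + rng.normal(0, 0.25, x0.shape)
            F = ff.forces(x, topo, bond_k=100.0)
            fnum = np.zeros_like(F)
            for a in range(x.shape[0]):
                for c in range(3):
                    xp = x.copy()
                    xp[a, c] += h
                    ep = ff.energy(xp, topo, bond_k=100.0)["total"]
                    xp[a, c] -= 2 * h
                    em = ff.energy(xp, topo, bond_k=100.0)["total"]
                    fnum[a, c] = -(ep - em) / (2 * h)
            scale = max(np.abs(fnum).max(), 1.0)
            assert np.abs(F - fnum).max() / scale <= 1e-5

    def test_zero_force_at_reference_per_term(self, helix30, helix30_topology):
        for term in ("angles", "dihedrals", "local"):
            F = ff.forces(helix30.coords, helix30_topology.only(term))
            assert np.abs(F).max() <= 1e-8

    def test_net_force_and_torque_vanish(self, helix30, helix30_topology):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = helix30.coords + rng.normal(0, 0.4, helix30.coords.shape)
            F = ff.forces(x, helix30_topology, bond_k=100.0)
            assert np.abs(F.sum(axis=0)).max() <= 1e-8
            assert np.abs(np.cross(x, F).sum(axis=0)).max() <= 1e-8
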