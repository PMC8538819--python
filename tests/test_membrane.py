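"""Tests for the coarse-grained membrane model and the SMD pulling engine."""

import numpy as np
import pytest

from mnpsteer import membrane as mb
from mnpsteer.membrane import (
    ACC,
    COULOMB_K,
    ForceDisplacementCurve,
    ForceFieldParams,
    MembraneModel,
    SMDConfig,
    SMDInstabilityError,
    aufdc,
    bonded_forces,
    build_aggregate,
    build_membrane,
    build_particle,
    kcal_per_mol_per_A_to_N,
    lost_atom_fraction,
    membrane_nonbonded,
    nonbonded_forces,
    particle_membrane_forces,
    relax,
    smd_pull,
)


def two_bead_model(r, eps=0.35, sigma=4.6, q1=0.0, q2=0.0):
    """Minimal hand-built membrane of two unbonded beads at distance r."""
    p = ForceFieldParams()
    pos = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    empty = np.zeros((0, 2), dtype=int)
    return MembraneModel(
        positions=pos,
        types=np.array(["T", "T"]),
        bonds=np.zeros((0, 2), dtype=int),
        angles=np.zeros((0, 3), dtype=int),
        dihedrals=np.zeros((0, 4), dtype=int),
        impropers=np.zeros((0, 4), dtype=int),
        params=p,
        lateral_size=(20.0, 20.0),
        masses=np.array([80.0, 80.0]),
        charges=np.array([q1, q2]),
        eps=np.array([eps, eps]),
        sigma=np.array([sigma, sigma]),
        anchor_idx=np.zeros(0, dtype=int),
        anchor_ref=np.zeros((0, 3)),
    )


class TestBuildMembrane:
    def test_topology_bookkeeping(self):
        m = build_membrane(2, 2, seed=0)
        n_lipids = 2 * 2 * 2
        assert m.n_beads == n_lipids * 4
        assert m.bonds.shape[0] == n_lipids * 3
        assert m.angles.shape[0] == n_lipids * 2
        assert m.dihedrals.shape[0] == n_lipids
        assert m.impropers.shape[0] == n_lipids

    def test_deterministic_per_seed(self):
        a = build_membrane(3, 3, seed=5)
        b = build_membrane(3, 3, seed=5)
        c = build_membrane(3, 3, seed=6)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_leaflets_mirrored_heads_outward(self):
        m = build_membrane(3, 3, seed=0, jitter=0.0)
        heads = m.positions[m.types == "H"][:, 2]
        tails = m.positions[m.types == "T"][:, 2]
        assert np.abs(heads).min() > np.abs(tails).max()

    def test_relaxed_membrane_interior_forces_vanish(self):
        m = build_membrane(4, 4, seed=0, jitter=0.2)
        mr = relax(m, maxiter=600)
        fb, _ = bonded_forces(mr)
        fn, _ = membrane_nonbonded(mr)
        fa, _ = mb._anchor_forces(mr)
        ftot = fb + fn + fa
        typical_bond_force = 2.0 * m.params.kb * m.params.b0
        assert np.abs(ftot).max() < 1e-4 * typical_bond_force

    def test_invalid_params_rejected(self):
        p = ForceFieldParams(kb=-1.0)
        with pytest.raises(ValueError):
            build_membrane(2, 2, params=p)
        with pytest.raises(ValueError):
            build_membrane(1, 2)


class TestBondedForces:
    def test_equilibrium_geometry_zero_force(self):
        p = ForceFieldParams(kphi=0.0)
        m = build_membrane(2, 2, params=p, seed=0, jitter=0.0)
        f, e = bonded_forces(m)
        assert np.abs(f).max() < 1e-10
        # improper/angle/bond all at their minima; only the dihedral was
        # switched off
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_restoring_force(self):
        p = ForceFieldParams()
        delta = 0.3
        m = two_bead_model(p.b0 + delta)
        m.bonds = np.array([[0, 1]])
        f, e = bonded_forces(m)
        assert e == pytest.approx(p.kb * delta**2)
        assert f[0, 0] == pytest.approx(2.0 * p.kb * delta)
        assert f[1, 0] == pytest.approx(-2.0 * p.kb * delta)

    def test_matches_finite_difference_gradient(self, rng):
        m = build_membrane(3, 3, seed=1, jitter=0.4)
        m.positions = m.positions + rng.normal(0, 0.25, m.positions.shape)
        f, _ = bonded_forces(m)
        h = 1e-5
        worst = 0.0
        for _ in range(60):
            k = int(rng.integers(m.n_beads))
            a = int(rng.integers(3))
            up = m.copy()
            up.positions[k, a] += h
            dn = m.copy()
            dn.positions[k, a] -= h
            fd = -(bonded_forces(up)[1] - bonded_forces(dn)[1]) / (2 * h)
            if abs(fd) > 1e-3:
                worst = max(worst, abs(fd - f[k, a]) / abs(fd))
        assert worst < 1e-6

    def test_degenerate_geometry_rejected(self):
        m = two_bead_model(1e-12)
        m.bonds = np.array([[0, 1]])
        with pytest.raises(ValueError):
            bonded_forces(m)


class TestNonbonded:
    def test_lj_root_and_minimum(self):
        eps, sigma = 0.35, 4.6
        m0 = two_bead_model(sigma, eps=eps, sigma=sigma)
        _, e0 = membrane_nonbonded(m0)
        assert e0 == pytest.approx(0.0, abs=1e-12)
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        m1 = two_bead_model(rmin, eps=eps, sigma=sigma)
        f1, e1 = membrane_nonbonded(m1)
        assert e1 == pytest.approx(-eps, rel=1e-12)
        assert np.abs(f1).max() < 1e-12

    def test_switching_window_continuity(self):
        eps, sigma = 0.35, 4.6
        # energy vanishes beyond the outer cutoff and decays smoothly
        _, e_beyond = membrane_nonbonded(two_bead_model(12.5, eps, sigma))
        assert e_beyond == 0.0
        h = 1e-6
        for edge in (10.0, 12.0):
            _, e_lo = membrane_nonbonded(two_bead_model(edge - h, eps, sigma))
            _, e_hi = membrane_nonbonded(two_bead_model(edge + h, eps, sigma))
            assert abs(e_lo - e_hi) < 1e-4

    def test_switched_force_is_energy_gradient(self):
        eps, sigma = 0.35, 4.6
        h = 1e-6
        for r in (8.0, 10.5, 11.5):
            f, _ = membrane_nonbonded(two_bead_model(r, eps, sigma))
            _, ep = membrane_nonbonded(two_bead_model(r + h, eps, sigma))
            _, em = membrane_nonbonded(two_bead_model(r - h, eps, sigma))
            fd = -(ep - em) / (2 * h)  # force on bead 1 along +x
            assert f[1, 0] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_bonded_pairs_excluded(self):
        m = two_bead_model(5.0)
        _, e_excl = membrane_nonbonded(m)
        assert e_excl != 0.0
        m.bonds = np.array([[0, 1]])
        if hasattr(m, "_excl"):
            del m._excl
        _, e_with_bond = membrane_nonbonded(m)
        assert e_with_bond == 0.0

    def test_coulomb_hand_formula(self):
        # zero the LJ wells so only electrostatics remain
        r = 8.0
        m = two_bead_model(r, eps=0.0, q1=-0.2, q2=0.0)
        m.charges = np.array([-0.2, 0.0])
        part = build_particle(3.5)
        part.site_eps[:] = 0.0
        part.position = np.array([-10.0, 0.0, 0.0])
        fs, fb, e = particle_membrane_forces(m, part, cutoff=1e4)
        expected = sum(
            COULOMB_K * q * (-0.2) / np.linalg.norm(s - m.positions[0])
            + COULOMB_K * q * 0.0
            for s, q in zip(part.world_sites(), part.site_charges)
        )
        assert e == pytest.approx(expected, rel=1e-10)

    def test_nonbonded_forces_combined_interface(self):
        m = build_membrane(2, 2, seed=0)
        part = build_particle(5.0)
        part.position = np.array([0.0, 0.0, m.z_range()[1] + 8.0])
        f_beads, f_sites, e = nonbonded_forces(m, part, SMDConfig())
        assert f_beads.shape == m.positions.shape
        assert f_sites.shape == (part.n_sites, 3)
        assert np.isfinite(e)

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError):
            membrane_nonbonded(two_bead_model(1e-8))


class TestRigidParticle:
    def test_sites_on_sphere_and_neutral(self):
        part = build_particle(5.0)
        radii = np.linalg.norm(part.body_sites, axis=1)
        assert np.allclose(radii, 5.0)
        assert part.n_sites % 7 == 0
        assert part.site_charges.sum() == pytest.approx(0.0, abs=1e-12)

    def test_charge_cycle_uses_fixture_values(self):
        import csv
        from importlib import resources

        path = resources.files("mnpsteer.data").joinpath("fe3o4_charges.csv")
        with path.open() as fh:
            table = {row["atom"]: float(row["q_e"]) for row in csv.DictReader(fh)}
        part = build_particle(5.0)
        got = set(np.round(np.unique(part.site_charges), 6))
        assert got == {table["Fe_tetrahedral"], table["Fe_octahedral"], table["O"]}

    def test_aggregate_geometry(self):
        r = 5.0
        orth = build_aggregate(r, "orthogonal")
        par = build_aggregate(r, "parallel")
        single = build_particle(r)
        assert orth.axial_extent([0, 0, 1]) == pytest.approx(4 * r)
        assert par.axial_extent([0, 0, 1]) == pytest.approx(2 * r)
        assert orth.n_sites == 2 * single.n_sites

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_particle(-1.0)
        with pytest.raises(ValueError):
            build_aggregate(5.0, "diagonal")


class TestSMDPull:
    def test_free_pulling_records_zero_membrane_force(self):
        part = build_particle(5.0)
        cfg = SMDConfig(velocity=0.05, dt=2.0, max_steps=5000)
        res = smd_pull(None, part, cfg, seed=0)
        assert np.all(res.curve.force == 0.0)
        assert aufdc(res.curve) == 0.0

    def test_deterministic_per_seed(self):
        mem = build_membrane(4, 4, seed=0)
        part = build_particle(4.0)
        cfg = SMDConfig(velocity=0.05, dt=2.0, gamma=0.05, equil_steps=50)
        r1 = smd_pull(mem, part, cfg, seed=3)
        r2 = smd_pull(mem, part, cfg, seed=3)
        assert np.array_equal(r1.curve.force, r2.curve.force)
        assert np.array_equal(r1.curve.displacement, r2.curve.displacement)
        r3 = smd_pull(mem, part, cfg, seed=4)
        assert not np.array_equal(r1.curve.force, r3.curve.force)

    def test_instability_reported(self):
        mem = build_membrane(4, 4, seed=0)
        part = build_particle(5.0)
        cfg = SMDConfig(velocity=0.05, dt=80.0, gamma=0.001, equil_steps=0)
        with pytest.raises(SMDInstabilityError):
            smd_pull(mem, part, cfg, seed=0)

    def test_crossing_produces_resistance_work(self):
        mem = build_membrane(5, 5, seed=0)
        part = build_particle(5.0)
        cfg = SMDConfig(velocity=0.05, dt=2.0, gamma=0.05, equil_steps=100)
        res = smd_pull(mem, part, cfg, seed=0)
        assert aufdc(res.curve) > 0.0
        assert res.curve.displacement[0] > 0
        assert np.all(np.diff(res.curve.displacement) > 0)
        # particle ended below the far leaflet
        assert res.particle.position[2] < res.membrane_before.z_range()[0]


class TestAUFDC:
    def test_rectangle(self):
        c = ForceDisplacementCurve(np.array([0.0, 4.0]), np.array([2.5, 2.5]))
        assert aufdc(c) == pytest.approx(10.0)

    def test_triangle(self):
        c = ForceDisplacementCurve(np.array([0.0, 6.0]), np.array([0.0, 3.0]))
        assert aufdc(c) == pytest.approx(9.0)

    def test_matches_fine_riemann_oracle(self, rng):
        x = np.sort(rng.uniform(0, 50, 40))
        x[0], x[-1] = 0.0, 50.0
        y = rng.normal(0, 5, 40)
        c = ForceDisplacementCurve(x, y)
        # midpoint Riemann sum subdivided within each linear segment
        # (midpoint rule integrates a linear function exactly)
        riemann = 0.0
        for k in range(x.size - 1):
            xs = np.linspace(x[k], x[k + 1], 101)
            mid = 0.5 * (xs[1:] + xs[:-1])
            riemann += float(np.sum(np.interp(mid, x, y) * np.diff(xs)))
        assert aufdc(c) == pytest.approx(riemann, rel=1e-10, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            aufdc(ForceDisplacementCurve(np.array([1.0]), np.array([1.0])))

    def test_curve_csv_round_trip(self, tmp_path):
        c = ForceDisplacementCurve(np.array([0.0, 1.5, 3.0]), np.array([0.1, -0.2, 0.5]))
        path = tmp_path / "curve.csv"
        c.to_csv(path)
        back = ForceDisplacementCurve.from_csv(path)
        assert np.array_equal(back.displacement, c.displacement)
        assert np.array_equal(back.force, c.force)

    def test_non_monotone_displacement_rejected(self):
        with pytest.raises(ValueError):
            ForceDisplacementCurve(np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestLostAtoms:
    def test_identical_states_zero(self):
        m = build_membrane(3, 3, seed=0)
        assert lost_atom_fraction(m, m.copy()) == 0.0

    def test_counting_single_and_multiple(self):
        before = build_membrane(5, 5, seed=0)  # 100 lipids won't divide: 50 -> use beads
        after = before.copy()
        n = before.n_beads  # 200 beads for 5x5x2 lipids
        after.positions[0, 2] += 100.0
        assert lost_atom_fraction(before, after) == pytest.approx(1.0 / n)
        after.positions[1, 2] -= 100.0
        after.positions[2, 2] += 100.0
        assert lost_atom_fraction(before, after) == pytest.approx(3.0 / n)

    def test_topology_mismatch_rejected(self):
        a = build_membrane(2, 2, seed=0)
        b = build_membrane(3, 3, seed=0)
        with pytest.raises(ValueError):
            lost_atom_fraction(a, b)


class TestUnits:
    def test_force_conversion_round_number(self):
        # 1 kcal/mol/A ~ 69.5 pN
        assert kcal_per_mol_per_A_to_N(1.0) == pytest.approx(6.95e-11, rel=1e-3)

    def test_acceleration_constant_consistent(self):
        # ACC must equal (kcal/mol in J) / (g/mol in kg) scaled to A/fs^2
        joules = 4184.0 / 6.02214076e23
        kg = 1e-3 / 6.02214076e23
        a_si = (joules / 1e-10) / kg  # m/s^2 for F=1, m=1
        assert ACC == pytest.approx(a_si * 1e-20, rel=1e-6)
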