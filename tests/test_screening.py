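"""Conductor matrix assembly, Born-ion oracles, solver and scaling rules."""

import numpy as np
import pytest

from cosmosol.cavity import Segment, Sphere, build_vdw_cavity
from cosmosol.constants import BOHR_PER_ANGSTROM
from cosmosol.screening import (
    DENSE_SOLVER_LIMIT,
    ScreenOption,
    apply_scaling,
    build_A_ks,
    build_A_yk,
    calibrate_yk,
    scale_factor,
    select_solver,
    solve_screening,
    yk_exponents,
)
from cosmosol.solute import Nucleus, SoluteModel, nuclear_potential


def _two_segments(distance_angstrom=1.0, area_angstrom2=0.5):
    n = np.array([0.0, 0.0, 1.0])
    return [
        Segment(np.zeros(3), area_angstrom2, n, 0),
        Segment(np.array([distance_angstrom, 0, 0]), area_angstrom2, n, 0),
    ]


def born_energy(radius_angstrom, charge, method, level="fine"):
    """Full-pipeline Born dielectric energy at ideal screening."""
    cav = build_vdw_cavity([Sphere(np.zeros(3), radius_angstrom, 0)], level)
    solute = SoluteModel(nuclei=[Nucleus([0.0, 0.0, 0.0], charge)])
    phi = nuclear_potential(solute, cav.centers)
    if method == "ks":
        A = build_A_ks(cav.segments)
    else:
        A = build_A_yk(cav.segments, yk_exponents(cav.segments, calibrate_yk(level)))
    q = solve_screening(A, phi, method="dense").q
    return 0.5 * float(phi @ q)


class TestMatrixKS:
    def test_two_segment_entries(self):
        segs = _two_segments()
        A = build_A_ks(segs).A
        s_bohr = 0.5 * BOHR_PER_ANGSTROM**2
        d_bohr = 1.0 * BOHR_PER_ANGSTROM
        diag = 1.07 * np.sqrt(4 * np.pi / s_bohr)
        assert A[0, 0] == pytest.approx(diag, rel=1e-12)
        assert A[1, 1] == pytest.approx(diag, rel=1e-12)
        assert A[0, 1] == pytest.approx(1.0 / d_bohr, rel=1e-12)

    def test_symmetry(self, rng):
        segs = [
            Segment(rng.uniform(0, 3, 3), rng.uniform(0.1, 0.4), np.array([0, 0, 1.0]), 0)
            for _ in range(20)
        ]
        A = build_A_ks(segs).A
        assert np.array_equal(A, A.T)

    def test_coincident_centers_point_to_merging(self):
        segs = [
            Segment(np.zeros(3), 0.2, np.array([0, 0, 1.0]), 0),
            Segment(np.zeros(3), 0.3, np.array([0, 0, 1.0]), 0),
        ]
        with pytest.raises(ValueError, match="merg"):
            build_A_ks(segs)


class TestMatrixYK:
    def test_large_exponents_recover_point_charges(self):
        segs = _two_segments()
        A_ks = build_A_ks(segs).A
        A_yk = build_A_yk(segs, np.array([1e5, 1e5])).A
        assert A_yk[0, 1] == pytest.approx(A_ks[0, 1], rel=1e-10)

    def test_coincident_segments_stay_finite(self):
        segs = [
            Segment(np.zeros(3), 0.2, np.array([0, 0, 1.0]), 0),
            Segment(np.zeros(3), 0.3, np.array([0, 0, 1.0]), 0),
        ]
        A = build_A_yk(segs, np.array([2.0, 3.0])).A
        assert np.all(np.isfinite(A))
        zij = 2.0 * 3.0 / np.sqrt(4.0 + 9.0)
        assert A[0, 1] == pytest.approx(2 * zij / np.sqrt(np.pi), rel=1e-12)


class TestYKCalibration:
    def test_born_energy_exact_after_calibration(self):
        for level in ("coarse", "fine"):
            e = born_energy(1.0, 1.0, "yk", level)
            exact = -0.5 / (1.0 * BOHR_PER_ANGSTROM)
            assert abs(e / exact - 1.0) < 1e-8

    def test_scale_invariance(self):
        # calibrated on the unit sphere, applied at R = 3 Å
        e = born_energy(3.0, 1.0, "yk")
        exact = -0.5 / (3.0 * BOHR_PER_ANGSTROM)
        assert abs(e / exact - 1.0) < 1e-6

    def test_level_constants_distinct_and_finite(self):
        zc, zf = calibrate_yk("coarse"), calibrate_yk("fine")
        assert zc != zf
        assert 0 < zc < np.inf and 0 < zf < np.inf


class TestSolver:
    def test_one_by_one(self):
        q = solve_screening(np.array([[4.0]]), np.array([2.0]), "dense").q
        assert q[0] == pytest.approx(-0.5, rel=1e-12)

    def test_dense_and_iterative_agree(self, rng):
        B = rng.normal(size=(50, 50))
        A = B @ B.T + 50 * np.eye(50)
        phi = rng.normal(size=50)
        qd = solve_screening(A, phi, "dense").q
        qi = solve_screening(A, phi, "iterative").q
        assert np.max(np.abs(qd - qi)) < 1e-8 * np.max(np.abs(qd))

    def test_auto_switchover_rule(self):
        assert select_solver(DENSE_SOLVER_LIMIT, "auto") == "dense"
        assert select_solver(DENSE_SOLVER_LIMIT + 1, "auto") == "iterative"
        assert select_solver(10, "dense") == "dense"
        with pytest.raises(ValueError):
            select_solver(10, "sparse")

    def test_linearity(self, rng):
        B = rng.normal(size=(30, 30))
        A = B @ B.T + 30 * np.eye(30)
        p1, p2 = rng.normal(size=30), rng.normal(size=30)
        q1 = solve_screening(A, p1, "dense").q
        q2 = solve_screening(A, p2, "dense").q
        q12 = solve_screening(A, p1 + p2, "dense").q
        assert np.allclose(q12, q1 + q2, atol=1e-10)

    def test_split_solve_adds_up(self, rng):
        B = rng.normal(size=(20, 20))
        A = B @ B.T + 20 * np.eye(20)
        pn, pe = rng.normal(size=20), rng.normal(size=20)
        ch = solve_screening(A, pn + pe, "dense", phi_N=pn, phi_e=pe)
        assert np.allclose(ch.q, ch.q_N + ch.q_e, atol=1e-12)


class TestDielectricScaling:
    def test_ideal_is_unity(self):
        assert scale_factor(ScreenOption("ideal", 78.4)) == 1.0

    def test_printed_formulas(self):
        assert scale_factor(ScreenOption("ks", 2.0)) == pytest.approx(0.4)
        assert scale_factor(ScreenOption("st", 2.0)) == pytest.approx(0.5)

    def test_infinite_dielectric_limit(self):
        f = scale_factor(ScreenOption("ks", 1e12))
        assert abs(f - 1.0) < 1e-9

    def test_eps_below_one_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(ScreenOption("ks", 1.0))

    def test_apply_scaling(self, rng):
        from cosmosol.screening import ScreeningCharges

        q = rng.normal(size=10)
        ch = ScreeningCharges(q=q, q_N=0.5 * q, q_e=0.5 * q)
        out = apply_scaling(ch, 0.5)
        assert np.allclose(out.q, 0.5 * q)
        assert out.q.sum() == pytest.approx(0.5 * q.sum())
        same = apply_scaling(ch, 1.0)
        assert np.array_equal(same.q, q)
        with pytest.raises(ValueError):
            apply_scaling(ch, 0.0)


class TestBornOracle:
    def test_ks_fine_within_half_percent(self):
        e = born_energy(2.0, 1.0, "ks")
        exact = -0.5 / (2.0 * BOHR_PER_ANGSTROM)
        assert abs(e / exact - 1.0) < 0.005

    def test_ks_and_yk_agree_on_smooth_sphere(self):
        e_ks = born_energy(2.0, 1.0, "ks")
        e_yk = born_energy(2.0, 1.0, "yk")
        assert abs(e_ks / e_yk - 1.0) < 0.005

    def test_gauss_law_defect_shrinks_with_refinement(self):
        def defect(level):
            cav = build_vdw_cavity([Sphere(np.zeros(3), 2.0, 0)], level)
            solute = SoluteModel(nuclei=[Nucleus([0.0, 0.0, 0.0], 1.0)])
            phi = nuclear_potential(solute, cav.centers)
            q = solve_screening(build_A_ks(cav.segments), phi, "dense").q
            return abs(q.sum() + 1.0)

        assert defect("xfine") < defect("coarse")
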