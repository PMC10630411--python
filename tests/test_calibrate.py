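"""Scan drivers, harmonic/LJ fitting, orientation scans, chain calibration."""

import numpy as np
import pytest

import silkcg as s
from silkcg.calibrate import (
    BoundaryMinimumError,
    CalibrationConfig,
    FitError,
    FitWindow,
    RigidResidue,
    measure_angle,
    measure_dihedral,
    scan_angle,
    scan_bond,
    scan_dihedral,
    zmatrix_positions,
)
from silkcg.forcefield import wrap_angle_deg
from silkcg.synth import CGOracle, OraclePotential, make_scan


def harmonic_bond_oracle(K=100.0, r0=3.8):
    def oracle(pos):
        r = np.linalg.norm(pos[1] - pos[0])
        return K * (r - r0) ** 2

    return oracle


class TestZMatrix:
    def test_internal_coordinates_roundtrip(self):
        r = [3.8, 3.7, 3.9, 3.75]
        th = [150.0, 162.0, 155.0]
        ph = [170.0, -165.0]
        pos = zmatrix_positions(r, th, ph)
        for m in range(4):
            assert np.linalg.norm(pos[m + 1] - pos[m]) == pytest.approx(r[m])
        for m in range(3):
            assert measure_angle(pos[m], pos[m + 1], pos[m + 2]) == pytest.approx(th[m])
        for m in range(2):
            assert measure_dihedral(*pos[m : m + 4]) == pytest.approx(ph[m])


class TestScanBond:
    def test_minimum_at_equilibrium(self):
        cluster = np.array([[0.0, 0, 0], [0, 0, 4.2]])
        scan = scan_bond(cluster, 0, 1, (3.4, 4.2), 0.02, harmonic_bond_oracle())
        assert scan.coordinates[np.argmin(scan.energies)] == pytest.approx(3.8)

    def test_coordinates_arithmetic(self):
        cluster = np.array([[0.0, 0, 0], [0, 0, 4.0]])
        scan = scan_bond(cluster, 0, 1, (3.5, 4.0), 0.1, harmonic_bond_oracle())
        assert np.allclose(np.diff(scan.coordinates), 0.1)
        assert scan.coordinates[0] == pytest.approx(3.5)

    def test_degenerate_range_rejected(self):
        cluster = np.array([[0.0, 0, 0], [0, 0, 4.0]])
        with pytest.raises(ValueError):
            scan_bond(cluster, 0, 1, (4.0, 4.0), 0.1, harmonic_bond_oracle())
        with pytest.raises(ValueError):
            scan_bond(cluster, 0, 0, (3.0, 4.0), 0.1, harmonic_bond_oracle())


class TestScanAngle:
    def cluster(self):
        return np.array([[3.8, 0, 0], [0.0, 0, 0], [-3.0, 2.0, 0]])

    def test_jk_length_preserved_and_minimum(self):
        K, t0 = 25.0, 120.0

        def oracle(pos):
            return K * np.radians(measure_angle(pos[0], pos[1], pos[2]) - t0) ** 2

        scan = scan_angle(self.cluster(), 0, 1, 2, (100.0, 140.0), 1.0, oracle)
        assert scan.coordinates[np.argmin(scan.energies)] == pytest.approx(120.0)

    def test_collinear_rejected(self):
        bad = np.array([[3.8, 0, 0], [0.0, 0, 0], [-2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            scan_angle(bad, 0, 1, 2, (100.0, 140.0), 1.0, lambda p: 0.0)


class TestScanDihedral:
    def cluster(self):
        return zmatrix_positions([3.8, 3.8, 3.8], [150.0, 150.0], [60.0])

    def test_minimum_at_equilibrium(self):
        K, p0 = 5.0, 60.0

        def oracle(pos):
            phi = measure_dihedral(*pos)
            return K * np.radians(wrap_angle_deg(phi - p0)) ** 2

        scan = scan_dihedral(self.cluster(), 0, 1, 2, 3, (30.0, 90.0), 1.0, oracle)
        assert scan.coordinates[np.argmin(scan.energies)] == pytest.approx(60.0)

    def test_only_torsion_varies(self):
        # bonds and bending angles of the quadruple stay fixed while the
        # coordinate sweeps: energy variation is purely torsional
        pos0 = self.cluster()
        seen = []

        def oracle(pos):
            seen.append(
                (
                    np.linalg.norm(pos[3] - pos[2]),
                    measure_angle(pos[1], pos[2], pos[3]),
                    np.linalg.norm(pos[3] - pos[0]),
                )
            )
            return 0.0

        scan_dihedral(pos0, 0, 1, 2, 3, (30.0, 90.0), 5.0, oracle)
        kl = np.array([x[0] for x in seen])
        jkl = np.array([x[1] for x in seen])
        il = np.array([x[2] for x in seen])
        assert np.ptp(kl) < 1e-10
        assert np.ptp(jkl) < 1e-8
        assert np.ptp(il) > 0.1  # the 1-4 distance does change

    def test_degenerate_axis_rejected(self):
        pos = self.cluster()
        pos[2] = pos[1]
        with pytest.raises(ValueError):
            scan_dihedral(pos, 0, 1, 2, 3, (30.0, 90.0), 1.0, lambda p: 0.0)


class TestFitHarmonic:
    def test_exact_quadratic_recovered(self):
        grid = np.arange(3.5, 4.1001, 0.02)
        scan = make_scan(
            OraclePotential("harmonic", {"k": 300.0, "x0": 3.8, "offset": -7.0}),
            grid,
            kind="bond",
        )
        fit = s.fit_harmonic(scan)
        assert fit.stiffness == pytest.approx(300.0, rel=1e-9)
        assert fit.equilibrium == pytest.approx(3.8, rel=1e-9)
        assert fit.offset == pytest.approx(-7.0, abs=1e-8)
        assert fit.residual_rms < 1e-9

    def test_morse_curvature_limit(self):
        # quadratic fit of a narrow Morse window converges to the
        # curvature at the minimum: 2 K -> 2 D a^2
        D, a, re = 100.0, 1.0, 4.0
        grid = np.arange(re - 0.05, re + 0.0500001, 0.005)
        scan = make_scan(
            OraclePotential("morse", {"D": D, "a": a, "r_e": re}), grid, kind="bond"
        )
        fit = s.fit_harmonic(scan, FitWindow(energy_above_min=np.inf, min_points=5))
        assert 2 * fit.stiffness == pytest.approx(2 * D * a * a, rel=0.01)
        assert fit.equilibrium == pytest.approx(re, abs=2e-3)

    def test_window_shrink_consistency(self):
        # fitted stiffness approaches the analytic curvature as the
        # window shrinks around the minimum
        D, a, re = 100.0, 1.0, 4.0
        errors = []
        for half in (0.3, 0.1, 0.03):
            grid = np.linspace(re - half, re + half, 41)
            scan = make_scan(
                OraclePotential("morse", {"D": D, "a": a, "r_e": re}), grid, "bond"
            )
            fit = s.fit_harmonic(scan, FitWindow(energy_above_min=np.inf))
            errors.append(abs(fit.stiffness - D * a * a) / (D * a * a))
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 5e-3

    def test_noisy_quadratic_within_tolerance(self):
        # sigma_E = 0.01 noise on K=300: recovery within 5% across seeds
        grid = np.arange(3.6, 4.0001, 0.01)
        worst = 0.0
        for seed in range(100):
            scan = make_scan(
                OraclePotential(
                    "harmonic", {"k": 300.0, "x0": 3.8}, noise_sigma=0.01, seed=seed
                ),
                grid,
                kind="bond",
            )
            fit = s.fit_harmonic(scan, FitWindow(energy_above_min=np.inf))
            worst = max(worst, abs(fit.stiffness - 300.0) / 300.0)
        assert worst < 0.05

    def test_boundary_minimum_rejected(self):
        grid = np.arange(3.9, 4.5, 0.02)  # minimum at left edge
        scan = make_scan(
            OraclePotential("harmonic", {"k": 300.0, "x0": 3.8}), grid, "bond"
        )
        with pytest.raises(BoundaryMinimumError, match="extend"):
            s.fit_harmonic(scan)

    def test_angle_kind_returns_per_radian_stiffness(self):
        k_rad, t0 = 25.0, 150.0
        grid = np.arange(140.0, 160.1, 1.0)
        energies = k_rad * np.radians(grid - t0) ** 2
        scan = s.EnergyScan(grid, energies, kind="angle")
        fit = s.fit_harmonic(scan)
        assert fit.stiffness == pytest.approx(k_rad, rel=1e-9)
        assert fit.equilibrium == pytest.approx(t0, rel=1e-9)


class TestFitLJ:
    def grid(self):
        return np.arange(4.6, 12.0, 0.05)

    def test_exact_self_fit(self):
        scan = make_scan(
            OraclePotential("lj", {"epsilon": 0.5, "sigma": 5.0}),
            self.grid(),
            kind="separation",
        )
        fit = s.fit_lj(scan)
        assert fit.epsilon == pytest.approx(0.5, rel=1e-6)
        assert fit.sigma == pytest.approx(5.0, rel=1e-6)

    def test_minimum_location_relation(self):
        scan = make_scan(
            OraclePotential("lj", {"epsilon": 0.7, "sigma": 4.6}),
            np.arange(4.2, 12.0, 0.02),
            kind="separation",
        )
        fit = s.fit_lj(scan)
        r_min = scan.coordinates[np.argmin(scan.energies)]
        assert r_min == pytest.approx(2 ** (1 / 6) * fit.sigma, abs=0.03)

    def test_perturbed_well_recovered_within_10pct(self):
        base = OraclePotential("lj", {"epsilon": 0.5, "sigma": 5.0})
        grid = self.grid()
        energies = base.evaluate(grid) + 0.01 * (grid - 6.0) ** 2
        scan = s.EnergyScan(grid, energies, kind="separation")
        fit = s.fit_lj(scan)
        assert fit.epsilon == pytest.approx(0.5, rel=0.10)

    def test_purely_repulsive_rejected(self):
        grid = np.arange(2.0, 4.0, 0.05)
        energies = (3.0 / grid) ** 12
        scan = s.EnergyScan(grid, energies, kind="separation")
        with pytest.raises(FitError):
            s.fit_lj(scan)


class TestOrientationScan:
    def point_pair(self):
        i = RigidResidue(np.zeros((1, 3)), np.array([57.0]))
        j = RigidResidue(np.array([[7.0, 0, 0]]), np.array([57.0]))
        return i, j

    def test_periodicity(self):
        # rigid tripod so orientation actually matters
        j = RigidResidue(
            np.array([[7.0, 0, 0], [8.0, 0.5, 0], [7.0, -0.5, 0.5]]),
            np.array([20.0, 20.0, 17.0]),
        )
        i = RigidResidue(np.zeros((1, 3)), np.array([57.0]))

        def oracle(a, b):
            return float(1.0 / np.linalg.norm(b - a, axis=1).min())

        scan0, _ = s.orientation_scan(i, j, "Z", np.array([0.0, 90, 180, 270, 360]), oracle)
        assert scan0.energies[0] == pytest.approx(scan0.energies[-1], abs=1e-9)

    def test_flat_profile_tie_breaks_to_smallest_angle(self):
        i, j = self.point_pair()
        scan, best = s.orientation_scan(
            i, j, "X", np.arange(0.0, 360.0, 5.0), lambda a, b: 1.0
        )
        assert best == 0.0

    def test_cosine_profile_argmin(self):
        i, j = self.point_pair()
        profile = OraclePotential("cosine", {"amplitude": 1.0, "center_deg": 40.0})
        angles = {"count": -1}
        grid = np.arange(0.0, 360.0, 1.0)

        def oracle(a, b):
            angles["count"] += 1
            return float(profile.evaluate(np.array([grid[angles["count"]]]))[0])

        scan, best = s.orientation_scan(i, j, "Y", grid, oracle)
        assert best == pytest.approx(40.0)


class TestCalibratePair:
    def test_orientation_independent_oracle_averages_to_itself(self):
        i = RigidResidue(np.zeros((1, 3)), np.array([57.0]))
        j = RigidResidue(np.array([[7.0, 0, 0]]), np.array([57.0]))
        eps, sigma = 0.6, 4.8

        def oracle(a, b):
            r = np.linalg.norm(b[0] - a[0])
            sr6 = (sigma / r) ** 6
            return 4 * eps * (sr6 * sr6 - sr6)

        param, report = s.calibrate_pair(i, j, (4.4, 11.0), 0.05, oracle)
        assert param.epsilon == pytest.approx(eps, rel=1e-6)
        assert param.sigma == pytest.approx(sigma, rel=1e-6)
        tetas = [report["scenarios"][ax]["teta"] for ax in "XYZ"]
        assert tetas == [0.0, 0.0, 0.0]  # flat orientation profiles

    def test_scenario_average_is_arithmetic_mean(self):
        # anisotropic oracle: construct per-axis wells with known depths
        i = RigidResidue(np.zeros((1, 3)), np.array([57.0]))
        # two-site rigid residue whose orientation controls the well depth
        j = RigidResidue(
            np.array([[7.0, 0, 0], [7.0, 1.0, 0]]), np.array([30.0, 27.0])
        )
        sigma = 4.8

        def oracle(a, b):
            com_j = b.mean(axis=0)  # near enough to the true COM
            r = np.linalg.norm(com_j - a[0])
            # depth modulated by the second site's offset direction
            direction = b[1] - b[0]
            eps = 0.5 + 0.2 * abs(direction[2]) / np.linalg.norm(direction)
            sr6 = (sigma / max(r, 1e-6)) ** 6
            return 4 * eps * (sr6 * sr6 - sr6)

        param, report = s.calibrate_pair(i, j, (4.4, 11.0), 0.05, oracle)
        fits = [report["scenarios"][ax]["fit"] for ax in "XYZ"]
        assert param.epsilon == pytest.approx(np.mean([f.epsilon for f in fits]))
        assert param.sigma == pytest.approx(np.mean([f.sigma for f in fits]))


class TestCalibrateChain:
    def test_tiny_sequence_counts(self):
        ff = s.default_forcefield("GAG")
        oracle = CGOracle(ff, "GAG")
        fit, report = s.calibrate_chain("GAG", oracle)
        assert len(fit.bonds) == 2
        assert len(fit.angles) == 1
        assert len(fit.dihedrals) == 0
        assert sorted(fit.pairs) == ["A", "G"]

    def test_roundtrip_recovers_parameters(self, short_seq, short_ff):
        oracle = CGOracle(short_ff, short_seq)
        fit, report = s.calibrate_chain(short_seq, oracle)
        assert report["failures"] == []
        for key, p in short_ff.bonds.items():
            assert fit.bonds[key].k == pytest.approx(p.k, rel=1e-6)
            assert fit.bonds[key].r0 == pytest.approx(p.r0, rel=1e-6)
        for key, p in short_ff.angles.items():
            assert fit.angles[key].k == pytest.approx(p.k, rel=1e-6)
            assert fit.angles[key].theta0 == pytest.approx(p.theta0, rel=1e-6)
        for key, p in short_ff.dihedrals.items():
            assert fit.dihedrals[key].k == pytest.approx(p.k, rel=1e-6)
            assert wrap_angle_deg(fit.dihedrals[key].phi0 - p.phi0) == pytest.approx(
                0.0, abs=1e-4
            )
        for sp, p in short_ff.pairs.items():
            assert fit.pairs[sp].epsilon == pytest.approx(p.epsilon, rel=1e-6)
            assert fit.pairs[sp].sigma == pytest.approx(p.sigma, rel=1e-6)

    def test_angle_fits_independent_of_pair_parameters(self, short_seq):
        # bending calibration drops non-bonded terms, so scaling every
        # epsilon leaves the fitted angle stiffnesses untouched
        ff_a = s.default_forcefield(short_seq)
        ff_b = s.default_forcefield(short_seq)
        from silkcg.forcefield import PairParam

        ff_b.pairs = {
            k: PairParam(p.epsilon * 10, p.sigma) for k, p in ff_b.pairs.items()
        }
        fit_a, _ = s.calibrate_chain(short_seq, CGOracle(ff_a, short_seq))
        fit_b, _ = s.calibrate_chain(short_seq, CGOracle(ff_b, short_seq))
        for key in fit_a.angles:
            assert fit_a.angles[key].k == pytest.approx(fit_b.angles[key].k, rel=1e-9)

    def test_failed_term_listed_not_fatal(self, short_seq, short_ff):
        class BrokenOracle(CGOracle):
            def cluster_energy(self, indices, positions, kind):
                if kind == "bond" and indices[0] == 0:
                    return 0.0  # flat scan: no interior minimum curvature
                return super().cluster_energy(indices, positions, kind)

        fit, report = s.calibrate_chain(short_seq, BrokenOracle(short_ff, short_seq))
        assert ("bond", "1-2", "fitted curvature is not positive") in [
            (k, t, m) for k, t, m in report["failures"]
        ] or any(k == "bond" and t == "1-2" for k, t, m in report["failures"])
        assert "1-2" not in fit.bonds
        assert "2-3" in fit.bonds
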