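import numpy as np
import pytest

from qeqpot.qeq import (
    ElementElectro,
    QeqError,
    ScreeningSpec,
    build_system,
    electrostatic_energy,
    ewald_energy,
    pair_kernel,
    pair_kernel_deriv,
    solution_derivatives,
    solve_qeq,
)
from qeqpot.structures import Structure
from qeqpot.units import ANGSTROM_TO_BOHR, BOHR

SQRT_PI = np.sqrt(np.pi)


@pytest.fixture
def electro():
    return ElementElectro({"A": 0.4, "B": 0.5}, {"A": 1.2, "B": 1.6})


def random_system(electro, n=8, seed=0, qtot=1.0):
    rng = np.random.default_rng(seed)
    s = Structure(["A", "B"] * (n // 2), rng.uniform(0, 4, (n, 3)), total_charge=qtot)
    chi = rng.normal(0, 0.1, n)
    return s, chi


def e_qeq(system, Q):
    """Eq-2 style quadratic energy of a charge vector."""
    return 0.5 * Q @ system.A @ Q + system.chi @ Q


class TestPairKernel:
    def test_long_range_is_coulomb(self):
        g = 1.3
        r = 100 * g
        assert abs(pair_kernel(r, g) - 1 / r) < 1e-12

    def test_small_r_limit_matches_series(self):
        # erf(x)/r = sqrt(2/pi)/g (1 - r^2/(6*2*g^2) + ...) -> limit sqrt(2/pi)/g
        g = 0.7
        lim = np.sqrt(2 / np.pi) / g
        assert abs(pair_kernel(1e-9, g) - lim) < 1e-10
        # just above the switch, series value agrees
        r = 1e-7
        series = lim * (1 - r**2 / (6 * g**2))
        assert abs(pair_kernel(r, g) - series) < 1e-10

    def test_strictly_decreasing_on_log_grid(self):
        g = 0.9
        r = np.geomspace(1e-3, 1e3, 400)
        v = pair_kernel(r, g)
        assert np.all(np.diff(v) < 0)

    def test_derivative_fd(self):
        g = 1.1
        r = np.linspace(0.2, 8.0, 40)
        h = 1e-6
        fd = (pair_kernel(r + h, g) - pair_kernel(r - h, g)) / (2 * h)
        np.testing.assert_allclose(pair_kernel_deriv(r, g), fd, atol=1e-8)


class TestBuildSystem:
    def test_single_atom_diagonal(self):
        el = ElementElectro({"A": 0.2}, {"A": 1.0})
        s = Structure(["A"], [[0, 0, 0]])
        sys_ = build_system(s, np.zeros(1), el)
        assert abs(sys_.A[0, 0] - (0.2 + 1 / SQRT_PI)) < 1e-14

    def test_symmetric(self, electro):
        s, chi = random_system(electro, n=6, seed=1)
        sys_ = build_system(s, chi, electro)
        np.testing.assert_allclose(sys_.A, sys_.A.T, atol=1e-12)

    def test_gamma_closed_form(self):
        el = ElementElectro({"A": 0.2, "B": 0.2}, {"A": 0.3, "B": 0.4})
        s = Structure(["A", "B"], [[0, 0, 0], [2, 0, 0]])
        sys_ = build_system(s, np.zeros(2), el)
        assert abs(sys_.gamma[0, 1] - 0.5) < 1e-15

    def test_overlapping_atoms_rejected(self, electro):
        s = Structure(["A", "B"], [[0, 0, 0], [0, 0, 1e-9]])
        with pytest.raises(ValueError, match="overlapping"):
            build_system(s, np.zeros(2), electro)

    def test_unknown_element(self, electro):
        s = Structure(["A", "Zz"], [[0, 0, 0], [2, 0, 0]])
        with pytest.raises(KeyError, match="Zz"):
            build_system(s, np.zeros(2), electro)


class TestSolve:
    def test_homonuclear_dimer_symmetry(self):
        el = ElementElectro({"A": 0.4}, {"A": 1.2})
        s = Structure(["A", "A"], [[0, 0, 0], [2.0, 0, 0]], total_charge=1.0)
        sol = solve_qeq(build_system(s, np.array([0.3, 0.3]), el))
        np.testing.assert_allclose(sol.charges, [0.5, 0.5], atol=1e-12)

    def test_heteronuclear_dimer_closed_form(self, electro):
        r_ang = 1.7
        s = Structure(["A", "B"], [[0, 0, 0], [r_ang, 0, 0]], total_charge=1.0)
        chi = np.array([0.05, -0.15])
        sol = solve_qeq(build_system(s, chi, electro))
        d1 = 0.4 + 1 / (1.2 * SQRT_PI)
        d2 = 0.5 + 1 / (1.6 * SQRT_PI)
        k = float(pair_kernel(r_ang * ANGSTROM_TO_BOHR, np.sqrt(1.2**2 + 1.6**2)))
        q1 = ((chi[1] - chi[0]) + 1.0 * (d2 - k)) / (d1 + d2 - 2 * k)
        assert abs(sol.charges[0] - q1) < 1e-12
        # the atom with larger chi (atom 0) receives the more negative charge
        assert sol.charges[0] < sol.charges[1]

    def test_charge_conservation(self, electro):
        for seed in range(5):
            s, chi = random_system(electro, seed=seed, qtot=float(seed - 2))
            sol = solve_qeq(build_system(s, chi, electro))
            assert abs(sol.charges.sum() - s.total_charge) < 1e-10

    def test_residual_small(self, electro):
        s, chi = random_system(electro, seed=3)
        sys_ = build_system(s, chi, electro)
        sol = solve_qeq(sys_)
        res = sys_.A @ sol.charges + sys_.chi + sol.lagrange
        assert np.abs(res).max() < 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_beats_random_constraint_satisfying_vectors(self, electro, seed):
        rng = np.random.default_rng(seed)
        n = 12
        s, chi = random_system(electro, n=n, seed=seed + 50, qtot=1.0)
        sys_ = build_system(s, chi, electro)
        sol = solve_qeq(sys_)
        e0 = e_qeq(sys_, sol.charges)
        for _ in range(1000):
            dq = rng.normal(0, 0.1, n)
            dq -= dq.mean()  # stay on the constraint surface
            assert e_qeq(sys_, sol.charges + dq) >= e0 - 1e-12

    def test_ill_conditioned_raises(self):
        # choose J so the diagonal equals the off-diagonal kernel: the
        # augmented matrix then has two identical rows and is singular
        r_bohr = 2.0
        k = float(pair_kernel(r_bohr, np.sqrt(2.0)))
        el = ElementElectro({"A": k - 1.0 / SQRT_PI}, {"A": 1.0})
        s = Structure(["A", "A"], [[0, 0, 0], [r_bohr * BOHR, 0, 0]], total_charge=0.0)
        with pytest.raises(QeqError):
            solve_qeq(build_system(s, np.zeros(2), el))


class TestElectrostaticEnergy:
    def test_single_atom_self_energy(self):
        el = ElementElectro({"A": 0.2}, {"A": 1.1})
        s = Structure(["A"], [[0, 0, 0]], total_charge=0.7)
        e = electrostatic_energy(s, np.array([0.7]), el)
        assert abs(e - 0.7**2 / (2 * 1.1 * SQRT_PI)) < 1e-14

    def test_zero_charges_zero(self, electro):
        s, _ = random_system(electro, seed=2)
        assert electrostatic_energy(s, np.zeros(8), electro) == 0.0

    def test_asymptotic_coulomb(self):
        el = ElementElectro({"A": 0.2}, {"A": 1.0})
        r = 50.0 / ANGSTROM_TO_BOHR  # 50 Bohr in Angstrom
        s = Structure(["A", "A"], [[0, 0, 0], [r, 0, 0]], total_charge=2.0)
        e = electrostatic_energy(s, np.array([1.0, 1.0]), el)
        selfE = 2 * 1.0 / (2 * 1.0 * SQRT_PI)
        assert abs(e - selfE - 1.0 / 50.0) < 1e-10

    def test_consistent_with_solution_e_elec(self, electro):
        s, chi = random_system(electro, seed=7)
        sys_ = build_system(s, chi, electro)
        sol = solve_qeq(sys_)
        e = electrostatic_energy(s, sol.charges, electro)
        assert abs(e - sol.e_elec) < 1e-12

    def test_screening_reduces_close_pairs(self):
        el = ElementElectro({"A": 0.2}, {"A": 1.0})
        s = Structure(["A", "A"], [[0, 0, 0], [1.0, 0, 0]], total_charge=2.0)
        full = electrostatic_energy(s, np.ones(2), el)
        scr = electrostatic_energy(s, np.ones(2), el, ScreeningSpec(1.5, 3.0))
        # pair is inside the inner radius: pair term fully removed
        selfE = 2 * 1.0 / (2 * 1.0 * SQRT_PI)
        assert scr < full
        assert abs(scr - selfE) < 1e-12

    def test_gradients_fd(self, electro):
        rng = np.random.default_rng(4)
        s, _ = random_system(electro, seed=4)
        q = rng.normal(0, 0.4, 8)
        scr = ScreeningSpec(1.5, 3.5)
        e, dE_dr, dE_dq = electrostatic_energy(s, q, electro, scr, with_grads=True)
        h = 1e-5
        for k in range(8):
            for c in range(3):
                sp = s.copy()
                sp.positions[k, c] += h / ANGSTROM_TO_BOHR
                sm = s.copy()
                sm.positions[k, c] -= h / ANGSTROM_TO_BOHR
                fd = (
                    electrostatic_energy(sp, q, electro, scr)
                    - electrostatic_energy(sm, q, electro, scr)
                ) / (2 * h)
                assert abs(fd - dE_dr[k, c]) < 1e-8
        for k in range(8):
            qp, qm = q.copy(), q.copy()
            qp[k] += h
            qm[k] -= h
            fd = (
                electrostatic_energy(s, qp, electro, scr)
                - electrostatic_energy(s, qm, electro, scr)
            ) / (2 * h)
            assert abs(fd - dE_dq[k]) < 1e-8


def rocksalt_cell(nn=2.0):
    """8-atom cubic NaCl cell with near-point charges; nn distance in Bohr."""
    a = nn * BOHR
    sp, pos, q = [], [], []
    for i in range(2):
        for j in range(2):
            for k in range(2):
                sp.append("P" if (i + j + k) % 2 == 0 else "M")
                pos.append((i * a, j * a, k * a))
                q.append(1.0 if (i + j + k) % 2 == 0 else -1.0)
    s = Structure(sp, np.array(pos), cell=np.eye(3) * 2 * a, pbc=(True, True, True))
    return s, np.array(q)


def evjen_direct_sum(structure, charges, sigma, nshell=7):
    """Charge-neutral (Evjen-weighted) expanding-cube direct sum oracle."""
    from scipy.special import erf

    pos = structure.positions * ANGSTROM_TO_BOHR
    cell = structure.cell * ANGSTROM_TO_BOHR
    n = len(charges)
    gamma = np.sqrt(2.0) * sigma
    e = 0.0
    rng = range(-nshell, nshell + 1)
    for a in rng:
        for b in rng:
            for c in rng:
                w = 1.0
                for t in (a, b, c):
                    if abs(t) == nshell:
                        w *= 0.5
                L = np.array([a, b, c], dtype=float) @ cell
                for i in range(n):
                    for j in range(n):
                        if (a, b, c) == (0, 0, 0) and i == j:
                            continue
                        r = np.linalg.norm(pos[j] + L - pos[i])
                        e += 0.5 * w * charges[i] * charges[j] * erf(r / (np.sqrt(2) * gamma)) / r
    return e


class TestEwald:
    def test_madelung_vs_direct_sum_oracle(self):
        s, q = rocksalt_cell(nn=2.0)
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 0.05, "M": 0.05})
        e = ewald_energy(s, q, el, accuracy=1e-8)
        self_term = float(np.sum(q**2 / (2 * 0.05 * SQRT_PI)))
        direct = evjen_direct_sum(s, q, 0.05, nshell=7)
        assert abs((e - self_term) - direct) / 4 < 1e-6  # per ion pair
        # and against the known Madelung constant
        assert abs((e - self_term) / 4 + 1.7475645946 / 2.0) < 1e-6

    def test_eta_independence(self):
        s, q = rocksalt_cell()
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 0.05, "M": 0.05})
        e1 = ewald_energy(s, q, el, accuracy=1e-8, eta=1.0)
        e2 = ewald_energy(s, q, el, accuracy=1e-8, eta=2.0)
        assert abs(e1 - e2) < 1e-8

    def test_zero_charges(self):
        s, q = rocksalt_cell()
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 0.5, "M": 0.5})
        assert ewald_energy(s, np.zeros(8), el) == 0.0

    def test_non_neutral_rejected(self):
        s, q = rocksalt_cell()
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 0.5, "M": 0.5})
        with pytest.raises(ValueError):
            ewald_energy(s, np.abs(q), el)

    def test_bad_accuracy(self):
        s, q = rocksalt_cell()
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 0.5, "M": 0.5})
        with pytest.raises(ValueError):
            ewald_energy(s, q, el, accuracy=0.0)

    def test_cluster_limit_large_vacuum(self):
        # isotropic (octahedral) neutral charge distribution: no shape terms
        d = 2.5
        pos = np.array(
            [[0, 0, 0], [d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d]]
        )
        sp = ["M"] + ["P"] * 6
        q = np.array([-1.2] + [0.2] * 6)
        el = ElementElectro({"P": 0.1, "M": 0.1}, {"P": 1.0, "M": 1.0})
        ec = electrostatic_energy(Structure(sp, pos), q, el)
        L = 60.0 * BOHR
        ep = ewald_energy(
            Structure(sp, pos, cell=np.eye(3) * L, pbc=(True, True, True)), q, el,
            accuracy=1e-9,
        )
        assert abs(ep - ec) < 1e-6

    def test_periodic_qeq_charge_conservation(self):
        el = ElementElectro({"P": 0.4, "M": 0.5}, {"P": 1.0, "M": 1.2})
        rng = np.random.default_rng(0)
        s = Structure(
            ["P", "M"] * 3, rng.uniform(0, 5, (6, 3)), cell=np.eye(3) * 6.0,
            pbc=(True, True, True), total_charge=0.0,
        )
        sol = solve_qeq(build_system(s, rng.normal(0, 0.1, 6), el))
        assert abs(sol.charges.sum()) < 1e-10

    def test_charged_periodic_rejected(self):
        el = ElementElectro({"P": 0.4}, {"P": 1.0})
        s = Structure(
            ["P"], [[0, 0, 0]], cell=np.eye(3) * 5.0, pbc=(True, True, True),
            total_charge=1.0,
        )
        with pytest.raises(ValueError):
            build_system(s, np.zeros(1), el)


class TestSolutionDerivatives:
    def setup_method(self):
        self.electro = ElementElectro({"A": 0.4, "B": 0.5}, {"A": 1.2, "B": 1.6})
        rng = np.random.default_rng(10)
        self.s = Structure(["A", "B"] * 4, rng.uniform(0, 4, (8, 3)), total_charge=1.0)
        self.chi = rng.normal(0, 0.1, 8)
        self.sys = build_system(self.s, self.chi, self.electro)
        self.sol = solve_qeq(self.sys)
        self.der = solution_derivatives(self.sys, self.sol, self.s)

    def test_gauge_invariance_rows_sum_zero(self):
        np.testing.assert_allclose(self.der.dq_dchi.sum(axis=1), 0.0, atol=1e-12)
        # verified by direct perturbation: shift all chi by a constant
        sol2 = solve_qeq(build_system(self.s, self.chi + 0.05, self.electro))
        np.testing.assert_allclose(sol2.charges, self.sol.charges, atol=1e-10)

    def test_translational_invariance(self):
        np.testing.assert_allclose(self.der.dq_dr.sum(axis=1), 0.0, atol=1e-12)

    def test_dq_dchi_fd(self):
        h = 1e-5
        for m in range(8):
            cp, cm = self.chi.copy(), self.chi.copy()
            cp[m] += h
            cm[m] -= h
            qp = solve_qeq(build_system(self.s, cp, self.electro)).charges
            qm = solve_qeq(build_system(self.s, cm, self.electro)).charges
            fd = (qp - qm) / (2 * h)
            np.testing.assert_allclose(self.der.dq_dchi[:, m], fd, atol=1e-6)

    def test_dq_dr_fd(self):
        h = 1e-5  # Bohr
        for k in range(8):
            for c in range(3):
                sp = self.s.copy()
                sp.positions[k, c] += h / ANGSTROM_TO_BOHR
                sm = self.s.copy()
                sm.positions[k, c] -= h / ANGSTROM_TO_BOHR
                qp = solve_qeq(build_system(sp, self.chi, self.electro)).charges
                qm = solve_qeq(build_system(sm, self.chi, self.electro)).charges
                fd = (qp - qm) / (2 * h)
                np.testing.assert_allclose(self.der.dq_dr[:, k, c], fd, atol=1e-6)

    def test_dq_dJ_fd(self):
        h = 1e-6
        for el in ("A", "B"):
            up = ElementElectro(dict(self.electro.hardness), dict(self.electro.width))
            dn = ElementElectro(dict(self.electro.hardness), dict(self.electro.width))
            up.hardness[el] += h
            dn.hardness[el] -= h
            qp = solve_qeq(build_system(self.s, self.chi, up)).charges
            qm = solve_qeq(build_system(self.s, self.chi, dn)).charges
            fd = (qp - qm) / (2 * h)
            np.testing.assert_allclose(self.der.dq_dJ[el], fd, atol=1e-6)

    def test_stale_factorization_rejected(self):
        other = build_system(self.s, self.chi, self.electro)
        with pytest.raises(QeqError, match="stale"):
            solution_derivatives(other, self.sol, self.s)

    def test_periodic_dq_dr_fd(self):
        el = ElementElectro({"A": 0.4, "B": 0.5}, {"A": 1.0, "B": 1.2})
        rng = np.random.default_rng(3)
        s = Structure(
            ["A", "B"] * 2, rng.uniform(0, 4, (4, 3)), cell=np.eye(3) * 5.0,
            pbc=(True, True, True), total_charge=0.0,
        )
        chi = rng.normal(0, 0.1, 4)
        sys_ = build_system(s, chi, el)
        der = solution_derivatives(sys_, solve_qeq(sys_), s)
        h = 1e-5
        for k in range(4):
            for c in range(3):
                sp = s.copy()
                sp.positions[k, c] += h / ANGSTROM_TO_BOHR
                sm = s.copy()
                sm.positions[k, c] -= h / ANGSTROM_TO_BOHR
                qp = solve_qeq(build_system(sp, chi, el)).charges
                qm = solve_qeq(build_system(sm, chi, el)).charges
                np.testing.assert_allclose(der.dq_dr[:, k, c], (qp - qm) / (2 * h), atol=1e-6)
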