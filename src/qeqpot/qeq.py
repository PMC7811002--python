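"""Charge equilibration with Gaussian charge densities.

Energy model (atomic units; r, sigma, gamma in Bohr, energies in Ha):

    E_Qeq  = E_elec + sum_i (chi_i Q_i + 1/2 J_i Q_i^2)
    E_elec = sum_{i<j} erf(r_ij / (sqrt(2) gamma_ij)) / r_ij Q_i Q_j
             + sum_i Q_i^2 / (2 sigma_i sqrt(pi))
    gamma_ij = sqrt(sigma_i^2 + sigma_j^2)

Stationarity under the total-charge constraint is the augmented saddle-point
system [[A, 1], [1^T, 0]] [Q; lambda] = [-chi; Q_tot] with
A_ij = erf(r_ij/(sqrt(2) gamma_ij))/r_ij off-diagonal and
A_ii = J_i + 1/(sigma_i sqrt(pi)).  Periodic off-diagonals are the Ewald
lattice sum of the same kernel (neutral cells only).  All derivatives of the
equilibrated charges are obtained by implicit differentiation reusing one LU
factorization; no finite differences anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import erf, erfcinv

from .structures import Structure, build_neighbor_list
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "ElementElectro",
    "ScreeningSpec",
    "QeqSystem",
    "QeqSolution",
    "QeqError",
    "pair_kernel",
    "pair_kernel_deriv",
    "build_system",
    "solve_qeq",
    "solution_derivatives",
    "electrostatic_energy",
    "ewald_energy",
]

_SQRT_PI = np.sqrt(np.pi)
_R_TINY = 1e-8  # Bohr; below this the analytic r -> 0 kernel limit is used
_COND_LIMIT = 1e12


class QeqError(RuntimeError):
    """Charge-equilibration failure (singular or ill-conditioned system)."""


@dataclass
class ElementElectro:
    """Per-element hardness J (Ha/e^2) and Gaussian width sigma (Bohr)."""

    hardness: dict[str, float]
    width: dict[str, float]

    def __post_init__(self):
        for el, s in self.width.items():
            if s <= 0:
                raise ValueError(f"Gaussian width for {el} must be positive")

    def per_atom(self, species: list[str]):
        try:
            J = np.array([self.hardness[el] for el in species])
            sigma = np.array([self.width[el] for el in species])
        except KeyError as exc:
            raise KeyError(f"element {exc.args[0]!r} missing from electrostatic table") from exc
        return J, sigma


@dataclass
class ScreeningSpec:
    """Cosine switch attenuating the Coulomb kernel at short range.

    S(r) = 0 for r <= inner, 1 for r >= outer, and
    S(r) = 1/2 [1 - cos(pi (r - inner)/(outer - inner))] in between.
    Radii in Angstrom.  Self-energy terms are never screened.
    """

    inner: float
    outer: float

    def __post_init__(self):
        if not 0 < self.inner < self.outer:
            raise ValueError("require 0 < inner < outer")

    def switch(self, r_ang):
        """Value and radial derivative (per Angstrom) of S at r (Angstrom)."""
        r = np.asarray(r_ang, dtype=float)
        t = np.clip((r - self.inner) / (self.outer - self.inner), 0.0, 1.0)
        val = 0.5 * (1.0 - np.cos(np.pi * t))
        dval = np.where(
            (r > self.inner) & (r < self.outer),
            0.5 * np.pi / (self.outer - self.inner) * np.sin(np.pi * t),
            0.0,
        )
        return val, dval


@dataclass
class QeqSystem:
    """Assembled interaction matrix and its geometric derivative cache."""

    A: np.ndarray                 # (N, N) Ha/e^2
    chi: np.ndarray               # (N,) Ha/e
    q_total: float
    gamma: np.ndarray             # (N, N) Bohr
    structure: Structure = field(repr=False)
    electro: ElementElectro = field(repr=False)
    pair_grad: np.ndarray = field(repr=False)  # (N, N, 3) dA_ij/dr_i, Ha/e^2/Bohr


@dataclass
class QeqSolution:
    charges: np.ndarray
    lagrange: float
    e_elec: float
    _lu: tuple = field(repr=False)
    _system: QeqSystem = field(repr=False)


def pair_kernel(r, gamma):
    """erf(r / (sqrt(2) gamma)) / r in Ha e^-2 (r, gamma in Bohr).

    Below r = 1e-8 Bohr the analytic limit sqrt(2/pi)/gamma is returned.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(gamma, dtype=float)
    small = r < _R_TINY
    rsafe = np.where(small, 1.0, r)
    val = erf(rsafe / (np.sqrt(2.0) * g)) / rsafe
    lim = np.sqrt(2.0 / np.pi) / g
    return np.where(small, lim, val)


def pair_kernel_deriv(r, gamma):
    """d/dr of pair_kernel (Ha e^-2 Bohr^-1); 0 at r -> 0 by symmetry."""
    r = np.asarray(r, dtype=float)
    g = np.asarray(gamma, dtype=float)
    small = r < _R_TINY
    rsafe = np.where(small, 1.0, r)
    a = 1.0 / (np.sqrt(2.0) * g)
    dval = (2.0 * a / _SQRT_PI) * np.exp(-((a * rsafe) ** 2)) / rsafe - erf(a * rsafe) / rsafe**2
    return np.where(small, 0.0, dval)


# ---------------------------------------------------------------------------
# Ewald machinery (Gaussian charges, neutral cells, tinfoil boundary)
# ---------------------------------------------------------------------------

def _auto_eta(cell_bohr: np.ndarray, gamma_max: float) -> float:
    vol = abs(np.linalg.det(cell_bohr))
    return max(gamma_max, 0.25 * vol ** (1.0 / 3.0))


def _ewald_pair_matrix(
    structure: Structure,
    gamma: np.ndarray,
    eta: float,
    accuracy: float,
    with_grad: bool,
):
    """Background-subtracted lattice-summed kernel matrix B (and dB_ij/dr_i).

    B_ij = sum_L erf(|d_ij + L| / (sqrt(2) gamma_ij)) / |d_ij + L|  - background,
    evaluated as real-space short-range part plus reciprocal sum; the i == j
    diagonal carries the self-image sum (no 1/0 term).
    """
    if not all(structure.pbc):
        raise ValueError("Ewald summation requires full periodicity")
    cell = structure.cell * ANGSTROM_TO_BOHR
    pos = structure.positions * ANGSTROM_TO_BOHR
    n = structure.n_atoms
    vol = abs(np.linalg.det(cell))
    if vol < 1e-12:
        raise ValueError("singular cell")

    eta_eff = max(eta, float(gamma.max()))
    acc = min(accuracy, 0.1) * 1e-2  # margin: bounds ignore 1/r and |S(k)|^2 prefactors
    rcut = np.sqrt(2.0) * eta_eff * float(erfcinv(acc))
    kcut = np.sqrt(2.0 * np.log(1.0 / acc)) / eta * 1.2

    d = pos[:, None, :] - pos[None, :, :]  # (N, N, 3)

    # real space
    dmax = float(np.linalg.norm(d, axis=-1).max())
    nmax = []
    for dd in range(3):
        cross = np.cross(cell[(dd + 1) % 3], cell[(dd + 2) % 3])
        width = vol / np.linalg.norm(cross)
        nmax.append(int(np.ceil((rcut + dmax) / width)))
    shifts = np.array(
        [
            (a, b, c)
            for a in range(-nmax[0], nmax[0] + 1)
            for b in range(-nmax[1], nmax[1] + 1)
            for c in range(-nmax[2], nmax[2] + 1)
        ],
        dtype=float,
    )
    L = shifts @ cell  # (M, 3)

    B = np.zeros((n, n))
    G = np.zeros((n, n, 3)) if with_grad else None
    sq2 = np.sqrt(2.0)
    for Lv in L:
        R = d + Lv  # (N, N, 3)
        r = np.linalg.norm(R, axis=-1)
        mask = (r <= rcut) & (r > _R_TINY)
        if not mask.any():
            continue
        rm = r[mask]
        gm = gamma[mask]
        term = (erf(rm / (sq2 * gm)) - erf(rm / (sq2 * eta))) / rm
        B[mask] += term
        if with_grad:
            dterm = (
                pair_kernel_deriv(rm, gm) - pair_kernel_deriv(rm, np.full_like(rm, eta))
            )
            G[mask] += dterm[:, None] * (R[mask] / rm[:, None])

    # reciprocal space (half-space, doubled)
    recip = 2.0 * np.pi * np.linalg.inv(cell).T
    kmax = [int(np.ceil(kcut * np.linalg.norm(cell[dd]) / (2 * np.pi))) for dd in range(3)]
    ks = []
    for a in range(0, kmax[0] + 1):
        for b in range(-kmax[1], kmax[1] + 1):
            for c in range(-kmax[2], kmax[2] + 1):
                if (a, b, c) <= (0, 0, 0):
                    continue
                ks.append((a, b, c))
    if ks:
        K = np.array(ks, dtype=float) @ recip  # (M, 3)
        k2 = np.einsum("md,md->m", K, K)
        keep = k2 <= kcut**2
        K, k2 = K[keep], k2[keep]
        coef = (8.0 * np.pi / vol) * np.exp(-0.5 * eta**2 * k2) / k2  # doubled half-space
        phase = np.einsum("md,ijd->mij", K, d)
        B += np.einsum("m,mij->ij", coef, np.cos(phase))
        if with_grad:
            G -= np.einsum("m,mij,md->ijd", coef, np.sin(phase), K)

    # background + self corrections
    B -= 2.0 * np.pi * eta**2 / vol
    B[np.diag_indices(n)] -= np.sqrt(2.0 / np.pi) / eta
    if with_grad:
        G[np.diag_indices(n)] = 0.0
    return B, G


def _pair_matrix(
    structure: Structure,
    gamma: np.ndarray,
    accuracy: float = 1e-8,
    eta: Optional[float] = None,
    with_grad: bool = True,
):
    """Kernel matrix B (zero diagonal for clusters) and dB_ij/dr_i."""
    n = structure.n_atoms
    if all(structure.pbc):
        cell = structure.cell * ANGSTROM_TO_BOHR
        if eta is None:
            eta = _auto_eta(cell, float(gamma.max()))
        return _ewald_pair_matrix(structure, gamma, eta, accuracy, with_grad)
    if any(structure.pbc):
        raise ValueError("mixed periodicity is not supported")
    pos = structure.positions * ANGSTROM_TO_BOHR
    d = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < 1e-6):
        raise ValueError("overlapping atoms (r < 1e-6 Bohr)")
    B = np.zeros((n, n))
    B[off] = pair_kernel(r[off], gamma[off])
    G = None
    if with_grad:
        G = np.zeros((n, n, 3))
        G[off] = pair_kernel_deriv(r[off], gamma[off])[:, None] * (d[off] / r[off][:, None])
    return B, G


def build_system(
    structure: Structure,
    chi: np.ndarray,
    electro: ElementElectro,
    accuracy: float = 1e-8,
) -> QeqSystem:
    """Assemble the Qeq matrix A for a cluster or a fully periodic cell."""
    n = structure.n_atoms
    chi = np.asarray(chi, dtype=float)
    if chi.shape != (n,):
        raise ValueError("chi must have one entry per atom")
    J, sigma = electro.per_atom(structure.species)
    gamma = np.sqrt(sigma[:, None] ** 2 + sigma[None, :] ** 2)
    if all(structure.pbc) and abs(structure.total_charge) > 1e-6:
        raise ValueError("charged periodic cells are not supported")
    B, G = _pair_matrix(structure, gamma, accuracy=accuracy, with_grad=True)
    A = B.copy()
    A[np.diag_indices(n)] += J + 1.0 / (sigma * _SQRT_PI)
    return QeqSystem(
        A=A, chi=chi, q_total=float(structure.total_charge), gamma=gamma,
        structure=structure, electro=electro, pair_grad=G,
    )


def _augmented(system: QeqSystem) -> np.ndarray:
    n = system.A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = system.A
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    return M


def solve_qeq(system: QeqSystem) -> QeqSolution:
    """One dense solve of the constrained stationarity conditions."""
    n = system.A.shape[0]
    M = _augmented(system)
    if np.linalg.cond(M) > _COND_LIMIT:
        raise QeqError(
            "augmented Qeq system is ill-conditioned; review hardness/width parameters"
        )
    lu = lu_factor(M)
    rhs = np.concatenate([-system.chi, [system.q_total]])
    sol = lu_solve(lu, rhs)
    Q, lam = sol[:n], float(sol[n])
    J, sigma = system.electro.per_atom(system.structure.species)
    Aq = system.A - np.diag(J)  # pair kernel + 1/(sigma sqrt(pi)) self diagonal
    e_elec = 0.5 * float(Q @ Aq @ Q)
    return QeqSolution(charges=Q, lagrange=lam, e_elec=e_elec, _lu=lu, _system=system)


@dataclass
class QeqDerivatives:
    """Implicit derivatives of the equilibrated charges."""

    dq_dchi: np.ndarray            # (N, N): dQ_i / dchi_m
    dq_dJ: dict[str, np.ndarray]   # element -> (N,)
    dq_dr: np.ndarray              # (N, N, 3): dQ_i / dR_{k,alpha}, e/Bohr


def solution_derivatives(
    system: QeqSystem, solution: QeqSolution, structure: Structure
) -> QeqDerivatives:
    """dQ/dchi, dQ/dJ and dQ/dR by differentiating the augmented system.

    Each right-hand side costs one triangular solve on the stored LU handle.
    """
    if solution._system is not system:
        raise QeqError("stale factorization: solution does not belong to this system")
    n = system.A.shape[0]
    Q = solution.charges
    lu = solution._lu

    rhs = np.zeros((n + 1, n))
    rhs[:n, :] = -np.eye(n)
    dq_dchi = lu_solve(lu, rhs)[:n, :].T  # [i, m] = dQ_i/dchi_m

    dq_dJ = {}
    species = np.array(structure.species)
    for el in sorted(set(structure.species)):
        mask = (species == el).astype(float)
        r = np.zeros(n + 1)
        r[:n] = -mask * Q
        dq_dJ[el] = lu_solve(lu, r)[:n]

    # dA/dR_k has nonzero entries only in row/column k:
    # (dA/dR_ka . Q)_i = g[i,k,a] Q_k * (-1)   for i != k   (dA_ik/dr_k = -g[i,k])
    # (dA/dR_ka . Q)_k = sum_j g[k,j,a] Q_j
    G = system.pair_grad
    rhs = np.zeros((n + 1, n * 3))
    for k in range(n):
        block = -G[:, k, :] * Q[k]           # (N, 3) rows i != k
        block[k, :] = G[k, :, :].T @ Q        # row k
        rhs[:n, 3 * k : 3 * k + 3] = -block
    sol = lu_solve(lu, rhs)[:n, :]
    dq_dr = sol.reshape(n, n, 3)

    return QeqDerivatives(dq_dchi=dq_dchi, dq_dJ=dq_dJ, dq_dr=dq_dr)


# ---------------------------------------------------------------------------
# electrostatic energies
# ---------------------------------------------------------------------------

def _screen_correction(
    structure: Structure,
    charges: np.ndarray,
    gamma: np.ndarray,
    screening: ScreeningSpec,
    with_grads: bool,
):
    """sum over pairs within outer radius of (S(r) - 1) k(r) Q_i Q_j."""
    nl = build_neighbor_list(structure, screening.outer)
    e = 0.0
    dE_dr = np.zeros((structure.n_atoms, 3)) if with_grads else None
    dE_dq = np.zeros(structure.n_atoms) if with_grads else None
    if nl.n_pairs == 0:
        return e, dE_dr, dE_dq
    i, j = nl.i, nl.j
    r_ang = nl.dist
    r_bohr = r_ang * ANGSTROM_TO_BOHR
    g = gamma[i, j]
    S, dS_ang = screening.switch(r_ang)
    k = pair_kernel(r_bohr, g)
    w = charges[i] * charges[j]
    e = float(np.sum((S - 1.0) * k * w))
    if with_grads:
        dk = pair_kernel_deriv(r_bohr, g)
        dS = dS_ang / ANGSTROM_TO_BOHR  # per Bohr
        dpair = (dS * k + (S - 1.0) * dk) * w  # d/dr_bohr of pair term
        u = nl.vec / r_ang[:, None]  # unit vector i -> j image
        for p in range(nl.n_pairs):
            f = dpair[p] * u[p]
            dE_dr[j[p]] += f
            dE_dr[i[p]] -= f
        contrib = (S - 1.0) * k
        np.add.at(dE_dq, i, contrib * charges[j])
        np.add.at(dE_dq, j, contrib * charges[i])
    return e, dE_dr, dE_dq


def electrostatic_energy(
    structure: Structure,
    charges: np.ndarray,
    electro: ElementElectro,
    screening: Optional[ScreeningSpec] = None,
    accuracy: float = 1e-8,
    with_grads: bool = False,
):
    """Electrostatic energy of the Gaussian charges (Ha).

    Cluster: sum_{i<j} S(r_ij) k(r_ij) Q_i Q_j + sum_i Q_i^2/(2 sigma_i sqrt(pi));
    periodic: Ewald-summed equivalent (neutral cells only) with the screening
    applied as a short-range pair correction.  With ``with_grads`` the return is
    (E, dE/dR in Ha/Bohr, dE/dQ in Ha/e).
    """
    charges = np.asarray(charges, dtype=float)
    n = structure.n_atoms
    if charges.shape != (n,):
        raise ValueError("charges must have one entry per atom")
    if all(structure.pbc) and abs(charges.sum()) > 1e-6:
        raise ValueError("periodic electrostatics requires a neutral cell")
    _, sigma = electro.per_atom(structure.species)
    gamma = np.sqrt(sigma[:, None] ** 2 + sigma[None, :] ** 2)
    B, G = _pair_matrix(structure, gamma, accuracy=accuracy, with_grad=with_grads)
    e = 0.5 * float(charges @ B @ charges) + float(np.sum(charges**2 / (2 * sigma * _SQRT_PI)))
    if with_grads:
        dE_dr = np.einsum("ijd,i,j->id", G, charges, charges)
        dE_dq = B @ charges + charges / (sigma * _SQRT_PI)
    if screening is not None:
        es, dr, dq = _screen_correction(structure, charges, gamma, screening, with_grads)
        e += es
        if with_grads:
            dE_dr += dr
            dE_dq += dq
    if with_grads:
        return e, dE_dr, dE_dq
    return e


def ewald_energy(
    structure: Structure,
    charges: np.ndarray,
    electro: ElementElectro,
    accuracy: float = 1e-6,
    eta: Optional[float] = None,
) -> float:
    """Ewald-summed electrostatic energy of a neutral periodic cell (Ha).

    The splitting width ``eta`` (Bohr) is auto-chosen from the accuracy target
    when not given; the result is eta-independent to within the target.
    """
    if accuracy <= 0:
        raise ValueError("accuracy must be positive")
    if not all(structure.pbc):
        raise ValueError("ewald_energy requires periodicity in all three directions")
    charges = np.asarray(charges, dtype=float)
    if abs(charges.sum()) > 1e-6:
        raise ValueError("non-neutral periodic cell")
    _, sigma = electro.per_atom(structure.species)
    gamma = np.sqrt(sigma[:, None] ** 2 + sigma[None, :] ** 2)
    if eta is None:
        eta = _auto_eta(structure.cell * ANGSTROM_TO_BOHR, float(gamma.max()))
    B, _ = _ewald_pair_matrix(structure, gamma, eta, accuracy, with_grad=False)
    return 0.5 * float(charges @ B @ charges) + float(
        np.sum(charges**2 / (2 * sigma * _SQRT_PI))
    )
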