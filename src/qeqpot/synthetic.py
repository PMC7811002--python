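"""Ground-truth surrogate and benchmark scenario generators.

The surrogate is a known charge-equilibration model with analytic labels:

* electronegativities  chi_i = chi0_e + c_e * coord_i, with
  coord_i = sum_j fc(r_ij) a smooth coordination count;
* charges from the constrained Qeq solve;
* energy  E = E_Qeq(unscreened, incl. chi.Q + J Q^2/2) + sum_pairs Morse(r) fc(r)
  + sum_i kappa_e Q_i^2 coord_i;
* forces fully analytic (implicit differentiation through the Qeq solve;
  the equilibrated part uses the envelope theorem).

The kappa Q^2 coord term makes the short-range energy genuinely
charge-dependent, so only charge-aware models can represent the labels; the
chi.Q term carries the large first-order energy difference between charge
states (the ionization-energy analogue).

Scenarios produce sub-populations whose discriminating feature is global
(total charge, or a compositional change far outside every local cutoff):

* ``chain_protonation``: linear C10H2 (neutral) vs C10H3+ (+1)
* ``trimer_ions``: Ag3 with Q_tot = +1 and -1 over identical geometries
* ``cluster_vacancy``: Na9Cl8+ rod vs Na8Cl8+ (far-end Na removed, charge kept)
* ``doped_slab``: periodic neutral Na/Cl slab with/without a deep K dopant
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .descriptors import cutoff_function
from .qeq import ElementElectro, build_system, electrostatic_energy, solution_derivatives, solve_qeq
from .structures import ReferenceRecord, Structure, build_neighbor_list, neighbor_arrays, perturb
from .units import ANGSTROM_TO_BOHR, BOHR

__all__ = [
    "COVALENT_RADII",
    "GroundTruth",
    "Scenario",
    "default_truth",
    "label",
    "generate",
    "SCENARIO_NAMES",
]

#: Covalent radii in Angstrom (Cordero et al. 2008), used as Gaussian widths.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "K": 2.03, "Ca": 1.76, "Ag": 1.45, "Au": 1.36,
}

SCENARIO_NAMES = ("chain_protonation", "trimer_ions", "cluster_vacancy", "doped_slab")

# fixed, documented surrogate parameter slots, assigned to sorted(elements)
_CHI0 = (0.15, -0.10, 0.03)        # Ha/e
_COUPLING = (0.030, -0.050, 0.015)  # Ha/e per coordination
_HARDNESS = (0.45, 0.30, 0.55)      # Ha/e^2
_KAPPA = (0.10, 0.20, 0.12)         # Ha/e^2 per coordination
# Morse well depths (Ha) by sorted-slot index pair; unlike pairs bind more
# strongly (ionic-like), and the first hetero pair is the stiffest
_MORSE_D = {(0, 0): 0.06, (1, 1): 0.06, (2, 2): 0.06,
            (0, 1): 0.30, (0, 2): 0.14, (1, 2): 0.14}
_MORSE_A = 1.5                      # 1/A


@dataclass
class GroundTruth:
    """Fixed surrogate parameters; all labels derive from these."""

    chi0: dict[str, float]
    coupling: dict[str, float]
    electro: ElementElectro
    kappa: dict[str, float]
    #: (element, element) sorted tuple -> (D Ha, a 1/A, r0 A)
    morse: dict[tuple[str, str], tuple[float, float, float]]
    cutoff: float = 4.23  # A (8 Bohr, rounded as in the cutoff-sphere figure)


def default_truth(elements: list[str]) -> GroundTruth:
    """Documented fixed parameters for 1-3 elements (pure function).

    Gaussian widths are the covalent radii; Morse minima sit at the sum of the
    covalent radii so the scenario templates are near their equilibria.
    """
    elements = sorted(set(elements))
    if not 1 <= len(elements) <= 3:
        raise ValueError("default_truth supports 1-3 elements")
    for el in elements:
        if el not in COVALENT_RADII:
            raise KeyError(f"no covalent radius tabulated for {el!r}")
    chi0, coupling, hardness, kappa = {}, {}, {}, {}
    for k, el in enumerate(elements):
        chi0[el] = _CHI0[k]
        coupling[el] = _COUPLING[k]
        hardness[el] = _HARDNESS[k]
        kappa[el] = _KAPPA[k]
    width = {el: COVALENT_RADII[el] * ANGSTROM_TO_BOHR for el in elements}
    morse = {}
    for a, e1 in enumerate(elements):
        for b, e2 in enumerate(elements[a:], start=a):
            r0 = COVALENT_RADII[e1] + COVALENT_RADII[e2]
            morse[(e1, e2)] = (_MORSE_D[(a, b)], _MORSE_A, r0)
    return GroundTruth(
        chi0=chi0,
        coupling=coupling,
        electro=ElementElectro(hardness=hardness, width=width),
        kappa=kappa,
        morse=morse,
    )


def _relax_probe(truth: "GroundTruth", structure: Structure, probe: int,
                 fmax: float = 1e-5, alpha: float = 0.15, max_iter: int = 4000):
    """Steepest-descent relaxation of one atom on the surrogate; used to centre
    sampling on the equilibria (relaxation endpoints are part of the data)."""
    s = structure.copy()
    for _ in range(max_iter):
        f = label(truth, s).forces[probe]
        if np.abs(f).max() <= fmax:
            break
        s.positions[probe] += alpha * f * BOHR
    return s.positions[probe].copy()


def _coordination(structure: Structure, cutoff: float):
    """coord_i = sum_j fc(r_ij) and dcoord[m, k, :] = dcoord_m/dR_k (1/A)."""
    n = structure.n_atoms
    nl = build_neighbor_list(structure, cutoff)
    nbrs = neighbor_arrays(structure, nl)
    coord = np.zeros(n)
    dcoord = np.zeros((n, n, 3))
    for m in range(n):
        jdx, vecs, dists = nbrs[m]
        if len(jdx) == 0:
            continue
        fc, dfc = cutoff_function(dists, cutoff)
        coord[m] = fc.sum()
        unit = vecs / dists[:, None]
        contrib = dfc[:, None] * unit
        for t, j in enumerate(jdx):
            dcoord[m, j] += contrib[t]
            dcoord[m, m] -= contrib[t]
    return coord, dcoord


def label(truth: GroundTruth, structure: Structure) -> ReferenceRecord:
    """Analytic reference energy (Ha), forces (Ha/Bohr) and charges (e)."""
    for el in structure.species:
        if el not in truth.chi0:
            raise KeyError(f"element {el!r} not covered by the ground truth")
    n = structure.n_atoms
    species = structure.species
    coord, dcoord = _coordination(structure, truth.cutoff)
    c_el = np.array([truth.coupling[el] for el in species])
    chi = np.array([truth.chi0[el] for el in species]) + c_el * coord

    system = build_system(structure, chi, truth.electro)
    sol = solve_qeq(system)
    Q = sol.charges
    e_elec, delec_dr, _ = electrostatic_energy(
        structure, Q, truth.electro, screening=None, with_grads=True
    )
    # full equilibration energy: the chi.Q + J Q^2/2 terms carry the
    # first-order (odd in Q) charge-transfer energy that separates charge
    # states; without them 2G models would fail only at noise level
    J_el, _sig = truth.electro.per_atom(species)
    e_qeq = e_elec + float(chi @ Q) + 0.5 * float(J_el @ Q**2)

    # Morse pair energy with cutoff switch (smooth at the cutoff)
    nl = build_neighbor_list(structure, truth.cutoff)
    e_morse = 0.0
    dE_dr = delec_dr.copy()  # Ha/Bohr accumulator
    for p in range(nl.n_pairs):
        i, j = int(nl.i[p]), int(nl.j[p])
        r = nl.dist[p]
        D, a, r0 = truth.morse[tuple(sorted((species[i], species[j])))]
        fc, dfc = cutoff_function(r, truth.cutoff)
        ex = np.exp(-a * (r - r0))
        core = D * ((1.0 - ex) ** 2 - 1.0)
        dcore = 2.0 * D * a * (1.0 - ex) * ex
        e_morse += core * fc
        dpair_ang = dcore * fc + core * dfc  # Ha/A
        u = nl.vec[p] / r
        f = dpair_ang * u * BOHR  # -> Ha/Bohr
        dE_dr[j] += f
        dE_dr[i] -= f

    kap = np.array([truth.kappa[el] for el in species])
    e_kappa = float(np.sum(kap * Q**2 * coord))
    energy = e_qeq + e_morse + e_kappa

    dchi_dr = c_el[:, None, None] * dcoord * BOHR  # (m, k, 3) Ha/e per Bohr
    # E_qeq is stationary in Q on the constraint surface (envelope theorem),
    # so its gradient is the explicit part only: dE_elec/dR|_Q + Q . dchi/dR
    dE_dr += np.einsum("i,ikc->kc", Q, dchi_dr)
    # the kappa term is not part of the equilibrated objective: chain dQ/dR
    w = 2.0 * kap * Q * coord
    derivs = solution_derivatives(system, sol, structure)
    dq_dr = derivs.dq_dr + np.einsum("im,mkc->ikc", derivs.dq_dchi, dchi_dr)
    dE_dr += np.einsum("i,ikc->kc", w, dq_dr)
    # explicit coordination dependence of the kappa term
    dE_dr += np.einsum("i,ikc->kc", kap * Q**2, dcoord * BOHR)

    return ReferenceRecord(structure, energy=float(energy), forces=-dE_dr, charges=Q.copy())


# ---------------------------------------------------------------------------
# scenario templates
# ---------------------------------------------------------------------------

def _chain_templates():
    dcc = 2 * COVALENT_RADII["C"]
    dch = COVALENT_RADII["C"] + COVALENT_RADII["H"]
    xs = np.arange(10) * dcc
    pos = [(x, 0.0, 0.0) for x in xs]
    species = ["C"] * 10
    neutral = Structure(
        species + ["H", "H"],
        np.array(pos + [(-dch, 0.0, 0.0), (xs[-1] + dch, 0.0, 0.0)]),
        total_charge=0.0,
        info={"subpop": "neutral"},
    )
    # protonated terminus: CH2-like end group
    hx, hy = dch * 0.5, dch * 0.87
    cation = Structure(
        species + ["H", "H", "H"],
        np.array(
            pos
            + [(-dch, 0.0, 0.0), (xs[-1] + hx, hy, 0.0), (xs[-1] + hx, -hy, 0.0)]
        ),
        total_charge=1.0,
        info={"subpop": "cation"},
    )
    return [neutral, cation]


def _trimer_template():
    d = 2 * COVALENT_RADII["Ag"]
    pos = np.array(
        [(0.0, 0.0, 0.0), (d, 0.0, 0.0), (d / 2, d * np.sqrt(3) / 2, 0.0)]
    )
    return Structure(["Ag"] * 3, pos)


def _rod_templates():
    """Elongated 2x2x(4+1) rock-salt rod: Na9Cl8 (+1) and Na8Cl8 (+1)."""
    a = COVALENT_RADII["Na"] + COVALENT_RADII["Cl"]
    species, pos = [], []
    for k in range(4):
        for i in range(2):
            for j in range(2):
                species.append("Na" if (i + j + k) % 2 == 0 else "Cl")
                pos.append((i * a, j * a, k * a))
    species.append("Na")  # capping atom continuing the rod (parity even)
    pos.append((0.0, 0.0, 4 * a))
    removed = len(species) - 1
    probe = 0  # Na at the opposite end
    full = Structure(
        species, np.array(pos), total_charge=1.0,
        info={"subpop": "full", "probe_index": probe},
    )
    reduced = Structure(
        species[:removed], np.array(pos[:removed]), total_charge=1.0,
        info={"subpop": "vacancy", "probe_index": probe},
    )
    return full, reduced, removed, probe


def _slab_templates():
    """3x3x2 rock-salt slab + 2-atom Na adsorbate; dopant K deep in the slab."""
    a = COVALENT_RADII["Na"] + COVALENT_RADII["Cl"]
    species, pos = [], []
    for l in range(2):
        for i in range(3):
            for j in range(3):
                species.append("Na" if (i + j + l) % 2 == 0 else "Cl")
                pos.append((i * a, j * a, l * a))
    n_sub = len(species)
    # adsorbate dimer above the top-layer Cl at (0, 0, a)
    species += ["Na", "Na"]
    pos += [(0.0, 0.0, a + 0.85 * a), (0.0, 0.0, a + 1.75 * a)]
    cell = np.diag([3 * a, 3 * a, 6 * a + 8.0])
    undoped = Structure(
        species, np.array(pos), cell=cell, pbc=(True, True, True),
        total_charge=0.0, info={"subpop": "undoped"},
    )
    doped_species = list(species)
    dop_site = 1 * 3 + 1  # bottom layer (1, 1), a Na site, far below the adsorbate
    assert doped_species[dop_site] == "Na"
    doped_species[dop_site] = "K"
    doped = Structure(
        doped_species, np.array(pos), cell=cell, pbc=(True, True, True),
        total_charge=0.0, info={"subpop": "doped"},
    )
    return undoped, doped, n_sub


@dataclass
class Scenario:
    """A named benchmark scenario emitting >= 2 sub-populations."""

    name: str
    n: int = 100
    sigma: Optional[float] = None  # None -> scenario default
    seed: int = 0
    probe_sigma: float = 0.08  # probe-atom sampling width (cluster_vacancy)

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")

    @property
    def elements(self) -> list[str]:
        return {
            "chain_protonation": ["C", "H"],
            "trimer_ions": ["Ag"],
            "cluster_vacancy": ["Na", "Cl"],
            "doped_slab": ["Na", "Cl", "K"],
        }[self.name]


def generate(scenario: Scenario, truth: GroundTruth) -> list[ReferenceRecord]:
    """Labelled records, ``scenario.n`` per sub-population, seed-deterministic.

    trimer_ions emits geometrically identical +1/-1 twins; cluster_vacancy
    applies the same displacement draw to both populations so the retained
    atoms coincide exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    records = []

    def tag(rec, **kv):
        rec.structure.info.update({"scenario": scenario.name, **kv})
        return rec

    if scenario.name == "chain_protonation":
        sigma = 0.05 if scenario.sigma is None else scenario.sigma
        for base in _chain_templates():
            for _ in range(scenario.n):
                s = perturb(base, sigma, int(rng.integers(2**31)))
                records.append(tag(label(truth, s)))

    elif scenario.name == "trimer_ions":
        sigma = 0.05 if scenario.sigma is None else scenario.sigma
        base = _trimer_template()
        for _ in range(scenario.n):
            s = perturb(base, sigma, int(rng.integers(2**31)))
            for q, sub in ((1.0, "cation"), (-1.0, "anion")):
                twin = s.copy()
                twin.total_charge = q
                twin.info["subpop"] = sub
                records.append(tag(label(truth, twin)))

    elif scenario.name == "cluster_vacancy":
        sigma = 0.05 if scenario.sigma is None else scenario.sigma
        full, reduced, removed, probe = _rod_templates()
        # sample the probe around the template site and around the relaxed
        # site (the equilibria are the structures of interest, so half of the
        # probe draws are centred on the relaxation endpoint)
        relaxed = 0.5 * (
            _relax_probe(truth, full, probe) + _relax_probe(truth, reduced, probe)
        )
        centers = (full.positions[probe], relaxed)
        for _ in range(scenario.n):
            disp_seed = int(rng.integers(2**31))
            center = centers[int(rng.integers(2))]
            pf = perturb(full, sigma, disp_seed)
            pf.positions[probe] = center + rng.normal(0.0, scenario.probe_sigma, 3)
            pr = reduced.copy()
            pr.positions = pf.positions[: removed].copy()
            records.append(tag(label(truth, pf)))
            records.append(tag(label(truth, pr)))

    elif scenario.name == "doped_slab":
        sig_sub = 0.02 if scenario.sigma is None else scenario.sigma
        sig_ads = 0.1
        undoped, doped, n_sub = _slab_templates()
        for base in (undoped, doped):
            for _ in range(scenario.n):
                s = base.copy()
                s.positions[:n_sub] += rng.normal(0.0, sig_sub, (n_sub, 3))
                s.positions[n_sub:] += rng.normal(0.0, sig_ads, (s.n_atoms - n_sub, 3))
                records.append(tag(label(truth, s)))

    return records
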