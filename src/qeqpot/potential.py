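"""2G/3G/4G potentials: charges, total energy, analytic forces, optimization.

Generations:

* 2G — E = sum_i E_i(G_i); no charges, no electrostatics.
* 3G — per-atom charges straight from atomic networks (optionally rescaled
  uniformly to the total charge); E = E_elec(screened) + sum_i E_i(G_i).
* 4G — atomic networks predict electronegativities chi_i; a constrained
  charge equilibration distributes Q_tot; E = E_elec(screened)
  + sum_i E_i(G_i, Q_i).  Forces include the dE/dQ . dQ/dR chain through the
  equilibration solve (implicit differentiation).

Energies in Ha, forces in Ha/Bohr, geometry in Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import atomic_nets as nets
from .atomic_nets import NetworkParams, init_network
from .descriptors import AcsfParams, symmetry_functions
from .qeq import (
    ElementElectro,
    ScreeningSpec,
    build_system,
    electrostatic_energy,
    solution_derivatives,
    solve_qeq,
)
from .structures import Structure, build_neighbor_list
from .units import BOHR

__all__ = [
    "PotentialModel",
    "ScreeningSpec",
    "OptimizeResult",
    "make_model",
    "predict_charges",
    "total_energy",
    "forces",
    "geometry_optimize",
]

GENERATIONS = ("2g", "3g", "4g")
CHECKPOINT_VERSION = 1


@dataclass
class PotentialModel:
    """Parameter container for one trained (or initialized) potential."""

    generation: str
    acsf: dict[str, AcsfParams]
    energy_nets: dict[str, NetworkParams]
    charge_nets: Optional[dict[str, NetworkParams]] = None
    electro: Optional[ElementElectro] = None
    screening: Optional[ScreeningSpec] = None
    charge_mode: str = "scaled"  # 3G only: "scaled" | "raw"
    energy_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.generation = self.generation.lower()
        if self.generation not in GENERATIONS:
            raise ValueError(f"generation must be one of {GENERATIONS}")
        if self.generation in ("3g", "4g"):
            if self.charge_nets is None or self.electro is None:
                raise ValueError(f"{self.generation} model needs charge nets and electro table")
        if self.generation == "2g" and self.electro is not None:
            raise ValueError("2G models carry no electrostatic parameters")
        for el, p in self.acsf.items():
            want = p.n_functions + (1 if self.generation == "4g" else 0)
            if self.energy_nets[el].n_inputs != want:
                raise ValueError(
                    f"energy net for {el} expects {self.energy_nets[el].n_inputs} inputs, "
                    f"descriptors provide {want}"
                )

    @property
    def elements(self) -> list[str]:
        return sorted(self.acsf)

    @property
    def cutoff(self) -> float:
        return max(p.cutoff for p in self.acsf.values())

    def shift_energy(self, species: list[str]) -> float:
        return sum(self.energy_shift.get(el, 0.0) for el in species)

    # -- checkpoint -------------------------------------------------------
    def save(self, path) -> None:
        def net_blob(n: NetworkParams):
            return {"layer_sizes": list(n.layer_sizes), "flat": n.to_flat().tolist()}

        blob = {
            "format": "qeqpot-checkpoint",
            "version": CHECKPOINT_VERSION,
            "generation": self.generation,
            "charge_mode": self.charge_mode,
            "acsf": {
                el: {
                    "cutoff": p.cutoff,
                    "radial": [list(t) for t in p.radial],
                    "angular": [[list(t[0]), t[1], t[2], t[3]] for t in p.angular],
                }
                for el, p in self.acsf.items()
            },
            "energy_nets": {el: net_blob(n) for el, n in self.energy_nets.items()},
            "charge_nets": None
            if self.charge_nets is None
            else {el: net_blob(n) for el, n in self.charge_nets.items()},
            "electro": None
            if self.electro is None
            else {"hardness": self.electro.hardness, "width": self.electro.width},
            "screening": None
            if self.screening is None
            else {"inner": self.screening.inner, "outer": self.screening.outer},
            "energy_shift": self.energy_shift,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "PotentialModel":
        with open(path) as fh:
            blob = json.load(fh)
        if blob.get("format") != "qeqpot-checkpoint":
            raise ValueError(f"{path} is not a qeqpot checkpoint")

        def unnet(b):
            return NetworkParams.from_flat(np.array(b["flat"]), tuple(b["layer_sizes"]))

        acsf = {
            el: AcsfParams(
                element=el,
                radial=[(t[0], float(t[1]), float(t[2])) for t in a["radial"]],
                angular=[
                    ((t[0][0], t[0][1]), float(t[1]), float(t[2]), int(t[3]))
                    for t in a["angular"]
                ],
                cutoff=float(a["cutoff"]),
            )
            for el, a in blob["acsf"].items()
        }
        return cls(
            generation=blob["generation"],
            acsf=acsf,
            energy_nets={el: unnet(b) for el, b in blob["energy_nets"].items()},
            charge_nets=None
            if blob["charge_nets"] is None
            else {el: unnet(b) for el, b in blob["charge_nets"].items()},
            electro=None
            if blob["electro"] is None
            else ElementElectro(blob["electro"]["hardness"], blob["electro"]["width"]),
            screening=None
            if blob["screening"] is None
            else ScreeningSpec(blob["screening"]["inner"], blob["screening"]["outer"]),
            charge_mode=blob.get("charge_mode", "scaled"),
            energy_shift=blob.get("energy_shift", {}),
        )


def make_model(
    generation: str,
    acsf: dict[str, AcsfParams],
    seed: int = 0,
    electro: Optional[ElementElectro] = None,
    screening: Optional[ScreeningSpec] = None,
    charge_mode: str = "scaled",
    hidden: tuple[int, int] = (15, 15),
) -> PotentialModel:
    """Fresh model with seed-deterministic network initialization."""
    generation = generation.lower()
    rngseed = np.random.default_rng(seed)
    energy_nets, charge_nets = {}, {}
    for k, el in enumerate(sorted(acsf)):
        nd = acsf[el].n_functions
        extra = 1 if generation == "4g" else 0
        energy_nets[el] = init_network(nd + extra, seed=int(rngseed.integers(2**31)), hidden=hidden)
        if generation in ("3g", "4g"):
            charge_nets[el] = init_network(nd, seed=int(rngseed.integers(2**31)), hidden=hidden)
    return PotentialModel(
        generation=generation,
        acsf=acsf,
        energy_nets=energy_nets,
        charge_nets=charge_nets if generation in ("3g", "4g") else None,
        electro=electro if generation in ("3g", "4g") else None,
        screening=screening if generation in ("3g", "4g") else None,
        charge_mode=charge_mode,
    )


def _check_elements(model: PotentialModel, structure: Structure):
    for el in structure.species:
        if el not in model.acsf:
            raise KeyError(f"element {el!r} unknown to the model")


def _evaluate(model: PotentialModel, structure: Structure, need_forces: bool,
              drop_short_q_term: bool = False):
    """Shared evaluation path; returns a dict of everything computed."""
    _check_elements(model, structure)
    n = structure.n_atoms
    gen = model.generation
    nl = build_neighbor_list(structure, model.cutoff)
    desc = symmetry_functions(structure, nl, model.acsf, gradients=need_forces)
    species = structure.species

    charges = None
    e_elec = None
    chi = None
    system = sol = None

    if gen == "3g":
        charges = np.array(
            [nets.forward(model.charge_nets[species[a]], desc.values[a]) for a in range(n)]
        )
        if model.charge_mode == "scaled":
            charges = charges + (structure.total_charge - charges.sum()) / n
    elif gen == "4g":
        chi = np.array(
            [nets.forward(model.charge_nets[species[a]], desc.values[a]) for a in range(n)]
        )
        system = build_system(structure, chi, model.electro)
        sol = solve_qeq(system)
        charges = sol.charges

    if gen in ("3g", "4g"):
        if need_forces:
            e_elec, delec_dr, delec_dq = electrostatic_energy(
                structure, charges, model.electro, model.screening, with_grads=True
            )
        else:
            e_elec = electrostatic_energy(
                structure, charges, model.electro, model.screening
            )

    # short-range atomic energies
    xs = []
    for a in range(n):
        x = desc.values[a]
        if gen == "4g":
            x = np.concatenate([x, [charges[a]]])
        xs.append(x)
    e_short = sum(nets.forward(model.energy_nets[species[a]], xs[a]) for a in range(n))
    e_short += model.shift_energy(species)
    e_total = e_short + (e_elec or 0.0)

    out = {
        "energy": e_total,
        "charges": charges,
        "e_elec": e_elec,
        "e_short": e_short,
    }
    if not need_forces:
        return out

    # ---- analytic forces (Ha/Bohr); descriptor grads are A^-1 -> x BOHR ----
    dE_dr = np.zeros((n, 3))
    # per-atom energy-net input gradients
    dy_dx = [nets.gradients(model.energy_nets[species[a]], xs[a])[0] for a in range(n)]
    for a in range(n):
        nd = model.acsf[species[a]].n_functions
        # descriptor chain: dG_a/dR has shape (nd, n, 3)
        dE_dr += np.einsum("d,dkc->kc", dy_dx[a][:nd], desc.gradients[a]) * BOHR

    if gen in ("3g", "4g"):
        dE_dr += delec_dr
        # adjoint weights on charges
        c = delec_dq.copy()
        if gen == "4g" and not drop_short_q_term:
            c += np.array([dy_dx[a][-1] for a in range(n)])

        # dQ/dR (e/Bohr), assembled per generation
        dchi_dr = None
        if gen == "4g":
            derivs = solution_derivatives(system, sol, structure)
            # chi chain: dchi_m/dR = dnet/dG . dG_m/dR
            dchi_dr = np.zeros((n, n, 3))
            for m in range(n):
                g_in = nets.gradients(model.charge_nets[species[m]], desc.values[m])[0]
                dchi_dr[m] = np.einsum("d,dkc->kc", g_in, desc.gradients[m]) * BOHR
            dq_dr = derivs.dq_dr + np.einsum("im,mkc->ikc", derivs.dq_dchi, dchi_dr)
        else:  # 3G: charges straight from nets
            dq_dr = np.zeros((n, n, 3))
            for m in range(n):
                g_in = nets.gradients(model.charge_nets[species[m]], desc.values[m])[0]
                dq_dr[m] = np.einsum("d,dkc->kc", g_in, desc.gradients[m]) * BOHR
            if model.charge_mode == "scaled":
                dq_dr = dq_dr - dq_dr.mean(axis=0, keepdims=True)
        dE_dr += np.einsum("i,ikc->kc", c, dq_dr)

    out["forces"] = -dE_dr
    return out


def predict_charges(model: PotentialModel, structure: Structure) -> np.ndarray:
    """Per-atom charges (e).  4G: Qeq over predicted electronegativities, so
    the sum matches Q_tot exactly; 3G: direct net outputs (scaled or raw)."""
    if model.generation == "2g":
        raise ValueError("no charges in 2G")
    return _evaluate(model, structure, need_forces=False)["charges"]


def total_energy(model: PotentialModel, structure: Structure):
    """(E_total Ha, per-atom charges or None, E_elec Ha or None)."""
    out = _evaluate(model, structure, need_forces=False)
    return out["energy"], out["charges"], out["e_elec"]


def forces(model: PotentialModel, structure: Structure,
           drop_short_q_term: bool = False) -> np.ndarray:
    """Analytic forces -dE/dR (Ha/Bohr).

    ``drop_short_q_term`` is a diagnostic switch that omits the
    dE_short/dQ . dQ/dR chain term (it must break force-energy consistency
    for 4G models; used by the test suite only).
    """
    return _evaluate(model, structure, need_forces=True,
                     drop_short_q_term=drop_short_q_term)["forces"]


@dataclass
class OptimizeResult:
    structure: Structure
    energies: list[float]
    converged: bool
    n_steps: int


def geometry_optimize(
    model: PotentialModel,
    structure: Structure,
    threshold: float = 1e-4,
    max_steps: int = 1000,
    mask: Optional[np.ndarray] = None,
    initial_step: float = 1e-2,
) -> OptimizeResult:
    """Steepest descent with backtracking until max |F| <= threshold (Ha/Bohr).

    ``mask`` selects movable atoms (True = free); energies along accepted steps
    are non-increasing.  Non-convergence is flagged, not raised.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cur = structure.copy()
    if mask is None:
        mask = np.ones(cur.n_atoms, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    alpha = initial_step  # Bohr^2/Ha
    out = _evaluate(model, cur, need_forces=True)
    e_cur = out["energy"]
    f_cur = out["forces"] * mask[:, None]
    energies = [e_cur]
    accepted = 0
    for _ in range(max_steps):
        fmax = np.abs(f_cur).max()
        if fmax <= threshold:
            return OptimizeResult(cur, energies, True, accepted)
        stepped = False
        while alpha > 1e-12:
            trial = cur.copy()
            trial.positions = cur.positions + alpha * f_cur * BOHR  # Bohr -> A
            t_out = _evaluate(model, trial, need_forces=True)
            if t_out["energy"] <= e_cur:
                cur, e_cur = trial, t_out["energy"]
                f_cur = t_out["forces"] * mask[:, None]
                energies.append(e_cur)
                alpha *= 1.1
                accepted += 1
                stepped = True
                break
            alpha *= 0.5
        if not stepped:
            return OptimizeResult(cur, energies, False, accepted)
    converged = bool(np.abs(f_cur).max() <= threshold)
    return OptimizeResult(cur, energies, converged, accepted)
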