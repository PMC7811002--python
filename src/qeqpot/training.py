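"""Two-stage training.

Stage 1 fits the charge model: for 4G, electronegativity networks plus the
per-element hardness (softplus-positive) so that the equilibrated charges
reproduce the reference charges, with gradients flowing through the Qeq solve
by implicit differentiation; for 3G the networks are fit directly to the
reference charges.

Stage 2 freezes the charge model and fits the short-range energy networks to
the residual energy E_ref - E_elec and to the total forces; the force-loss
gradient carries every chain-rule path of the analytic forces (including the
dE_short/dQ . dQ/dR term for 4G).

Records are grouped into blocks of identical (composition, atom order) so all
linear solves and network evaluations batch over records; semantics are
identical to the single-structure API, which the tests cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import atomic_nets as nets
from .atomic_nets import NetworkParams
from .descriptors import symmetry_functions
from .potential import PotentialModel, forces as model_forces, predict_charges, total_energy
from .qeq import build_system, electrostatic_energy, solution_derivatives, solve_qeq
from .structures import ReferenceRecord, build_neighbor_list
from .units import BOHR, HARTREE

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "Metrics",
    "split_dataset",
    "fit_charge_stage",
    "fit_short_range_stage",
    "evaluate",
]

_SQRT_PI = np.sqrt(np.pi)


@dataclass
class TrainConfig:
    split_fraction: float = 0.9
    lr: float = 0.01
    lr_final: Optional[float] = None  # geometric decay target; None = constant
    epochs: int = 2000
    batch_size: int = 0          # 0 = full batch
    patience: int = 0            # 0 = no early stopping
    val_fraction: float = 0.1    # carved out of the training records
    w_e: float = 1.0
    w_f: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")
        if self.w_e < 0 or self.w_f < 0 or (self.w_e == 0 and self.w_f == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


@dataclass
class Metrics:
    """Error metrics on one record set (RMSE and MAE, both always reported)."""

    n_records: int
    energy_rmse: Optional[float] = None  # meV/atom
    energy_mae: Optional[float] = None
    force_rmse: Optional[float] = None   # eV/A
    force_mae: Optional[float] = None
    charge_rmse: Optional[float] = None  # 10^-3 e
    charge_mae: Optional[float] = None

    def __post_init__(self):
        for v in (self.energy_rmse, self.energy_mae, self.force_rmse,
                  self.force_mae, self.charge_rmse, self.charge_mae):
            if v is not None and v < 0:
                raise ValueError("metrics must be non-negative")


def split_dataset(records: list[ReferenceRecord], fraction: float, seed: int):
    """Disjoint, exhaustive, deterministic split, stratified by scenario tag."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = {}
    for k, rec in enumerate(records):
        key = (rec.structure.info.get("scenario"), rec.structure.info.get("subpop"))
        groups.setdefault(key, []).append(k)
    train_idx, test_idx = [], []
    for key in sorted(groups, key=str):
        idx = np.array(groups[key])
        idx = idx[rng.permutation(len(idx))]
        ntr = int(round(fraction * len(idx)))
        if len(idx) > 1:
            ntr = min(max(ntr, 1), len(idx) - 1)
        train_idx.extend(idx[:ntr])
        test_idx.extend(idx[ntr:])
    if not train_idx or not test_idx:
        raise ValueError("split fraction yields an empty subset")
    return ([records[k] for k in sorted(train_idx)], [records[k] for k in sorted(test_idx)])


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        corr1 = 1 - self.b1**self.t
        corr2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


def _lr_at(config: TrainConfig, epoch: int) -> float:
    if config.lr_final is None or config.epochs <= 1:
        return config.lr
    t = epoch / (config.epochs - 1)
    return config.lr * (config.lr_final / config.lr) ** t


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return y + np.log(-np.expm1(-y))


# ---------------------------------------------------------------------------
# record blocks
# ---------------------------------------------------------------------------

def _block_key(rec: ReferenceRecord):
    return ("P" if any(rec.structure.pbc) else "C",) + tuple(rec.structure.species)


def _group_records(records):
    blocks: dict[tuple, list[ReferenceRecord]] = {}
    for rec in records:
        blocks.setdefault(_block_key(rec), []).append(rec)
    return [blocks[k] for k in sorted(blocks)]


class _ChargeBlock:
    """Precomputed quantities for stage-1 training on one record block (4G)."""

    def __init__(self, model: PotentialModel, recs: list[ReferenceRecord]):
        s0 = recs[0].structure
        self.species = list(s0.species)
        self.n = s0.n_atoms
        self.B = len(recs)
        elements = sorted(set(self.species))
        self.atom_idx = {
            el: np.array([a for a, sp in enumerate(self.species) if sp == el])
            for el in elements
        }
        cutoff = model.cutoff
        G = [[] for _ in range(self.n)]
        Aaug = np.zeros((self.B, self.n + 1, self.n + 1))
        qref = np.zeros((self.B, self.n))
        qtot = np.zeros(self.B)
        _, sigma = model.electro.per_atom(self.species)
        for b, rec in enumerate(recs):
            s = rec.structure
            nl = build_neighbor_list(s, cutoff)
            ds = symmetry_functions(s, nl, model.acsf, gradients=False)
            for a in range(self.n):
                G[a].append(ds.values[a])
            sys_ = build_system(s, np.zeros(self.n), model.electro)
            Aaug[b, : self.n, : self.n] = sys_.A - np.diag(
                [model.electro.hardness[sp] for sp in self.species]
            )
            Aaug[b, : self.n, self.n] = 1.0
            Aaug[b, self.n, : self.n] = 1.0
            qref[b] = rec.charges
            qtot[b] = s.total_charge
        # X[el]: (B, n_el, nd)
        self.X = {
            el: np.stack([np.stack([G[a][b] for a in self.atom_idx[el]]) for b in range(self.B)])
            for el in elements
        }
        self.Aaug = Aaug          # J-free augmented matrices
        self.qref = qref
        self.qtot = qtot
        self.species_arr = np.array(self.species)

    def solve(self, model: PotentialModel, J: dict[str, float]):
        """Batched chi evaluation and Qeq solve; returns (chi, Q, M)."""
        chi = np.zeros((self.B, self.n))
        for el, idx in self.atom_idx.items():
            Xf = self.X[el].reshape(-1, self.X[el].shape[-1])
            chi[:, idx] = nets.forward_batch(model.charge_nets[el], Xf).reshape(self.B, -1)
        M = self.Aaug.copy()
        diag = np.array([J[sp] for sp in self.species])
        M[:, np.arange(self.n), np.arange(self.n)] += diag
        rhs = np.concatenate([-chi, self.qtot[:, None]], axis=1)
        sol = np.linalg.solve(M, rhs[..., None])[..., 0]
        return chi, sol[:, : self.n], M


def fit_charge_stage(model: PotentialModel, train: list[ReferenceRecord],
                     config: TrainConfig):
    """Stage 1: fit chi nets (4G) or charge nets (3G) to reference charges.

    Returns (model, history); history rows carry per-epoch train/val charge
    RMSE in 10^-3 e.  The model is updated in place (zero epochs = unchanged).
    """
    if model.generation == "2g":
        raise ValueError("2G models have no charge stage")
    for rec in train:
        if rec.charges is None:
            raise ValueError("stage-1 training requires reference charges")

    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(train))
    nval = max(1, int(round(config.val_fraction * len(train)))) if len(train) > 4 else 0
    val_recs = [train[k] for k in idx[:nval]]
    fit_recs = [train[k] for k in idx[nval:]]

    history = []
    if model.generation == "3g":
        _fit_charges_3g(model, fit_recs, val_recs, config, history)
        return model, history

    blocks = [_ChargeBlock(model, recs) for recs in _group_records(fit_recs)]
    vblocks = [_ChargeBlock(model, recs) for recs in _group_records(val_recs)] if val_recs else []
    n_atoms_total = sum(b.B * b.n for b in blocks)
    elements = sorted(model.charge_nets)

    params = {f"chi:{el}": model.charge_nets[el].to_flat() for el in elements}
    params["J"] = np.array([_softplus_inv(model.electro.hardness[el]) for el in elements])
    layer_sizes = {el: model.charge_nets[el].layer_sizes for el in elements}

    def sync():
        for el in elements:
            model.charge_nets[el] = NetworkParams.from_flat(params[f"chi:{el}"], layer_sizes[el])
        for k, el in enumerate(elements):
            model.electro.hardness[el] = float(_softplus(params["J"][k]))

    def rmse_on(blist):
        J = {el: float(_softplus(params["J"][k])) for k, el in enumerate(elements)}
        se, cnt = 0.0, 0
        for blk in blist:
            _, Q, _ = blk.solve(model, J)
            se += float(np.sum((Q - blk.qref) ** 2))
            cnt += blk.B * blk.n
        return np.sqrt(se / cnt) if cnt else np.nan

    opt = _Adam(params, config.lr)
    best = (np.inf, None, -1)
    for epoch in range(config.epochs):
        sync()
        J = {el: model.electro.hardness[el] for el in elements}
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        se = 0.0
        sig = 1.0 / (1.0 + np.exp(-params["J"]))  # softplus'
        for blk in blocks:
            chi, Q, M = blk.solve(model, J)
            dq = Q - blk.qref
            se += float(np.sum(dq**2))
            adj = np.concatenate([dq, np.zeros((blk.B, 1))], axis=1)
            z = np.linalg.solve(M, adj[..., None])[..., 0][:, : blk.n]  # M symmetric
            dLdchi = -2.0 * z / n_atoms_total
            for el, aidx in blk.atom_idx.items():
                Xf = blk.X[el].reshape(-1, blk.X[el].shape[-1])
                w = dLdchi[:, aidx].reshape(-1)
                grads[f"chi:{el}"] += nets.param_grad_weighted(model.charge_nets[el], Xf, w)
            for k, el in enumerate(elements):
                mask = blk.species_arr == el
                if mask.any():
                    dLdJ = -2.0 * float(np.sum(z[:, mask] * Q[:, mask])) / n_atoms_total
                    grads["J"][k] += dLdJ * sig[k]
        train_rmse = np.sqrt(se / n_atoms_total)
        val_rmse = rmse_on(vblocks) if vblocks else train_rmse
        history.append(
            {"epoch": epoch, "train_charge_rmse": train_rmse * 1e3,
             "val_charge_rmse": val_rmse * 1e3}
        )
        if val_rmse < best[0]:
            best = (val_rmse, {k: v.copy() for k, v in params.items()}, epoch)
        elif config.patience and epoch - best[2] > config.patience:
            break
        opt.lr = _lr_at(config, epoch)
        opt.step(params, grads)
    if config.epochs and best[1] is not None:
        params.update(best[1])
    sync()
    return model, history


def _fit_charges_3g(model, fit_recs, val_recs, config, history):
    """Direct net-output-vs-reference-charge fit (no Qeq in the loop)."""
    elements = sorted(model.charge_nets)
    cutoff = model.cutoff

    def gather(recs):
        X = {el: [] for el in elements}
        y = {el: [] for el in elements}
        for rec in recs:
            s = rec.structure
            ds = symmetry_functions(s, build_neighbor_list(s, cutoff), model.acsf, gradients=False)
            for a in range(s.n_atoms):
                X[s.species[a]].append(ds.values[a])
                y[s.species[a]].append(rec.charges[a])
        return (
            {el: np.array(X[el]) for el in elements if X[el]},
            {el: np.array(y[el]) for el in elements if y[el]},
        )

    Xf, yf = gather(fit_recs)
    Xv, yv = gather(val_recs) if val_recs else ({}, {})
    ntot = sum(len(v) for v in yf.values())
    params = {el: model.charge_nets[el].to_flat() for el in Xf}
    layer_sizes = {el: model.charge_nets[el].layer_sizes for el in Xf}

    def sync():
        for el in params:
            model.charge_nets[el] = NetworkParams.from_flat(params[el], layer_sizes[el])

    def rmse(X, y):
        se, cnt = 0.0, 0
        for el in X:
            p = nets.forward_batch(model.charge_nets[el], X[el])
            se += float(np.sum((p - y[el]) ** 2))
            cnt += len(y[el])
        return np.sqrt(se / cnt) if cnt else np.nan

    opt = _Adam(params, config.lr)
    best = (np.inf, None, -1)
    for epoch in range(config.epochs):
        sync()
        grads = {}
        se = 0.0
        for el in Xf:
            p = nets.forward_batch(model.charge_nets[el], Xf[el])
            d = p - yf[el]
            se += float(np.sum(d**2))
            grads[el] = nets.param_grad_weighted(model.charge_nets[el], Xf[el], 2.0 * d / ntot)
        train_rmse = np.sqrt(se / ntot)
        val_rmse = rmse(Xv, yv) if Xv else train_rmse
        history.append(
            {"epoch": epoch, "train_charge_rmse": train_rmse * 1e3,
             "val_charge_rmse": val_rmse * 1e3}
        )
        if val_rmse < best[0]:
            best = (val_rmse, {k: v.copy() for k, v in params.items()}, epoch)
        elif config.patience and epoch - best[2] > config.patience:
            break
        opt.lr = _lr_at(config, epoch)
        opt.step(params, grads)
    if config.epochs and best[1] is not None:
        params.update(best[1])
    sync()


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

class _EnergyBlock:
    """Precomputed stage-2 quantities for one record block.

    With the charge model frozen, everything except the energy-net evaluation
    is constant: inputs X, input-to-position maps M (dx_i/dR, per Bohr),
    the electrostatic force part, and the short-range targets.
    """

    def __init__(self, model: PotentialModel, recs: list[ReferenceRecord]):
        s0 = recs[0].structure
        self.species = list(s0.species)
        self.n = s0.n_atoms
        self.B = len(recs)
        gen = model.generation
        elements = sorted(set(self.species))
        self.atom_idx = {
            el: np.array([a for a, sp in enumerate(self.species) if sp == el])
            for el in elements
        }
        cutoff = model.cutoff
        extra = 1 if gen == "4g" else 0
        nd = {el: model.acsf[el].n_functions for el in elements}

        X = {el: np.zeros((self.B, len(self.atom_idx[el]), nd[el] + extra)) for el in elements}
        Mten = {
            el: np.zeros((self.B, len(self.atom_idx[el]), nd[el] + extra, self.n, 3))
            for el in elements
        }
        f_const = np.zeros((self.B, self.n, 3))
        e_short_ref = np.zeros(self.B)
        f_ref = np.zeros((self.B, self.n, 3))

        for b, rec in enumerate(recs):
            s = rec.structure
            nl = build_neighbor_list(s, cutoff)
            ds = symmetry_functions(s, nl, model.acsf, gradients=True)
            e_elec = 0.0
            if gen in ("3g", "4g"):
                if gen == "4g":
                    chi = np.array(
                        [
                            nets.forward(model.charge_nets[s.species[a]], ds.values[a])
                            for a in range(self.n)
                        ]
                    )
                    system = build_system(s, chi, model.electro)
                    sol = solve_qeq(system)
                    Q = sol.charges
                    derivs = solution_derivatives(system, sol, s)
                    dchi_dr = np.zeros((self.n, self.n, 3))
                    for m in range(self.n):
                        gin = nets.gradients(model.charge_nets[s.species[m]], ds.values[m])[0]
                        dchi_dr[m] = np.einsum("d,dkc->kc", gin, ds.gradients[m]) * BOHR
                    dq_dr = derivs.dq_dr + np.einsum("im,mkc->ikc", derivs.dq_dchi, dchi_dr)
                else:
                    Q = np.array(
                        [
                            nets.forward(model.charge_nets[s.species[a]], ds.values[a])
                            for a in range(self.n)
                        ]
                    )
                    dq_dr = np.zeros((self.n, self.n, 3))
                    for m in range(self.n):
                        gin = nets.gradients(model.charge_nets[s.species[m]], ds.values[m])[0]
                        dq_dr[m] = np.einsum("d,dkc->kc", gin, ds.gradients[m]) * BOHR
                    if model.charge_mode == "scaled":
                        Q = Q + (s.total_charge - Q.sum()) / self.n
                        dq_dr = dq_dr - dq_dr.mean(axis=0, keepdims=True)
                e_elec, delec_dr, delec_dq = electrostatic_energy(
                    s, Q, model.electro, model.screening, with_grads=True
                )
                f_const[b] = -(delec_dr + np.einsum("i,ikc->kc", delec_dq, dq_dr))
            for el in elements:
                for slot, a in enumerate(self.atom_idx[el]):
                    X[el][b, slot, : nd[el]] = ds.values[a]
                    Mten[el][b, slot, : nd[el]] = ds.gradients[a] * BOHR
                    if gen == "4g":
                        X[el][b, slot, -1] = Q[a]
                        Mten[el][b, slot, -1] = dq_dr[a]
            e_short_ref[b] = rec.energy - e_elec
            f_ref[b] = rec.forces

        self.X = X
        self.M = Mten
        self.f_const = f_const
        self.e_short_ref = e_short_ref
        self.f_ref = f_ref
        counts = {el: len(self.atom_idx[el]) for el in elements}
        self.counts = counts

    def predict(self, model: PotentialModel):
        """(E_short, F, per-element (X, activations) caches)."""
        E = np.full(self.B, sum(model.energy_shift.get(sp, 0.0) for sp in self.species))
        F = self.f_const.copy()
        cache = {}
        for el, idx in self.atom_idx.items():
            net = model.energy_nets[el]
            Xf = self.X[el].reshape(-1, self.X[el].shape[-1])
            hid = nets.hidden_cache(net, Xf)
            y = nets.forward_batch(net, Xf, cache=hid).reshape(self.B, -1)
            gin = nets.input_grad_batch(net, Xf, cache=hid).reshape(self.B, len(idx), -1)
            E += y.sum(axis=1)
            Mflat = self.M[el].reshape(self.B, gin.shape[1] * gin.shape[2], -1)
            F -= (gin.reshape(self.B, 1, -1) @ Mflat).reshape(self.B, self.n, 3)
            cache[el] = (Xf, hid)
        return E, F, cache


def _fit_energy_shift(model: PotentialModel, blocks: list[_EnergyBlock]):
    """Least-squares per-element mean atomic energies of the short-range target."""
    elements = model.elements
    rows, ys = [], []
    for blk in blocks:
        cnt = [blk.species.count(el) for el in elements]
        for b in range(blk.B):
            rows.append(cnt)
            ys.append(blk.e_short_ref[b])
    A = np.array(rows, dtype=float)
    y = np.array(ys)
    mu, *_ = np.linalg.lstsq(A, y, rcond=None)
    model.energy_shift = {el: float(m) for el, m in zip(elements, mu)}


def fit_short_range_stage(model: PotentialModel, train: list[ReferenceRecord],
                          config: TrainConfig):
    """Stage 2: fit energy nets to residual energies and total forces.

    The charge model (chi nets, hardness) is frozen; loss is
    w_e * mean[(dE/N_at)^2] + w_f * mean[dF^2] with dF over all Cartesian
    components.  Returns (model, history) with per-epoch train/val energy and
    force RMSEs (meV/atom, eV/A).
    """
    for rec in train:
        if rec.energy is None or rec.forces is None:
            raise ValueError("stage-2 training requires reference energies and forces")
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(train))
    nval = max(1, int(round(config.val_fraction * len(train)))) if len(train) > 4 else 0
    val_recs = [train[k] for k in idx[:nval]]
    fit_recs = [train[k] for k in idx[nval:]]

    blocks = [_EnergyBlock(model, recs) for recs in _group_records(fit_recs)]
    vblocks = [_EnergyBlock(model, recs) for recs in _group_records(val_recs)] if val_recs else []
    _fit_energy_shift(model, blocks)

    elements = sorted(model.energy_nets)
    params = {el: model.energy_nets[el].to_flat() for el in elements}
    layer_sizes = {el: model.energy_nets[el].layer_sizes for el in elements}

    def sync():
        for el in elements:
            model.energy_nets[el] = NetworkParams.from_flat(params[el], layer_sizes[el])

    n_rec = sum(b.B for b in blocks)
    n_fcomp = sum(b.B * b.n * 3 for b in blocks)

    def losses(blist):
        se_e, se_f, nr, nf = 0.0, 0.0, 0, 0
        for blk in blist:
            E, F, _ = blk.predict(model)
            se_e += float(np.sum(((E - blk.e_short_ref) / blk.n) ** 2))
            se_f += float(np.sum((F - blk.f_ref) ** 2))
            nr += blk.B
            nf += blk.B * blk.n * 3
        return (np.sqrt(se_e / nr) if nr else np.nan,
                np.sqrt(se_f / nf) if nf else np.nan)

    history = []
    opt = _Adam(params, config.lr)
    best = (np.inf, None, -1)
    for epoch in range(config.epochs):
        sync()
        grads = {el: np.zeros_like(params[el]) for el in elements}
        se_e = se_f = 0.0
        for blk in blocks:
            E, F, cache = blk.predict(model)
            dE = (E - blk.e_short_ref) / blk.n
            dF = F - blk.f_ref
            se_e += float(np.sum(dE**2))
            se_f += float(np.sum(dF**2))
            wE = config.w_e * 2.0 * dE / (blk.n * n_rec)       # per-record scalars
            dLdF = config.w_f * 2.0 * dF / n_fcomp             # (B, N, 3)
            for el, idx_ in blk.atom_idx.items():
                net = model.energy_nets[el]
                Xf, hid = cache[el]
                wy = np.repeat(wE, len(idx_))
                grads[el] += nets.param_grad_weighted(net, Xf, wy, cache=hid)
                n_in = blk.M[el].shape[2]
                Mflat = blk.M[el].reshape(blk.B, len(idx_) * n_in, -1)
                Cmat = -(Mflat @ dLdF.reshape(blk.B, -1, 1))[..., 0]
                grads[el] += nets.mixed_param_grad(net, Xf, Cmat.reshape(Xf.shape), cache=hid)
        e_rmse = np.sqrt(se_e / n_rec)
        f_rmse = np.sqrt(se_f / n_fcomp)
        ve, vf = losses(vblocks) if vblocks else (e_rmse, f_rmse)
        train_loss = config.w_e * e_rmse**2 + config.w_f * f_rmse**2
        val_loss = config.w_e * ve**2 + config.w_f * vf**2
        history.append(
            {
                "epoch": epoch,
                "train_energy_rmse": e_rmse * HARTREE * 1e3,
                "train_force_rmse": f_rmse * HARTREE / BOHR,
                "val_energy_rmse": ve * HARTREE * 1e3,
                "val_force_rmse": vf * HARTREE / BOHR,
                "train_loss": train_loss,
            }
        )
        if val_loss < best[0]:
            best = (val_loss, {k: v.copy() for k, v in params.items()}, epoch)
        elif config.patience and epoch - best[2] > config.patience:
            break
        opt.lr = _lr_at(config, epoch)
        opt.step(params, grads)
    if config.epochs and best[1] is not None:
        params.update(best[1])
    sync()
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(model: PotentialModel, records: list[ReferenceRecord]) -> Metrics:
    """Energy (meV/atom), force (eV/A) and charge (10^-3 e) errors, RMSE + MAE."""
    if not records:
        raise ValueError("no records to evaluate")
    de, df, dq = [], [], []
    for rec in records:
        s = rec.structure
        if rec.energy is not None:
            e, _, _ = total_energy(model, s)
            de.append((e - rec.energy) / s.n_atoms * HARTREE * 1e3)
        if rec.forces is not None:
            f = model_forces(model, s)
            df.extend(((f - rec.forces) * HARTREE / BOHR).ravel())
        if rec.charges is not None and model.generation != "2g":
            q = predict_charges(model, s)
            dq.extend((q - rec.charges) * 1e3)

    def rm(x):
        x = np.asarray(x)
        return (float(np.sqrt(np.mean(x**2))), float(np.mean(np.abs(x)))) if len(x) else (None, None)

    er, ea = rm(de)
    fr, fa = rm(df)
    qr, qa = rm(dq)
    return Metrics(
        n_records=len(records),
        energy_rmse=er, energy_mae=ea,
        force_rmse=fr, force_mae=fa,
        charge_rmse=qr, charge_mae=qa,
    )
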