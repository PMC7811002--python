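"""Atom-centered symmetry functions (ACSF) with analytic position gradients.

Radial functions  G2 = sum_j exp(-eta (r_ij - r_s)^2) fc(r_ij)  over neighbors
of one element, and angular functions
G4 = 2^(1-zeta) sum_{j<k} (1 + lambda cos th)^zeta
     exp(-eta (r_ij^2 + r_ik^2 + r_jk^2)) fc(r_ij) fc(r_ik) fc(r_jk)
over element-matched neighbor pairs, with the cosine cutoff
fc(r) = 0.5 [cos(pi r / R_c) + 1].

All lengths in Angstrom, eta in A^-2, gradients in A^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import NeighborList, Structure, build_neighbor_list, neighbor_arrays

__all__ = [
    "AcsfParams",
    "DescriptorSet",
    "cutoff_function",
    "symmetry_functions",
    "descriptor_gradient_check",
    "default_acsf_params",
    "compact_acsf_params",
]


@dataclass
class AcsfParams:
    """Symmetry-function definitions for one center element."""

    element: str
    #: (neighbor element, eta A^-2, r_shift A)
    radial: list[tuple[str, float, float]]
    #: (neighbor element pair (unordered), eta A^-2, zeta >= 1, lambda +-1)
    angular: list[tuple[tuple[str, str], float, float, int]]
    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for _, eta, _ in self.radial:
            if eta < 0:
                raise ValueError("radial eta must be >= 0")
        for _, eta, zeta, lam in self.angular:
            if eta < 0 or zeta < 1 or lam not in (-1, 1):
                raise ValueError("angular parameters out of range")
        if not 1 <= self.n_functions:
            raise ValueError("need at least one symmetry function")

    @property
    def n_functions(self) -> int:
        return len(self.radial) + len(self.angular)


@dataclass
class DescriptorSet:
    """Per-atom descriptor vectors and dense position gradients.

    values[i] is the vector G_i; gradients[i] has shape (n_desc_i, N, 3) and
    holds dG_i / dR_k in A^-1 (zero outside the cutoff sphere of atom i).
    """

    values: list[np.ndarray]
    gradients: list[np.ndarray] | None = None


def cutoff_function(r, cutoff: float):
    """Cosine cutoff value and radial derivative; zero at and beyond cutoff."""
    r = np.asarray(r, dtype=float)
    inside = r < cutoff
    x = np.where(inside, r / cutoff, 1.0)
    val = np.where(inside, 0.5 * (np.cos(np.pi * x) + 1.0), 0.0)
    dval = np.where(inside, -0.5 * np.pi / cutoff * np.sin(np.pi * x), 0.0)
    return val, dval


def symmetry_functions(
    structure: Structure,
    neighbor_list: NeighborList,
    params: dict[str, AcsfParams],
    gradients: bool = True,
) -> DescriptorSet:
    """Evaluate ACSF values (and analytic gradients) for every atom.

    ``params`` maps each element to its AcsfParams; every element in the
    structure must be covered.
    """
    for el in structure.species:
        if el not in params:
            raise KeyError(f"element {el!r} not covered by descriptor parameters")

    n = structure.n_atoms
    nbrs = neighbor_arrays(structure, neighbor_list)
    values = []
    grads = [] if gradients else None

    for a in range(n):
        p = params[structure.species[a]]
        nd = p.n_functions
        g = np.zeros(nd)
        dg = np.zeros((nd, n, 3)) if gradients else None
        jdx, vecs, dists = nbrs[a]
        if len(jdx) == 0:
            values.append(g)
            if gradients:
                grads.append(dg)
            continue

        rc = p.cutoff
        fc, dfc = cutoff_function(dists, rc)
        elems = np.array([structure.species[j] for j in jdx])

        # radial
        for fi, (el, eta, rs) in enumerate(p.radial):
            mask = elems == el
            if not mask.any():
                continue
            r = dists[mask]
            expf = np.exp(-eta * (r - rs) ** 2)
            g[fi] = np.sum(expf * fc[mask])
            if gradients:
                # d/dr [exp * fc] along unit vector from a to j
                dterm = expf * (dfc[mask] - 2.0 * eta * (r - rs) * fc[mask])
                unit = vecs[mask] / r[:, None]
                contrib = dterm[:, None] * unit  # dG/dR_j per neighbor
                for t, j in enumerate(jdx[mask]):
                    dg[fi, j] += contrib[t]
                    dg[fi, a] -= contrib[t]

        # angular
        if p.angular:
            ang = p.angular
            etas = np.array([x[1] for x in ang])
            zetas = np.array([x[2] for x in ang])
            lams = np.array([x[3] for x in ang])
            pairs = [tuple(sorted(x[0])) for x in ang]
            off = len(p.radial)
            m = len(jdx)
            for t1 in range(m):
                for t2 in range(t1 + 1, m):
                    pe = tuple(sorted((elems[t1], elems[t2])))
                    sel = np.array([pe == q for q in pairs])
                    if not sel.any():
                        continue
                    rij, rik = dists[t1], dists[t2]
                    vij, vik = vecs[t1], vecs[t2]
                    vjk = vik - vij
                    rjk = np.linalg.norm(vjk)
                    fcj, dfcj = fc[t1], dfc[t1]
                    fck, dfck = fc[t2], dfc[t2]
                    fcl, dfcl = cutoff_function(rjk, rc)
                    cos = float(vij @ vik) / (rij * rik)
                    base = 1.0 + lams * cos
                    base = np.where(base < 0, 0.0, base)  # guard lambda*cos = -1
                    expf = np.exp(-etas * (rij**2 + rik**2 + rjk**2))
                    powm1 = np.where(base > 0, base ** (zetas - 1), 0.0)
                    powz = powm1 * base
                    pref = 2.0 ** (1.0 - zetas)
                    fcs = fcj * fck * fcl
                    term = pref * powz * expf * fcs
                    g[off:][sel] += term[sel]
                    if gradients:
                        # dcos/dRj and dcos/dRk (Ra fixed at center a)
                        dcos_dj = vik / (rij * rik) - cos * vij / rij**2
                        dcos_dk = vij / (rij * rik) - cos * vik / rik**2
                        # derivative pieces per angular function (vector chain)
                        dang = pref * zetas * lams * powm1 * expf * fcs
                        # d/d rij, rik, rjk of exp and fc products
                        dexp_rij = -2.0 * etas * rij * term
                        dexp_rik = -2.0 * etas * rik * term
                        dexp_rjk = -2.0 * etas * rjk * term
                        dfc_rij = pref * powz * expf * dfcj * fck * fcl
                        dfc_rik = pref * powz * expf * fcj * dfck * fcl
                        dfc_rjk = pref * powz * expf * fcj * fck * dfcl
                        uij = vij / rij
                        uik = vik / rik
                        ujk = vjk / rjk if rjk > 0 else np.zeros(3)
                        # gradient wrt R_j
                        gj = (
                            dang[:, None] * dcos_dj[None, :]
                            + (dexp_rij + dfc_rij)[:, None] * uij[None, :]
                            - (dexp_rjk + dfc_rjk)[:, None] * ujk[None, :]
                        )
                        gk = (
                            dang[:, None] * dcos_dk[None, :]
                            + (dexp_rik + dfc_rik)[:, None] * uik[None, :]
                            + (dexp_rjk + dfc_rjk)[:, None] * ujk[None, :]
                        )
                        jj, kk = jdx[t1], jdx[t2]
                        dga = dg[off:]
                        dga[sel, jj] += gj[sel]
                        dga[sel, kk] += gk[sel]
                        dga[sel, a] -= gj[sel] + gk[sel]

        values.append(g)
        if gradients:
            grads.append(dg)

    return DescriptorSet(values=values, gradients=grads)


def descriptor_gradient_check(
    structure: Structure, params: dict[str, AcsfParams], step: float = 1e-4
) -> float:
    """Max |analytic dG/dR - central finite difference| over all entries (A^-1)."""
    if not 1e-6 <= step <= 1e-3:
        raise ValueError("step must lie in [1e-6, 1e-3] A")
    cutoff = max(p.cutoff for p in params.values())
    nl = build_neighbor_list(structure, cutoff)
    ds = symmetry_functions(structure, nl, params, gradients=True)
    n = structure.n_atoms
    worst = 0.0
    for k in range(n):
        for c in range(3):
            sp = structure.copy()
            sp.positions[k, c] += step
            sm = structure.copy()
            sm.positions[k, c] -= step
            dsp = symmetry_functions(sp, build_neighbor_list(sp, cutoff), params, gradients=False)
            dsm = symmetry_functions(sm, build_neighbor_list(sm, cutoff), params, gradients=False)
            for a in range(n):
                fd = (dsp.values[a] - dsm.values[a]) / (2 * step)
                worst = max(worst, float(np.max(np.abs(ds.gradients[a][:, k, c] - fd), initial=0.0)))
    return worst


def compact_acsf_params(elements: list[str], cutoff: float = 4.23) -> dict[str, AcsfParams]:
    """Compact set: per element pair, five radial functions on a shifted grid
    (plus one wide coordination-counting function) and two angular functions.

    Smaller and better-resolved than ``default_acsf_params`` for narrow
    training distributions; input counts stay near the low end of the usual
    12-54 range.
    """
    elements = sorted(set(elements))
    shifts = [(4.0, 1.0), (4.0, 1.6), (4.0, 2.2), (2.0, 3.0), (1e-4, 0.0)]
    pairs = [(e1, e2) for a, e1 in enumerate(elements) for e2 in elements[a:]]
    out = {}
    for el in elements:
        radial = [(ne, eta, rs) for ne in elements for (eta, rs) in shifts]
        angular = [((p[0], p[1]), 0.02, 1.0, lam) for p in pairs for lam in (1, -1)]
        out[el] = AcsfParams(element=el, radial=radial, angular=angular, cutoff=cutoff)
    return out


def default_acsf_params(
    elements: list[str],
    cutoff: float,
    n_radial: int = 6,
    radial_eta_range: tuple[float, float] = (0.02, 2.0),
    angular_etas: tuple[float, ...] = (0.001, 0.03),
    zetas: tuple[float, ...] = (1.0, 4.0),
) -> dict[str, AcsfParams]:
    """Standard parameter generation: per element pair, ``n_radial`` radial
    functions with log-spaced eta and r_shift = 0, plus angular functions for
    every zeta/lambda/eta combination.  Fully overridable via config.
    """
    elements = sorted(set(elements))
    etas = np.geomspace(radial_eta_range[0], radial_eta_range[1], n_radial)
    out = {}
    pairs = [
        (e1, e2) for a, e1 in enumerate(elements) for e2 in elements[a:]
    ]
    for el in elements:
        radial = [(ne, float(eta), 0.0) for ne in elements for eta in etas]
        angular = [
            ((p[0], p[1]), float(aeta), float(z), int(lam))
            for p in pairs
            for aeta in angular_etas
            for z in zetas
            for lam in (1, -1)
        ]
        out[el] = AcsfParams(element=el, radial=radial, angular=angular, cutoff=cutoff)
    return out
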