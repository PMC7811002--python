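"""Atomic structures, extended-XYZ I/O, neighbor lists, geometry perturbation.

Positions, cells and cutoffs are in Angstrom; record energies are Hartree,
record forces Ha/Bohr, charges in units of e.  Files use eV and eV/A (see
``read_extxyz``/``write_extxyz`` for the dialect).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .units import BOHR, HARTREE

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "ReferenceRecord",
    "NeighborList",
    "read_extxyz",
    "write_extxyz",
    "build_neighbor_list",
    "neighbor_arrays",
    "perturb",
]


class ParseError(ValueError):
    """Malformed extended-XYZ input."""


@dataclass
class Structure:
    """Species, Cartesian coordinates (A), optional cell, and total charge."""

    species: list[str]
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    total_charge: float = 0.0
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if len(self.species) != self.positions.shape[0]:
            raise ValueError("species and positions length mismatch")
        if self.positions.shape[0] < 1:
            raise ValueError("structure needs at least one atom")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        self.pbc = tuple(bool(b) for b in self.pbc)
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("periodic structure requires a cell")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValueError("singular cell with periodic boundary conditions")
        if not np.isfinite(self.total_charge):
            raise ValueError("total_charge must be finite")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Structure":
        return Structure(
            species=list(self.species),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc,
            total_charge=self.total_charge,
            info=dict(self.info),
        )


@dataclass
class ReferenceRecord:
    """A labelled training/evaluation sample.

    energy in Ha, forces in Ha/Bohr, charges in e; optional fields are None.
    """

    structure: Structure
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    charges: Optional[np.ndarray] = None

    def __post_init__(self):
        n = self.structure.n_atoms
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (n, 3):
                raise ValueError("forces must have one row per atom")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charges must have one entry per atom")
            if abs(self.charges.sum() - self.structure.total_charge) > 1e-6:
                logger.warning(
                    "sum of per-atom charges (%.8f) deviates from total_charge (%.8f)",
                    self.charges.sum(),
                    self.structure.total_charge,
                )


@dataclass
class NeighborList:
    """Half neighbor list.

    Convention (consumers symmetrize): same-image pairs (shift == 0) are stored
    once with i < j; image pairs are stored once with the lexicographically
    positive shift, covering all ordered (i, j) including i == j self-images.
    """

    i: np.ndarray          # (P,) int
    j: np.ndarray          # (P,) int
    shift: np.ndarray      # (P, 3) int, cell-vector multiples applied to atom j
    vec: np.ndarray        # (P, 3) float, r_j + shift.cell - r_i  (A)
    dist: np.ndarray       # (P,) float (A)
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return len(self.i)


# ---------------------------------------------------------------------------
# extended-XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(line):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    return out


def _parse_properties(spec: str):
    toks = spec.split(":")
    if len(toks) % 3 != 0:
        raise ParseError(f"malformed Properties specification: {spec!r}")
    cols = []
    for k in range(0, len(toks), 3):
        cols.append((toks[k], toks[k + 1], int(toks[k + 2])))
    return cols


def _fmt(x: float) -> str:
    return format(x, ".16g")


def read_extxyz(path) -> list[ReferenceRecord]:
    """Read a (possibly multi-frame) extended-XYZ file into ReferenceRecords.

    File units are A / eV / eV A^-1 / e; the returned records are converted to
    the internal Ha / (Ha/Bohr) convention.  Missing optional fields (energy,
    forces, charge) stay absent (None), never zero-filled.  A frame without a
    ``total_charge`` key gets total charge 0 with a logged warning.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    records = []
    ln = 0
    nlines = len(lines)
    while ln < nlines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError as exc:
            raise ParseError(f"line {ln + 1}: expected atom count, got {lines[ln]!r}") from exc
        if ln + 1 >= nlines:
            raise ParseError(f"line {ln + 1}: truncated frame (missing comment line)")
        meta = _parse_comment(lines[ln + 1])
        body = lines[ln + 2 : ln + 2 + nat]
        if len(body) < nat or any(not b.strip() for b in body):
            raise ParseError(
                f"line {ln + 1}: frame declares {nat} atoms but fewer coordinate lines follow"
            )

        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        species, pos, forces, charges = [], [], [], []
        has_forces = any(p[0] == "forces" for p in props)
        has_charge = any(p[0] == "charge" for p in props)
        for off, row in enumerate(body):
            toks = row.split()
            want = sum(p[2] for p in props)
            if len(toks) != want:
                raise ParseError(
                    f"line {ln + 3 + off}: expected {want} columns, got {len(toks)}"
                )
            c = 0
            for name, _typ, ncol in props:
                chunk = toks[c : c + ncol]
                c += ncol
                if name == "species":
                    species.append(chunk[0])
                elif name == "pos":
                    pos.append([float(v) for v in chunk])
                elif name == "forces":
                    forces.append([float(v) for v in chunk])
                elif name == "charge":
                    charges.append(float(chunk[0]))

        cell = None
        pbc = (False, False, False)
        if "Lattice" in meta:
            vals = [float(v) for v in meta["Lattice"].split()]
            if len(vals) != 9:
                raise ParseError(f"line {ln + 2}: Lattice needs 9 numbers")
            cell = np.array(vals).reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in meta:
            pbc = tuple(t.strip() in ("T", "True", "1") for t in meta["pbc"].split())

        if "total_charge" in meta:
            qtot = float(meta["total_charge"])
        else:
            qtot = 0.0
            logger.warning("frame at line %d has no total_charge key; assuming 0", ln + 1)

        info = {
            k: v
            for k, v in meta.items()
            if k not in ("Lattice", "Properties", "pbc", "total_charge", "energy")
        }
        structure = Structure(species, np.array(pos), cell, pbc, qtot, info)
        energy = float(meta["energy"]) / HARTREE if "energy" in meta else None
        records.append(
            ReferenceRecord(
                structure,
                energy=energy,
                forces=np.array(forces) / (HARTREE / BOHR) if has_forces else None,
                charges=np.array(charges) if has_charge else None,
            )
        )
        ln += 2 + nat
    return records


def write_extxyz(records: list[ReferenceRecord], path) -> None:
    """Write records in the documented extended-XYZ dialect (A / eV / eV/A)."""
    if not records:
        raise ValueError("no records to write")
    out = []
    for rec in records:
        s = rec.structure
        cols = "species:S:1:pos:R:3"
        if rec.forces is not None:
            cols += ":forces:R:3"
        if rec.charges is not None:
            cols += ":charge:R:1"
        meta = []
        if s.cell is not None:
            meta.append('Lattice="' + " ".join(_fmt(v) for v in s.cell.ravel()) + '"')
        meta.append(f"Properties={cols}")
        if rec.energy is not None:
            meta.append(f"energy={_fmt(rec.energy * HARTREE)}")
        meta.append(f"total_charge={_fmt(s.total_charge)}")
        if any(s.pbc):
            meta.append('pbc="' + " ".join("T" if b else "F" for b in s.pbc) + '"')
        for k, v in s.info.items():
            sv = str(v)
            meta.append(f'{k}="{sv}"' if re.search(r"\s", sv) else f"{k}={sv}")
        out.append(str(s.n_atoms))
        out.append(" ".join(meta))
        for a in range(s.n_atoms):
            row = [s.species[a]] + [_fmt(v) for v in s.positions[a]]
            if rec.forces is not None:
                row += [_fmt(v) for v in rec.forces[a] * (HARTREE / BOHR)]
            if rec.charges is not None:
                row.append(_fmt(rec.charges[a]))
            out.append(" ".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

def build_neighbor_list(structure: Structure, cutoff: float) -> NeighborList:
    """All pairs with r_ij <= cutoff (A), including periodic images.

    Image replication bounds come from the cell's perpendicular widths, so the
    cutoff may exceed the cell dimensions.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = structure.positions

    if any(structure.pbc):
        cell = structure.cell
        vol = abs(np.linalg.det(cell))
        if vol < 1e-12:
            raise ValueError("singular cell")
        # perpendicular width along axis a is V / |b x c|
        nmax = []
        for d in range(3):
            if structure.pbc[d]:
                cross = np.cross(cell[(d + 1) % 3], cell[(d + 2) % 3])
                width = vol / np.linalg.norm(cross)
                nmax.append(int(np.ceil(cutoff / width)))
            else:
                nmax.append(0)
        shift_list = [
            (sa, sb, sc)
            for sa in range(-nmax[0], nmax[0] + 1)
            for sb in range(-nmax[1], nmax[1] + 1)
            for sc in range(-nmax[2], nmax[2] + 1)
        ]
    else:
        shift_list = [(0, 0, 0)]

    ii, jj, ss, vv, dd = [], [], [], [], []
    for s in shift_list:
        if s < (0, 0, 0):
            continue  # canonical half: keep shift==0 and lexicographically positive
        if s == (0, 0, 0):
            disp = pos[None, :, :] - pos[:, None, :]
            dist = np.linalg.norm(disp, axis=-1)
            a, b = np.nonzero((dist <= cutoff) & (dist > 0))
            keep = a < b
            a, b = a[keep], b[keep]
            for x, y in zip(a, b):
                ii.append(x)
                jj.append(y)
                ss.append(s)
                vv.append(disp[x, y])
                dd.append(dist[x, y])
        else:
            offset = np.asarray(s, dtype=float) @ structure.cell
            disp = (pos + offset)[None, :, :] - pos[:, None, :]
            dist = np.linalg.norm(disp, axis=-1)
            a, b = np.nonzero(dist <= cutoff)
            for x, y in zip(a, b):
                ii.append(x)
                jj.append(y)
                ss.append(s)
                vv.append(disp[x, y])
                dd.append(dist[x, y])

    return NeighborList(
        i=np.array(ii, dtype=int),
        j=np.array(jj, dtype=int),
        shift=np.array(ss, dtype=int).reshape(-1, 3),
        vec=np.array(vv, dtype=float).reshape(-1, 3),
        dist=np.array(dd, dtype=float),
        cutoff=float(cutoff),
    )


def neighbor_arrays(structure: Structure, nl: NeighborList):
    """Symmetrized per-atom neighbor arrays.

    Returns a list of (indices, vectors, distances) per atom, where vectors
    point from the atom to each neighbor image.
    """
    n = structure.n_atoms
    idx = [[] for _ in range(n)]
    vec = [[] for _ in range(n)]
    for p in range(nl.n_pairs):
        a, b = int(nl.i[p]), int(nl.j[p])
        v = nl.vec[p]
        idx[a].append(b)
        vec[a].append(v)
        idx[b].append(a)
        vec[b].append(-v)
    out = []
    for a in range(n):
        if idx[a]:
            iarr = np.array(idx[a], dtype=int)
            varr = np.array(vec[a], dtype=float)
            out.append((iarr, varr, np.linalg.norm(varr, axis=1)))
        else:
            out.append((np.empty(0, dtype=int), np.empty((0, 3)), np.empty(0)))
    return out


def perturb(structure: Structure, sigma: float, seed: int) -> Structure:
    """Displace every Cartesian component by N(0, sigma^2); deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    new = structure.copy()
    new.positions = new.positions + rng.normal(0.0, sigma, size=new.positions.shape)
    return new
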