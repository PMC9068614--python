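"""Atomic structures, periodic neighbor lists, and extended-XYZ I/O.

A structure holds positions (Å), atomic numbers, an optional periodic cell
with per-axis flags, and optional energy (eV) / force (eV/Å) labels.  The
neighbor graph contains every directed pair within the cutoff, including
periodic images; a full image search is used (not minimum image), so cutoffs
larger than half the cell are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AtomicStructure",
    "NeighborGraph",
    "build_neighbor_graph",
    "average_num_neighbors",
    "read_extxyz",
    "write_extxyz",
    "CHEMICAL_SYMBOLS",
    "ATOMIC_MASSES",
]

CHEMICAL_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
]
_SYMBOL_TO_Z = {s: i for i, s in enumerate(CHEMICAL_SYMBOLS)}

# average atomic masses (amu) for the supported elements
ATOMIC_MASSES = np.array([
    0.0, 1.008, 4.0026, 6.94, 9.0122, 10.81, 12.011, 14.007, 15.999, 18.998,
    20.18, 22.99, 24.305, 26.982, 28.085, 30.974, 32.06, 35.45, 39.948,
    39.098, 40.078, 44.956, 47.867, 50.942, 51.996, 54.938, 55.845, 58.933,
    58.693, 63.546, 65.38,
])


@dataclass
class AtomicStructure:
    """Positions in Å, atomic numbers, optional cell/PBC and labels."""

    positions: np.ndarray
    species: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype=int).reshape(-1)
        self.pbc = np.asarray(self.pbc, dtype=bool).reshape(3)
        if len(self.positions) < 1:
            raise ValueError("structure must contain at least one atom")
        if len(self.species) != len(self.positions):
            raise ValueError("species/positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
            if not np.all(np.isfinite(self.cell)):
                raise ValueError("cell must be finite")
        if self.cell is None and self.pbc.any():
            raise ValueError("periodic flags require a cell")
        if self.cell is not None and not self.pbc.any():
            raise ValueError("cell present but no periodic axis flagged")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if len(self.forces) != len(self.positions):
                raise ValueError("forces/positions length mismatch")
        if self.energy is not None:
            self.energy = float(self.energy)

    def __len__(self):
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            positions=self.positions.copy(),
            species=self.species.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc.copy(),
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
        )


@dataclass
class NeighborGraph:
    """Directed edges (i -> j, image shift) with vectors pointing i -> j."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    shifts: np.ndarray          # integer periodic image vectors, (E, 3)
    vectors: np.ndarray         # r_j + shift @ cell - r_i, (E, 3), Å
    distances: np.ndarray       # (E,), Å
    n_atoms: int
    r_c: float

    @property
    def n_edges(self) -> int:
        return len(self.edge_i)


def _image_ranges(cell: np.ndarray, pbc: np.ndarray, r_c: float) -> np.ndarray:
    """Number of periodic images per axis guaranteeing full cutoff coverage."""
    inv = np.linalg.inv(cell)
    # spacing between lattice planes normal to axis k: 1 / |column k of inv|
    heights = 1.0 / np.linalg.norm(inv, axis=0)
    n = np.where(pbc, np.floor(r_c / heights).astype(int) + 1, 0)
    return n


def build_neighbor_graph(structure: AtomicStructure, r_c: float) -> NeighborGraph:
    """All directed pairs (including periodic images) with distance < r_c."""
    if r_c <= 0:
        raise ValueError("cutoff radius must be positive")
    pos = structure.positions
    n = len(pos)
    if structure.cell is not None:
        cell = structure.cell
        if abs(np.linalg.det(cell)) < 1e-12:
            raise ValueError("cell is singular")
        nmax = _image_ranges(cell, structure.pbc, r_c)
    else:
        cell = np.eye(3)
        nmax = np.zeros(3, dtype=int)
    shift_list = np.array([
        (sx, sy, sz)
        for sx in range(-nmax[0], nmax[0] + 1)
        for sy in range(-nmax[1], nmax[1] + 1)
        for sz in range(-nmax[2], nmax[2] + 1)
    ], dtype=int)
    ei, ej, sh, vec, dist = [], [], [], [], []
    diff0 = pos[None, :, :] - pos[:, None, :]  # (i, j): r_j - r_i
    for s in shift_list:
        disp = diff0 + s @ cell
        d = np.linalg.norm(disp, axis=-1)
        mask = d < r_c
        if not s.any():
            np.fill_diagonal(mask, False)
        idx_i, idx_j = np.nonzero(mask)
        if len(idx_i) == 0:
            continue
        ei.append(idx_i)
        ej.append(idx_j)
        sh.append(np.tile(s, (len(idx_i), 1)))
        vec.append(disp[idx_i, idx_j])
        dist.append(d[idx_i, idx_j])
    if ei:
        ei = np.concatenate(ei)
        ej = np.concatenate(ej)
        sh = np.concatenate(sh)
        vec = np.concatenate(vec)
        dist = np.concatenate(dist)
        order = np.lexsort((sh[:, 2], sh[:, 1], sh[:, 0], ej, ei))
        ei, ej, sh, vec, dist = ei[order], ej[order], sh[order], vec[order], dist[order]
    else:
        ei = np.zeros(0, dtype=int)
        ej = np.zeros(0, dtype=int)
        sh = np.zeros((0, 3), dtype=int)
        vec = np.zeros((0, 3))
        dist = np.zeros(0)
    return NeighborGraph(ei, ej, sh, vec, dist, n_atoms=n, r_c=float(r_c))


def average_num_neighbors(structures, r_c: float) -> float:
    """Mean per-atom neighbor count over a dataset (frozen into the model)."""
    structures = list(structures)
    if not structures:
        raise ValueError("dataset is empty")
    total_edges = 0
    total_atoms = 0
    for s in structures:
        g = build_neighbor_graph(s, r_c)
        total_edges += g.n_edges
        total_atoms += s.n_atoms
    return total_edges / total_atoms


# --------------------------------------------------------------------------
# extended XYZ
# --------------------------------------------------------------------------

def _parse_comment(line: str) -> dict:
    """Key=value pairs from the extxyz comment line (quoted values allowed)."""
    out = {}
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        if i >= n:
            break
        j = i
        while j < n and line[j] not in "= \t":
            j += 1
        key = line[i:j]
        if j >= n or line[j] != "=":
            out[key] = "T"
            i = j
            continue
        j += 1
        if j < n and line[j] == '"':
            k = line.find('"', j + 1)
            if k < 0:
                raise ValueError("unterminated quote in comment line")
            out[key] = line[j + 1:k]
            i = k + 1
        else:
            k = j
            while k < n and not line[k].isspace():
                k += 1
            out[key] = line[j:k]
            i = k
    return out


def _species_to_symbol(z: int) -> str:
    return CHEMICAL_SYMBOLS[z]


def read_extxyz(path) -> list[AtomicStructure]:
    """Read every frame of an extended-XYZ file.

    Recognized comment keys: ``Lattice`` (9 numbers, row-major lattice
    vectors), ``pbc`` ("T T T" style), ``energy`` (eV), and a ``Properties``
    descriptor with ``species:S:1``, ``pos:R:3`` and optionally
    ``forces:R:3`` columns.  Malformed frames raise with their frame index.
    """
    structures = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
            header = _parse_comment(lines[i + 1])
            body = lines[i + 2:i + 2 + nat]
            if len(body) < nat:
                raise ValueError("truncated frame")
            props = header.get("Properties", "species:S:1:pos:R:3")
            fields = props.split(":")
            columns = [(fields[k], fields[k + 1], int(fields[k + 2]))
                       for k in range(0, len(fields), 3)]
            species, positions, forces = [], [], []
            has_forces = any(name == "forces" for name, _, _ in columns)
            for row in body:
                toks = row.split()
                c = 0
                for name, kind, width in columns:
                    vals = toks[c:c + width]
                    c += width
                    if name == "species":
                        v = vals[0]
                        species.append(_SYMBOL_TO_Z[v] if v in _SYMBOL_TO_Z else int(v))
                    elif name == "pos":
                        positions.append([float(x) for x in vals])
                    elif name == "forces":
                        forces.append([float(x) for x in vals])
            cell = None
            pbc = np.zeros(3, dtype=bool)
            if "Lattice" in header:
                cell = np.array([float(x) for x in header["Lattice"].split()]).reshape(3, 3)
                if "pbc" in header:
                    pbc = np.array([t in ("T", "True", "true", "1")
                                    for t in header["pbc"].split()])
                else:
                    pbc = np.ones(3, dtype=bool)
            energy = float(header["energy"]) if "energy" in header else None
            structures.append(AtomicStructure(
                positions=np.array(positions),
                species=np.array(species),
                cell=cell,
                pbc=pbc,
                energy=energy,
                forces=np.array(forces) if has_forces else None,
            ))
        except Exception as exc:
            raise ValueError(f"malformed extxyz frame {frame} in {path}: {exc}") from exc
        i += 2 + nat
        frame += 1
    return structures


def write_extxyz(structures, path) -> None:
    """Write structures as extended XYZ (lossless round trip with read_extxyz)."""
    if isinstance(structures, AtomicStructure):
        structures = [structures]
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            parts = []
            if s.cell is not None:
                lat = " ".join(f"{x:.12g}" for x in s.cell.ravel())
                parts.append(f'Lattice="{lat}"')
                parts.append('pbc="' + " ".join("T" if b else "F" for b in s.pbc) + '"')
            props = "species:S:1:pos:R:3"
            if s.forces is not None:
                props += ":forces:R:3"
            parts.append(f"Properties={props}")
            if s.energy is not None:
                parts.append(f"energy={s.energy:.12g}")
            fh.write(" ".join(parts) + "\n")
            for k in range(s.n_atoms):
                row = [_species_to_symbol(s.species[k])]
                row += [f"{x:.12g}" for x in s.positions[k]]
                if s.forces is not None:
                    row += [f"{x:.12g}" for x in s.forces[k]]
                fh.write(" ".join(row) + "\n")
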