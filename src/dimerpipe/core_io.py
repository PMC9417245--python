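"""Shared data model and structure/table IO.

Structures are stored internally in nm; PDB files (Angstrom) are converted
at the boundary.  Residue indices are 0-based internally; helpers are
provided to translate to the 1-based peptide numbering that excludes an
N-terminal anchor residue.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .units import NM_PER_ANGSTROM

__all__ = [
    "StructureFrame",
    "Ensemble",
    "RuptureDataset",
    "read_structure",
    "write_structure",
    "read_rupture_table",
    "write_rupture_table",
]


@dataclass
class StructureFrame:
    """One conformation: per-atom coordinates (nm) plus topology labels."""

    coords: np.ndarray
    atom_names: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        n = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        for arr, name in [
            (self.atom_names, "atom_names"),
            (self.residue_index, "residue_index"),
            (self.residue_name, "residue_name"),
            (self.chain_id, "chain_id"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length does not match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def select(self, mask: np.ndarray) -> "StructureFrame":
        return StructureFrame(
            coords=self.coords[mask],
            atom_names=self.atom_names[mask],
            residue_index=self.residue_index[mask],
            residue_name=self.residue_name[mask],
            chain_id=self.chain_id[mask],
        )

    def atom_mask(self, names: Iterable[str]) -> np.ndarray:
        names = set(names)
        return np.array([a in names for a in self.atom_names])

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        """Calpha coordinates in residue order (optionally one chain)."""
        mask = self.atom_names == "CA"
        if chain is not None:
            mask &= self.chain_mask(chain)
        if not mask.any():
            raise ValueError("no CA atoms present")
        return self.coords[mask]

    def residues_of_chain(self, chain: str) -> np.ndarray:
        """Sorted unique residue indices of one chain."""
        mask = self.chain_mask(chain)
        if not mask.any():
            raise ValueError(f"chain {chain!r} not present")
        return np.unique(self.residue_index[mask])

    def topology_key(self) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.atom_names).encode())
        h.update(np.ascontiguousarray(self.residue_index).tobytes())
        h.update("|".join(self.residue_name).encode())
        h.update("|".join(self.chain_id).encode())
        return h.hexdigest()


@dataclass
class Ensemble:
    """Ordered stack of frames sharing one topology."""

    frames: list[StructureFrame]
    frame_times: np.ndarray | None = None
    topology_hash: str = field(default="")

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        key = self.frames[0].topology_key()
        for f in self.frames[1:]:
            if f.topology_key() != key:
                raise ValueError("frames do not share a common topology")
        self.topology_hash = key
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.frames):
                raise ValueError("frame_times length mismatch")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> StructureFrame:
        return self.frames[i]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coords for f in self.frames])

    def concat(self, other: "Ensemble") -> "Ensemble":
        if other.topology_hash != self.topology_hash:
            raise ValueError("cannot concatenate ensembles with different topologies")
        return Ensemble(frames=list(self.frames) + list(other.frames))


@dataclass
class RuptureDataset:
    """Paired rupture force (pN) and position samples."""

    forces: np.ndarray
    positions: np.ndarray
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.forces.shape != self.positions.shape:
            raise ValueError("forces and positions must have the same length")
        if self.forces.size and np.any(self.forces < 0):
            raise ValueError("forces must be non-negative")
        if self.normalized and self.forces.size:
            if np.any(self.positions < 0) or np.any(self.positions > 1):
                raise ValueError("normalized positions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.forces)


def _frame_to_atom_array(frame: StructureFrame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords / NM_PER_ANGSTROM
    arr.atom_name = np.asarray(frame.atom_names, dtype="U6")
    arr.res_id = frame.residue_index + 1  # PDB is 1-based
    arr.res_name = np.asarray(frame.residue_name, dtype="U5")
    arr.chain_id = np.asarray(frame.chain_id, dtype="U4")
    arr.element = np.array([str(a)[0] for a in frame.atom_names], dtype="U2")
    return arr


def _atom_array_to_frame(arr: struc.AtomArray) -> StructureFrame:
    return StructureFrame(
        coords=np.asarray(arr.coord, dtype=float) * NM_PER_ANGSTROM,
        atom_names=np.asarray(arr.atom_name, dtype=object),
        residue_index=np.asarray(arr.res_id, dtype=int) - 1,
        residue_name=np.asarray(arr.res_name, dtype=object),
        chain_id=np.asarray(arr.chain_id, dtype=object),
    )


def read_structure(path: str | Path, model_policy: str = "all") -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    ``model_policy`` is ``"all"`` (one frame per model) or ``"first"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if model_policy not in ("all", "first"):
        raise ValueError("model_policy must be 'all' or 'first'")
    pdb = pdbio.PDBFile.read(str(path))
    if model_policy == "first":
        stack = pdbio.get_structure(pdb, model=1)
        frames = [_atom_array_to_frame(stack)]
    else:
        stack = pdbio.get_structure(pdb)  # AtomArrayStack; fails on ragged models
        frames = [_atom_array_to_frame(stack[i]) for i in range(stack.stack_depth())]
    ens = Ensemble(frames=frames)
    if not any("CA" == a for a in ens.frames[0].atom_names):
        raise ValueError(f"{path} contains no CA atoms")
    return ens


def write_structure(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as a multi-model PDB file."""
    path = Path(path)
    arrays = [_frame_to_atom_array(f) for f in ensemble.frames]
    stack = struc.stack(arrays)
    pdb = pdbio.PDBFile()
    pdbio.set_structure(pdb, stack)
    pdb.write(str(path))
    return path


_FORCE_ALIASES = ("force", "force_pn", "rupture_force", "f")
_POS_ALIASES = ("position", "position_nm", "distance", "pos", "x")
_NORM_ALIASES = ("normalized_position", "norm_position", "normalized_distance")


def read_rupture_table(path: str | Path, label: str | None = None) -> RuptureDataset:
    """Read a delimited force/position table.

    Recognises headers naming a force column and either a raw position
    column (nm) or a normalized-position column; headerless two-column
    files are treated as (force, position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path} is empty")
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {str(c).strip().lower(): c for c in df.columns}
    normalized = False
    force_col = next((cols[a] for a in _FORCE_ALIASES if a in cols), None)
    pos_col = next((cols[a] for a in _POS_ALIASES if a in cols), None)
    norm_col = next((cols[a] for a in _NORM_ALIASES if a in cols), None)
    if force_col is None or (pos_col is None and norm_col is None):
        # headerless: reread without header
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        if df.shape[1] < 2:
            raise ValueError("rupture table needs at least two columns")
        force_col, pos_col = df.columns[0], df.columns[1]
    if norm_col is not None and pos_col is None:
        pos_col = norm_col
        normalized = True
    forces = pd.to_numeric(df[force_col], errors="raise").to_numpy(dtype=float)
    positions = pd.to_numeric(df[pos_col], errors="raise").to_numpy(dtype=float)
    if np.any(~np.isfinite(forces)) or np.any(~np.isfinite(positions)):
        raise ValueError("non-numeric rows in rupture table")
    return RuptureDataset(
        forces=forces,
        positions=positions,
        label=label if label is not None else path.stem,
        normalized=normalized,
    )


def write_rupture_table(dataset: RuptureDataset, path: str | Path) -> Path:
    path = Path(path)
    pos_name = "normalized_position" if dataset.normalized else "position_nm"
    pd.DataFrame({"force_pn": dataset.forces, pos_name: dataset.positions}).to_csv(
        path, sep="\t", index=False
    )
    return path


def to_peptide_numbering(residue_index: np.ndarray | int, anchor_offset: int = 1) -> np.ndarray | int:
    """Translate internal 0-based indices to 1-based peptide numbering that
    excludes ``anchor_offset`` leading anchor residues (anchor itself maps
    to 0)."""
    return np.asarray(residue_index) - anchor_offset + 1
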