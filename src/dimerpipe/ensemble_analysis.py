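"""Superposition, RMSD clustering, contact maps and shape descriptors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .core_io import Ensemble, StructureFrame
from .geometry import kabsch

__all__ = [
    "ClusterResult",
    "ContactMap",
    "ShapeDescriptors",
    "superpose",
    "rmsd_matrix",
    "gromos_cluster",
    "contact_probability_map",
    "contact_difference",
    "shape_descriptors",
    "progressive_fit",
]

BACKBONE_ATOMS = ("N", "CA", "C")

#: van der Waals radii (nm) keyed by element, used for SASA.
VDW_RADII = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

#: atomic masses (Da) keyed by element, used for mass-weighted Rg.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0 = most populated)
    representatives: np.ndarray  # cluster id -> frame index of the center
    populations: np.ndarray  # fractions, descending
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


@dataclass
class ContactMap:
    matrix: np.ndarray
    mode: str  # intra | inter | difference
    cutoff: float
    chains: tuple[str, str] = ("A", "A")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        lo = -1.0 if self.mode == "difference" else 0.0
        finite = self.matrix[~np.isnan(self.matrix)]
        if finite.size and (finite.min() < lo - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("contact probabilities out of range")


@dataclass
class ShapeDescriptors:
    radius_of_gyration: float  # nm
    volume: float  # nm^3 (convex hull of atom centres)
    sasa: float  # nm^2


def _element_of(atom_name: str) -> str:
    return str(atom_name)[0]


def _selection_coords(frame: StructureFrame, atom_selection) -> np.ndarray:
    if atom_selection is None:
        mask = np.ones(frame.n_atoms, dtype=bool)
    else:
        mask = frame.atom_mask(atom_selection)
    return frame.coords[mask]


def superpose(mobile: StructureFrame, reference: StructureFrame,
              atom_selection=BACKBONE_ATOMS) -> tuple[StructureFrame, float]:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    The rotation is computed on the atom selection but applied to all atoms;
    returns (transformed frame, minimal RMSD over the selection in nm).
    """
    sel_m = _selection_coords(mobile, atom_selection)
    sel_r = _selection_coords(reference, atom_selection)
    if sel_m.shape != sel_r.shape:
        raise ValueError("mismatched atom selections")
    rot, trans, rmsd = kabsch(sel_m, sel_r)
    moved = mobile.select(np.ones(mobile.n_atoms, dtype=bool))
    moved.coords = mobile.coords @ rot.T + trans
    return moved, rmsd


def progressive_fit(ensemble: Ensemble, atom_selection=BACKBONE_ATOMS) -> Ensemble:
    """De-drift a trajectory by fitting each frame onto the previous fitted one."""
    fitted = [ensemble.frames[0]]
    for frame in ensemble.frames[1:]:
        moved, _ = superpose(frame, fitted[-1], atom_selection)
        fitted.append(moved)
    return Ensemble(frames=fitted, frame_times=ensemble.frame_times)


def rmsd_matrix(ensemble: Ensemble, atom_selection=BACKBONE_ATOMS) -> np.ndarray:
    """Pairwise minimal backbone RMSD (nm) after optimal superposition."""
    if ensemble.n_frames < 2:
        raise ValueError("need at least two frames")
    sels = [_selection_coords(f, atom_selection) for f in ensemble.frames]
    T = len(sels)
    mat = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            _, _, r = kabsch(sels[i], sels[j])
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(rmsd: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering on a pairwise RMSD matrix.

    Repeatedly takes the frame with the most unassigned neighbours within
    ``cutoff`` as a cluster centre (lowest index on ties), assigns centre
    plus neighbours, removes them, and recurses.  Populations are fractions
    of all frames; clusters are returned in descending population order
    (ties by formation order).
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if rmsd.ndim != 2 or rmsd.shape[0] != rmsd.shape[1]:
        raise ValueError("rmsd must be square")
    if np.any(np.isnan(rmsd)):
        raise ValueError("rmsd matrix contains NaN")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    T = rmsd.shape[0]
    neighbor = rmsd <= cutoff
    np.fill_diagonal(neighbor, True)
    remaining = np.ones(T, dtype=bool)
    assignments = np.full(T, -1, dtype=int)
    centers, sizes = [], []
    cid = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbor[center] & remaining
        assignments[members] = cid
        centers.append(center)
        sizes.append(int(members.sum()))
        remaining &= ~members
        cid += 1
    order = np.argsort(-np.asarray(sizes), kind="stable")
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(len(order))
    return ClusterResult(
        assignments=relabel[assignments],
        representatives=np.asarray(centers)[order],
        populations=np.asarray(sizes, dtype=float)[order] / T,
        cutoff=float(cutoff),
    )


def contact_probability_map(ensemble: Ensemble, chain_pair: tuple[str, str],
                            cutoff: float = 0.8, exclude_bonded: int = 0) -> ContactMap:
    """Residue-residue Calpha contact probability over an ensemble.

    Entry (i, j) is the fraction of frames in which the Calpha atoms of
    residue i of the first chain and residue j of the second chain are
    within ``cutoff`` nm.  For intra-chain maps ``exclude_bonded`` masks
    |i - j| <= exclude_bonded with NaN.
    """
    ca, cb = chain_pair
    frame0 = ensemble.frames[0]
    if ca not in frame0.chains or cb not in frame0.chains:
        raise ValueError(f"chain pair {chain_pair} not present")
    acc = None
    for frame in ensemble.frames:
        xa = frame.ca_coords(chain=ca)
        xb = frame.ca_coords(chain=cb)
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        hit = (d <= cutoff).astype(float)
        acc = hit if acc is None else acc + hit
    prob = acc / ensemble.n_frames
    mode = "intra" if ca == cb else "inter"
    if mode == "intra" and exclude_bonded > 0:
        n = prob.shape[0]
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        prob[np.abs(ii - jj) <= exclude_bonded] = np.nan
    return ContactMap(matrix=prob, mode=mode, cutoff=float(cutoff), chains=(ca, cb))


def contact_difference(map_a: ContactMap, map_b: ContactMap) -> ContactMap:
    """Element-wise difference map (first minus second) of two intra maps."""
    if map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError("contact maps have different shapes")
    if map_a.mode != "intra" or map_b.mode != "intra":
        raise ValueError("difference maps are defined for intra maps")
    return ContactMap(
        matrix=map_a.matrix - map_b.matrix,
        mode="difference",
        cutoff=map_a.cutoff,
        chains=(map_a.chains[0], map_b.chains[0]),
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe_radius: float = 0.14, sphere_points: int = 960) -> float:
    """Solvent-accessible surface area (nm^2) by the Shrake-Rupley method."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    pts = _sphere_points(sphere_points)
    total = 0.0
    n = len(coords)
    for i in range(n):
        test = coords[i] + radii[i] * pts
        accessible = np.ones(sphere_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > radii[i] + radii[j]:
                continue
            d = np.linalg.norm(test - coords[j], axis=1)
            accessible &= d >= radii[j]
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (nm); unit masses when omitted."""
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=masses)))


def shape_descriptors(frame: StructureFrame, probe_radius: float = 0.14,
                      sphere_points: int = 960) -> ShapeDescriptors:
    """Mass-weighted Rg, convex-hull volume and Shrake-Rupley SASA."""
    coords = frame.coords
    elements = np.array([_element_of(a) for a in frame.atom_names])
    masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])
    rg = radius_of_gyration(coords, masses)

    if len(coords) < 4:
        raise ValueError("need at least 4 atoms for a hull volume")
    try:
        volume = float(ConvexHull(coords).volume)
    except Exception as exc:  # scipy raises QhullError for degenerate input
        raise ValueError("atoms are degenerate (coplanar/colinear)") from exc

    radii = np.array([VDW_RADII.get(e, 0.170) for e in elements])
    sasa = shrake_rupley_sasa(coords, radii, probe_radius, sphere_points)
    return ShapeDescriptors(radius_of_gyration=rg, volume=volume, sasa=sasa)
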