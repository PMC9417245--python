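"""Synthetic peptide ensembles, dimers and rupture samples with known truth.

Chains are built as backbone-only (N, CA, C, O) peptides from sampled
(phi, psi) dihedrals using ideal bond geometry, so every downstream stage
(dihedral assignment, hydrogen-bond assignment, contact maps, pulling) can
be exercised against generator-level ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Ensemble, RuptureDataset, StructureFrame
from .geometry import place_atom

__all__ = [
    "ALPHA_PHI_RANGE",
    "ALPHA_PSI_RANGE",
    "BETA_PHI_RANGE",
    "BETA_PSI_RANGE",
    "PropensityProfile",
    "DimerSpec",
    "sample_dihedral_chain",
    "build_chain_frame",
    "build_dimer",
    "sample_rupture_data",
]

# Dihedral boxes of the two-consecutive-residue secondary-structure criterion.
ALPHA_PHI_RANGE = (-80.0, -48.0)
ALPHA_PSI_RANGE = (-59.0, -27.0)
BETA_PHI_RANGE = (-150.0, -90.0)
BETA_PSI_RANGE = (90.0, 150.0)

# Ideal backbone geometry (nm / degrees).
BOND_N_CA = 0.146
BOND_CA_C = 0.152
BOND_C_N = 0.133
BOND_C_O = 0.123
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

CLASH_DISTANCE = 0.25  # nm, non-bonded heavy-atom clash threshold
_STATE_NAMES = ("alpha", "beta", "coil")


@dataclass
class PropensityProfile:
    """Per-residue (alpha, beta, coil) state probabilities for one chain."""

    p_alpha: np.ndarray
    p_beta: np.ndarray

    def __post_init__(self) -> None:
        self.p_alpha = np.atleast_1d(np.asarray(self.p_alpha, dtype=float))
        self.p_beta = np.atleast_1d(np.asarray(self.p_beta, dtype=float))
        if self.p_alpha.shape != self.p_beta.shape:
            raise ValueError("p_alpha and p_beta must have equal length")
        if np.any(self.p_alpha < 0) or np.any(self.p_beta < 0):
            raise ValueError("propensities must be non-negative")
        if np.any(self.p_alpha + self.p_beta > 1 + 1e-12):
            raise ValueError("p_alpha + p_beta must not exceed 1")

    @classmethod
    def uniform(cls, n_residues: int, p_alpha: float, p_beta: float) -> "PropensityProfile":
        return cls(np.full(n_residues, p_alpha), np.full(n_residues, p_beta))

    @property
    def n_residues(self) -> int:
        return len(self.p_alpha)

    @property
    def p_coil(self) -> np.ndarray:
        return 1.0 - self.p_alpha - self.p_beta


@dataclass
class DimerSpec:
    """Two chain profiles plus a target inter-chain contact architecture."""

    profile_a: PropensityProfile
    profile_b: PropensityProfile
    inter_contact_pairs: list[tuple[int, int]] = field(default_factory=list)
    contact_distance: float = 0.8

    def __post_init__(self) -> None:
        if self.contact_distance <= 0:
            raise ValueError("contact_distance must be positive")
        for i, j in self.inter_contact_pairs:
            if not (0 <= i < self.profile_a.n_residues):
                raise ValueError(f"contact residue {i} outside chain A")
            if not (0 <= j < self.profile_b.n_residues):
                raise ValueError(f"contact residue {j} outside chain B")


def _in_box(phi: float, psi: float, phi_range, psi_range) -> bool:
    return phi_range[0] <= phi <= phi_range[1] and psi_range[0] <= psi <= psi_range[1]


def _sample_box(rng: np.random.Generator, phi_range, psi_range, margin: float = 0.1):
    phi = rng.uniform(phi_range[0] + margin, phi_range[1] - margin)
    psi = rng.uniform(psi_range[0] + margin, psi_range[1] - margin)
    return phi, psi


def _sample_coil(rng: np.random.Generator):
    # uniform on the Ramachandran square minus both criterion boxes
    while True:
        phi = rng.uniform(-180.0, 180.0)
        psi = rng.uniform(-180.0, 180.0)
        if _in_box(phi, psi, ALPHA_PHI_RANGE, ALPHA_PSI_RANGE):
            continue
        if _in_box(phi, psi, BETA_PHI_RANGE, BETA_PSI_RANGE):
            continue
        return phi, psi


def sample_states(profile: PropensityProfile, rng: np.random.Generator) -> np.ndarray:
    """Draw one state index per residue (0=alpha, 1=beta, 2=coil)."""
    u = rng.random(profile.n_residues)
    states = np.full(profile.n_residues, 2, dtype=int)
    states[u < profile.p_alpha] = 0
    states[(u >= profile.p_alpha) & (u < profile.p_alpha + profile.p_beta)] = 1
    return states


def sample_dihedrals_for_states(states: np.ndarray, rng: np.random.Generator):
    phi = np.empty(len(states))
    psi = np.empty(len(states))
    for i, s in enumerate(states):
        if s == 0:
            phi[i], psi[i] = _sample_box(rng, ALPHA_PHI_RANGE, ALPHA_PSI_RANGE)
        elif s == 1:
            phi[i], psi[i] = _sample_box(rng, BETA_PHI_RANGE, BETA_PSI_RANGE)
        else:
            phi[i], psi[i] = _sample_coil(rng)
    return phi, psi


def build_chain_frame(phi: np.ndarray, psi: np.ndarray, chain_id: str = "A",
                      residue_name: str = "ALA") -> StructureFrame:
    """Build an N/CA/C/O backbone from per-residue dihedrals.

    phi[0] and psi[-1] are not geometrically encoded (undefined at the
    termini); values passed there are ignored.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi/psi length mismatch")
    if n_res < 1:
        raise ValueError("need at least one residue")

    n_xyz = np.empty((n_res, 3))
    ca_xyz = np.empty((n_res, 3))
    c_xyz = np.empty((n_res, 3))

    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (BOND_N_CA, 0.0, 0.0)
    # first C: phi[0] undefined, use an arbitrary reference torsion
    ref = np.array([0.0, -1.0, 0.0])
    c_xyz[0] = place_atom(ref, n_xyz[0], ca_xyz[0], BOND_CA_C, ANGLE_N_CA_C, -120.0)

    for i in range(1, n_res):
        n_xyz[i] = place_atom(n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_xyz[i] = place_atom(ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
                               BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_xyz[i] = place_atom(c_xyz[i - 1], n_xyz[i], ca_xyz[i],
                              BOND_CA_C, ANGLE_N_CA_C, phi[i])

    o_xyz = np.empty((n_res, 3))
    for i in range(n_res):
        tors = psi[i] + 180.0 if i < n_res - 1 else 0.0
        o_xyz[i] = place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                              BOND_C_O, ANGLE_CA_C_O, tors)

    coords = np.empty((4 * n_res, 3))
    atom_names, res_idx = [], []
    for i in range(n_res):
        coords[4 * i] = n_xyz[i]
        coords[4 * i + 1] = ca_xyz[i]
        coords[4 * i + 2] = c_xyz[i]
        coords[4 * i + 3] = o_xyz[i]
        atom_names += ["N", "CA", "C", "O"]
        res_idx += [i] * 4
    return StructureFrame(
        coords=coords,
        atom_names=np.array(atom_names, dtype=object),
        residue_index=np.array(res_idx),
        residue_name=np.array([residue_name] * (4 * n_res), dtype=object),
        chain_id=np.array([chain_id] * (4 * n_res), dtype=object),
    )


def _has_clash(frame: StructureFrame, threshold: float = CLASH_DISTANCE) -> bool:
    coords = frame.coords
    n = len(coords)
    if n < 3:
        return False
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    # mask bonded / same-residue neighbourhood: atoms within one residue of
    # each other along the chain are connected via short covalent paths
    res = frame.residue_index
    same_chain = frame.chain_id[:, None] == frame.chain_id[None, :]
    near = same_chain & (np.abs(res[:, None] - res[None, :]) <= 1)
    d[near] = np.inf
    return bool(np.any(d < threshold))


def _sample_chain_frame(profile: PropensityProfile, rng: np.random.Generator,
                        chain_id: str, max_retries: int = 50) -> StructureFrame:
    best = None
    for _ in range(max_retries):
        states = sample_states(profile, rng)
        phi, psi = sample_dihedrals_for_states(states, rng)
        frame = build_chain_frame(phi, psi, chain_id=chain_id)
        if not _has_clash(frame):
            return frame
        if best is None:
            best = frame
    return best  # bounded retries exhausted; keep a (mildly) clashing frame


def sample_dihedral_chain(profile: PropensityProfile, n_frames: int, seed: int,
                          chain_id: str = "A") -> Ensemble:
    """Generate an ensemble of single-chain conformations from a profile.

    Per frame each residue independently draws alpha/beta/coil; alpha and
    beta residues receive dihedrals strictly inside the corresponding
    criterion box, coil residues outside both.  Deterministic under seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = [_sample_chain_frame(profile, rng, chain_id) for _ in range(n_frames)]
    return Ensemble(frames=frames, frame_times=np.arange(n_frames, dtype=float))


def _merge_frames(a: StructureFrame, b: StructureFrame) -> StructureFrame:
    return StructureFrame(
        coords=np.vstack([a.coords, b.coords]),
        atom_names=np.concatenate([a.atom_names, b.atom_names]),
        residue_index=np.concatenate([a.residue_index, b.residue_index]),
        residue_name=np.concatenate([a.residue_name, b.residue_name]),
        chain_id=np.concatenate([a.chain_id, b.chain_id]),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _dock_chain_b(frame_a: StructureFrame, frame_b: StructureFrame,
                  spec: DimerSpec, rng: np.random.Generator,
                  n_candidates: int = 60) -> StructureFrame | None:
    """Rigid-body place chain B; returns the docked frame or None."""
    ca_a = frame_a.ca_coords()
    ca_b = frame_b.ca_coords()
    pairs = spec.inter_contact_pairs
    if not pairs:
        # push B away along a random direction until min distance >= 2 nm
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        span = (np.linalg.norm(frame_a.coords - frame_a.coords.mean(0), axis=1).max()
                + np.linalg.norm(frame_b.coords - frame_b.coords.mean(0), axis=1).max())
        offset = frame_a.coords.mean(0) - frame_b.coords.mean(0) + direction * (span + 2.5)
        moved = frame_b.select(np.ones(frame_b.n_atoms, dtype=bool))
        moved.coords = frame_b.coords + offset
        return moved

    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    target = 0.55 * spec.contact_distance
    best_frame, best_score = None, np.inf
    for _ in range(n_candidates):
        rot = _random_rotation(rng)
        b_rot = (ca_b - ca_b.mean(0)) @ rot.T
        # translation matching contact anchors in a least-squares sense,
        # with a small random offset so distinct frames differ
        trans = (ca_a[ia].mean(0) - b_rot[ib].mean(0)) + rng.normal(scale=0.05, size=3)
        coords_b = (frame_b.coords - ca_b.mean(0)) @ rot.T + trans
        cand_ca_b = b_rot + trans
        dists = np.linalg.norm(ca_a[ia] - cand_ca_b[ib], axis=1)
        moved = frame_b.select(np.ones(frame_b.n_atoms, dtype=bool))
        moved.coords = coords_b
        merged = _merge_frames(frame_a, moved)
        clash = _has_clash(merged)
        score = float(np.sum(np.maximum(dists - spec.contact_distance, 0.0) ** 2)
                      + np.sum((dists - target) ** 2) * 1e-3
                      + (10.0 if clash else 0.0))
        if score < best_score:
            best_score, best_frame = score, moved
        if not clash and np.all(dists <= spec.contact_distance):
            return moved
    return best_frame


def build_dimer(spec: DimerSpec, n_frames: int, seed: int,
                max_dock_retries: int = 8) -> Ensemble:
    """Generate a two-chain ensemble with the requested inter-chain contacts.

    Each requested pair has a Calpha-Calpha distance <= ``contact_distance``
    in at least 90% of frames; with an empty contact list the chains are
    separated by >= 2 nm.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    n_satisfied = 0
    for _ in range(n_frames):
        satisfied = False
        merged = None
        for _ in range(max_dock_retries):
            fa = _sample_chain_frame(spec.profile_a, rng, "A")
            fb = _sample_chain_frame(spec.profile_b, rng, "B")
            docked = _dock_chain_b(fa, fb, spec, rng)
            if docked is None:
                continue
            merged = _merge_frames(fa, docked)
            if not spec.inter_contact_pairs:
                satisfied = True
                break
            ca_a = fa.ca_coords()
            ca_b = docked.ca_coords()
            dists = np.array([
                np.linalg.norm(ca_a[i] - ca_b[j]) for i, j in spec.inter_contact_pairs
            ])
            if np.all(dists <= spec.contact_distance):
                satisfied = True
                break
        if merged is None:
            raise RuntimeError("docking failed to produce any candidate")
        frames.append(merged)
        n_satisfied += satisfied
    if spec.inter_contact_pairs and n_satisfied < 0.9 * n_frames:
        raise RuntimeError(
            f"infeasible contact set: only {n_satisfied}/{n_frames} frames satisfied"
        )
    return Ensemble(frames=frames, frame_times=np.arange(n_frames, dtype=float))


def sample_rupture_data(components, n: int, seed: int, label: str = "synthetic",
                        normalized: bool = True) -> RuptureDataset:
    """Draw rupture (force, position) samples from a Gaussian mixture.

    ``components`` is a list of (weight, force_mean_pN, force_sd_pN,
    pos_mean, pos_sd).  Forces are truncated at 0 (rejection); positions are
    truncated to [0, 1] when ``normalized``.
    """
    components = [tuple(map(float, c)) for c in components]
    if n < 0:
        raise ValueError("n must be non-negative")
    weights = np.array([c[0] for c in components])
    if len(weights) == 0 or not np.isclose(weights.sum(), 1.0):
        raise ValueError("component weights must sum to 1")
    if any(c[2] <= 0 or c[4] <= 0 for c in components):
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    if n == 0:
        return RuptureDataset(np.empty(0), np.empty(0), label=label, normalized=normalized)
    idx = rng.choice(len(components), size=n, p=weights)
    forces = np.empty(n)
    positions = np.empty(n)
    for k, (_, fm, fs, pm, ps) in enumerate(components):
        mask = idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        f = rng.normal(fm, fs, size=m)
        while np.any(f < 0):  # truncate at zero by rejection
            bad = f < 0
            f[bad] = rng.normal(fm, fs, size=int(bad.sum()))
        p = rng.normal(pm, ps, size=m)
        if normalized:
            while np.any((p < 0) | (p > 1)):
                bad = (p < 0) | (p > 1)
                p[bad] = rng.normal(pm, ps, size=int(bad.sum()))
        forces[mask] = f
        positions[mask] = p
    return RuptureDataset(forces, positions, label=label, normalized=normalized)
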