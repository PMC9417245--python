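"""Monte Carlo pulling of two-chain Calpha bead models.

A structure-based (Go-type) energy is built from a reference dimer
conformation: native contacts get 12-10 wells at their native distances,
consecutive beads are joined by stiff harmonic pseudo-bonds, and all other
pairs are purely repulsive.  Two virtual springs attached to the anchor
beads (Calpha of each chain's first residue) recede along the initial
anchor-anchor axis, adding (k/2) * [L(x) - L0 - v*t]^2 to the energy; bead
coordinates evolve by Metropolis Monte Carlo with t advancing once per
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core_io import Ensemble, RuptureDataset, StructureFrame
from .units import NM_PER_FM, kt_pn_nm

__all__ = [
    "EnergyModel",
    "PullingProtocol",
    "PullingTrace",
    "build_energy_model",
    "total_energy",
    "run_pulling",
    "pull_ensemble",
]

KIND_NONE, KIND_BOND, KIND_CONTACT, KIND_REP = 0, 1, 2, 3

DEFAULT_BOND_STIFFNESS = 500.0  # kT / nm^2
DEFAULT_REPULSION_SIGMA = 0.38  # nm
DEFAULT_REPULSION_EPS = 1.0  # kT
CONTACT_BREAK_FACTOR = 1.5  # contact counts as formed while r < factor * r0


@dataclass
class EnergyModel:
    """Go-type Calpha energy for a two-chain system (energies in kT)."""

    n_beads: int
    chain_of_bead: np.ndarray  # 0 / 1
    bonds: np.ndarray  # (nb_bonds, 2) bead indices
    bond_r0: np.ndarray
    bond_k: float
    contacts: np.ndarray  # (nc, 2) bead indices
    contact_eps: np.ndarray  # kT
    contact_r0: np.ndarray  # nm
    contact_inter: np.ndarray  # bool per contact
    repulsion_sigma: float = DEFAULT_REPULSION_SIGMA
    repulsion_eps: float = DEFAULT_REPULSION_EPS

    def n_inter_contacts(self) -> int:
        return int(self.contact_inter.sum())

    def pair_tables(self):
        """Dense (kind, eps, r0) matrices for the MC kernel."""
        nb = self.n_beads
        kind = np.full((nb, nb), KIND_REP, dtype=np.int8)
        eps = np.full((nb, nb), self.repulsion_eps)
        r0 = np.full((nb, nb), self.repulsion_sigma)
        np.fill_diagonal(kind, KIND_NONE)
        for (i, j), b0 in zip(self.bonds, self.bond_r0):
            kind[i, j] = kind[j, i] = KIND_BOND
            eps[i, j] = eps[j, i] = self.bond_k
            r0[i, j] = r0[j, i] = b0
        for k, (i, j) in enumerate(self.contacts):
            kind[i, j] = kind[j, i] = KIND_CONTACT
            eps[i, j] = eps[j, i] = self.contact_eps[k]
            r0[i, j] = r0[j, i] = self.contact_r0[k]
        return kind, eps, r0


@dataclass
class PullingProtocol:
    """Virtual-spring pulling protocol.

    ``k`` in pN/nm; ``v_fm_per_step`` in femtometres per elementary MC step
    (one attempted bead move); the anchor target distance advances by
    ``v_fm_per_step * n_beads`` fm per sweep.
    """

    k: float = 35.0  # pN/nm
    v_fm_per_step: float = 0.083
    temperature: float = 300.0
    max_sweeps: int = 200_000
    record_stride: int = 10  # sweeps between trace records
    move_sigma: float = 0.03  # nm, single-bead displacement scale
    crankshaft_fraction: float = 0.2
    dwell_sweeps: int = 100  # contacts must stay broken this long
    smooth_records: int = 21  # moving-average window for rupture extraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")
        if self.v_fm_per_step < 0:
            raise ValueError("pulling speed must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def v_nm_per_sweep(self, n_beads: int) -> float:
        return self.v_fm_per_step * NM_PER_FM * n_beads


@dataclass
class PullingTrace:
    """Recorded pulling trajectory plus rupture summary."""

    sweeps: np.ndarray
    distance: np.ndarray  # L(x), nm
    force: np.ndarray  # pN, spring tension k*(L0 + v t - L); positive = stretched
    inter_contacts: np.ndarray  # formed inter-chain native contacts
    l0: float
    rupture_force: float | None = None
    rupture_position: float | None = None  # L at rupture - L0 (nm)
    normalized_position: float | None = None
    censored: bool = False
    final_coords: np.ndarray | None = None


def build_energy_model(frame: StructureFrame, contact_cutoff: float = 0.8,
                       epsilon_intra: float = 1.0, epsilon_inter: float = 1.0,
                       bond_stiffness: float = DEFAULT_BOND_STIFFNESS,
                       repulsion_sigma: float = DEFAULT_REPULSION_SIGMA) -> EnergyModel:
    """Derive a Go-type model from a two-chain reference conformation.

    Native contacts are Calpha pairs within ``contact_cutoff`` nm, excluding
    intra-chain pairs with |i - j| <= 2; wells are 12-10 potentials of depth
    epsilon (kT) with minima at the native distances.
    """
    chains = frame.chains
    if len(chains) != 2:
        raise ValueError("energy model requires exactly two chains")
    ca_a = frame.ca_coords(chain=chains[0])
    ca_b = frame.ca_coords(chain=chains[1])
    coords = np.vstack([ca_a, ca_b])
    na = len(ca_a)
    nb_total = len(coords)
    chain_of_bead = np.array([0] * na + [1] * (nb_total - na))

    bonds, bond_r0 = [], []
    for i in range(nb_total - 1):
        if chain_of_bead[i] == chain_of_bead[i + 1]:
            bonds.append((i, i + 1))
            bond_r0.append(np.linalg.norm(coords[i + 1] - coords[i]))

    contacts, eps_list, r0_list, inter_list = [], [], [], []
    for i in range(nb_total):
        for j in range(i + 1, nb_total):
            inter = chain_of_bead[i] != chain_of_bead[j]
            if not inter and j - i <= 2:
                continue
            r = np.linalg.norm(coords[j] - coords[i])
            if r <= contact_cutoff:
                eps = epsilon_inter if inter else epsilon_intra
                if eps <= 0:
                    continue  # zero-depth wells degrade to plain repulsion
                contacts.append((i, j))
                eps_list.append(eps)
                r0_list.append(r)
                inter_list.append(inter)
    return EnergyModel(
        n_beads=nb_total,
        chain_of_bead=chain_of_bead,
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.asarray(bond_r0, dtype=float),
        bond_k=float(bond_stiffness),
        contacts=np.asarray(contacts, dtype=int).reshape(-1, 2),
        contact_eps=np.asarray(eps_list, dtype=float),
        contact_r0=np.asarray(r0_list, dtype=float),
        contact_inter=np.asarray(inter_list, dtype=bool),
        repulsion_sigma=repulsion_sigma,
    )


def ca_positions(frame: StructureFrame) -> np.ndarray:
    chains = frame.chains
    return np.vstack([frame.ca_coords(chain=c) for c in chains])


def anchor_indices(model: EnergyModel) -> tuple[int, int]:
    """Bead indices of the two anchors (first residue of each chain)."""
    a1 = int(np.where(model.chain_of_bead == 0)[0][0])
    a2 = int(np.where(model.chain_of_bead == 1)[0][0])
    return a1, a2


def _pair_energy(kind: int, eps: float, r0: float, r: float) -> float:
    if kind == KIND_BOND:
        return 0.5 * eps * (r - r0) ** 2
    if kind == KIND_CONTACT:
        q = r0 / r
        return eps * (5.0 * q ** 12 - 6.0 * q ** 10)
    if kind == KIND_REP:
        if r >= r0:
            return 0.0
        return eps * ((r0 / r) ** 12 - 1.0)
    return 0.0


def conformational_energy(model: EnergyModel, coords: np.ndarray) -> float:
    """E(x) in kT: bonds + native wells + excluded-volume repulsion."""
    kind, eps, r0 = model.pair_tables()
    total = 0.0
    for i in range(model.n_beads):
        for j in range(i + 1, model.n_beads):
            r = float(np.linalg.norm(coords[j] - coords[i]))
            total += _pair_energy(int(kind[i, j]), float(eps[i, j]), float(r0[i, j]), r)
    return total


def total_energy(model: EnergyModel, coords: np.ndarray, protocol: PullingProtocol,
                 t_sweeps: float, l0: float) -> float:
    """Total energy in kT: E(x) + (k/2) [L(x) - L0 - v t]^2."""
    a1, a2 = anchor_indices(model)
    length = float(np.linalg.norm(coords[a2] - coords[a1]))
    k_kt = protocol.k / kt_pn_nm(protocol.temperature)
    target = l0 + protocol.v_nm_per_sweep(model.n_beads) * t_sweeps
    return conformational_energy(model, coords) + 0.5 * k_kt * (length - target) ** 2


@njit(cache=True)
def _mc_kernel(pos, kind, eps, r0, a1, a2, k_spring_kt, l0, v_per_sweep,
               n_sweeps, record_stride, move_sigma, crank_fraction,
               inter_i, inter_j, inter_r0, break_factor, seed):  # pragma: no cover
    np.random.seed(seed)
    nb = pos.shape[0]
    n_records = n_sweeps // record_stride + 1
    rec_sweep = np.zeros(n_records)
    rec_l = np.zeros(n_records)
    rec_force_kt = np.zeros(n_records)
    rec_contacts = np.zeros(n_records, dtype=np.int64)

    def pair_e(kd, ep, rr0, r):
        if kd == 1:
            d = r - rr0
            return 0.5 * ep * d * d
        elif kd == 2:
            q = rr0 / r
            q2 = q * q
            q10 = q2 * q2 * q2 * q2 * q2
            return ep * (5.0 * q10 * q2 - 6.0 * q10)
        elif kd == 3:
            if r >= rr0:
                return 0.0
            q = rr0 / r
            q2 = q * q
            return ep * (q2 * q2 * q2 * q2 * q2 * q2 - 1.0)
        return 0.0

    def bead_energy(b, pnew):
        e = 0.0
        for j in range(nb):
            if j == b:
                continue
            dx = pnew[0] - pos[j, 0]
            dy = pnew[1] - pos[j, 1]
            dz = pnew[2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-6:
                r = 1e-6
            e += pair_e(kind[b, j], eps[b, j], r0[b, j], r)
        return e

    def anchor_l(pa, pb):
        dx = pa[0] - pb[0]
        dy = pa[1] - pb[1]
        dz = pa[2] - pb[2]
        return np.sqrt(dx * dx + dy * dy + dz * dz)

    rec_idx = 0
    for sweep in range(n_sweeps + 1):
        t = float(sweep)
        target = l0 + v_per_sweep * t
        if sweep % record_stride == 0 and rec_idx < n_records:
            length = anchor_l(pos[a1], pos[a2])
            rec_sweep[rec_idx] = t
            rec_l[rec_idx] = length
            rec_force_kt[rec_idx] = k_spring_kt * (target - length)
            cnt = 0
            for c in range(inter_i.shape[0]):
                dxc = pos[inter_i[c], 0] - pos[inter_j[c], 0]
                dyc = pos[inter_i[c], 1] - pos[inter_j[c], 1]
                dzc = pos[inter_i[c], 2] - pos[inter_j[c], 2]
                if np.sqrt(dxc * dxc + dyc * dyc + dzc * dzc) < break_factor * inter_r0[c]:
                    cnt += 1
            rec_contacts[rec_idx] = cnt
            rec_idx += 1
        if sweep == n_sweeps:
            break
        for _ in range(nb):
            b = np.random.randint(nb)
            old = pos[b].copy()
            new = old.copy()
            if np.random.random() < crank_fraction and 0 < b < nb - 1 \
                    and kind[b - 1, b] == 1 and kind[b, b + 1] == 1:
                # crankshaft: rotate bead about the axis through neighbours
                ax = pos[b + 1] - pos[b - 1]
                axn = np.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
                if axn > 1e-9:
                    ax = ax / axn
                    theta = (np.random.random() - 0.5) * np.pi
                    rel = old - pos[b - 1]
                    dot = rel[0] * ax[0] + rel[1] * ax[1] + rel[2] * ax[2]
                    para = dot * ax
                    perp = rel - para
                    cr = np.empty(3)
                    cr[0] = ax[1] * perp[2] - ax[2] * perp[1]
                    cr[1] = ax[2] * perp[0] - ax[0] * perp[2]
                    cr[2] = ax[0] * perp[1] - ax[1] * perp[0]
                    new = pos[b - 1] + para + np.cos(theta) * perp + np.sin(theta) * cr
            else:
                new = old + move_sigma * np.random.randn(3)
            de = bead_energy(b, new) - bead_energy(b, old)
            if b == a1 or b == a2:
                other = pos[a2] if b == a1 else pos[a1]
                l_old = anchor_l(old, other)
                l_new = anchor_l(new, other)
                de += 0.5 * k_spring_kt * ((l_new - target) ** 2 - (l_old - target) ** 2)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                pos[b, 0] = new[0]
                pos[b, 1] = new[1]
                pos[b, 2] = new[2]
    return rec_sweep[:rec_idx], rec_l[:rec_idx], rec_force_kt[:rec_idx], rec_contacts[:rec_idx]


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(x) < 2:
        return np.asarray(x, dtype=float)
    width = min(width, len(x))
    kernel = np.ones(width) / width
    pad_lo = np.full(width // 2, x[0])
    pad_hi = np.full(width - width // 2 - 1, x[-1])
    padded = np.concatenate([pad_lo, x, pad_hi])
    return np.convolve(padded, kernel, mode="valid")


def run_pulling(frame: StructureFrame, model: EnergyModel,
                protocol: PullingProtocol, contour_length: float | None = None,
                stop_when_ruptured: bool = True) -> PullingTrace:
    """Run one Metropolis pulling trajectory.

    Rupture is the maximum (smoothed) spring force over the segment ending
    when the inter-chain native-contact count first reaches zero and stays
    zero for ``dwell_sweeps``; runs that never separate are censored.
    """
    coords = ca_positions(frame).copy()
    if coords.shape[0] != model.n_beads:
        raise ValueError("frame does not match energy model")
    a1, a2 = anchor_indices(model)
    l0 = float(np.linalg.norm(coords[a2] - coords[a1]))
    kind, eps, r0 = model.pair_tables()
    inter = model.contacts[model.contact_inter] if len(model.contacts) else np.empty((0, 2), int)
    inter_r0 = model.contact_r0[model.contact_inter] if len(model.contacts) else np.empty(0)
    k_kt = protocol.k / kt_pn_nm(protocol.temperature)
    sweeps, lvals, force_kt, contacts = _mc_kernel(
        coords, kind.astype(np.int8), eps, r0, a1, a2, k_kt, l0,
        protocol.v_nm_per_sweep(model.n_beads),
        protocol.max_sweeps, protocol.record_stride, protocol.move_sigma,
        protocol.crankshaft_fraction,
        inter[:, 0].astype(np.int64), inter[:, 1].astype(np.int64),
        inter_r0.astype(np.float64), CONTACT_BREAK_FACTOR,
        protocol.seed & 0x7FFFFFFF,
    )
    force_pn = force_kt * kt_pn_nm(protocol.temperature)
    trace = PullingTrace(
        sweeps=sweeps, distance=lvals, force=force_pn,
        inter_contacts=contacts, l0=l0, final_coords=coords,
    )
    _extract_rupture(trace, protocol, contour_length, model.n_inter_contacts() > 0)
    return trace


def _extract_rupture(trace: PullingTrace, protocol: PullingProtocol,
                     contour_length: float | None, had_contacts: bool) -> None:
    contacts = trace.inter_contacts
    n = len(contacts)
    dwell_records = max(1, protocol.dwell_sweeps // protocol.record_stride)
    sep_idx = None
    run = 0
    for i in range(n):
        if contacts[i] == 0:
            run += 1
            if run >= dwell_records:
                sep_idx = i - dwell_records + 1
                break
        else:
            run = 0
    if sep_idx is None:
        if had_contacts:
            trace.censored = True
            return
        sep_idx = 0
    smoothed = _moving_average(trace.force, protocol.smooth_records)
    end = max(sep_idx, 1)
    seg = smoothed[: end + 1]
    peak = int(np.argmax(seg))
    trace.rupture_force = float(max(seg[peak], 0.0))
    trace.rupture_position = float(trace.distance[peak] - trace.l0)
    if contour_length is not None:
        if contour_length <= 0:
            raise ValueError("contour_length must be positive")
        trace.normalized_position = float(
            np.clip(trace.rupture_position / contour_length, 0.0, 1.0)
        )


def pull_ensemble(conformations: Ensemble, protocol: PullingProtocol,
                  n_runs_per_conf: int = 1, contact_cutoff: float = 0.8,
                  epsilon_intra: float = 1.0, epsilon_inter: float = 1.0,
                  contour_length: float | None = None,
                  label: str = "mcp") -> RuptureDataset:
    """Aggregate rupture events over conformations and seeds.

    Each run uses seed ``protocol.seed + conf_index * n_runs + run_index``.
    Censored runs are dropped; raises if every run is censored.
    """
    forces, positions = [], []
    for ci, frame in enumerate(conformations.frames):
        model = build_energy_model(frame, contact_cutoff=contact_cutoff,
                                   epsilon_intra=epsilon_intra,
                                   epsilon_inter=epsilon_inter)
        for ri in range(n_runs_per_conf):
            proto = PullingProtocol(
                k=protocol.k, v_fm_per_step=protocol.v_fm_per_step,
                temperature=protocol.temperature, max_sweeps=protocol.max_sweeps,
                record_stride=protocol.record_stride, move_sigma=protocol.move_sigma,
                crankshaft_fraction=protocol.crankshaft_fraction,
                dwell_sweeps=protocol.dwell_sweeps,
                smooth_records=protocol.smooth_records,
                seed=protocol.seed + ci * n_runs_per_conf + ri,
            )
            trace = run_pulling(frame, model, proto, contour_length=contour_length)
            if trace.censored or trace.rupture_force is None:
                continue
            forces.append(trace.rupture_force)
            positions.append(
                trace.normalized_position if contour_length is not None
                else trace.rupture_position
            )
    if not forces:
        raise RuntimeError("all pulling runs were censored")
    return RuptureDataset(
        forces=np.asarray(forces),
        positions=np.clip(np.asarray(positions), 0.0, None),
        label=label,
        normalized=contour_length is not None,
    )
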