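"""Secondary-structure assignment and time-resolved content.

Two assignment routes are provided: the dihedral-box criterion on pairs of
consecutive residues, and a reduced hydrogen-bond (Kabsch-Sander energy)
assignment yielding H/E/C labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Ensemble, StructureFrame
from .geometry import dihedral_angle
from .synthetic import (
    ALPHA_PHI_RANGE,
    ALPHA_PSI_RANGE,
    BETA_PHI_RANGE,
    BETA_PSI_RANGE,
)

__all__ = [
    "DihedralSeries",
    "SSMatrix",
    "compute_dihedrals",
    "assign_dihedral_ss",
    "ss_fraction_timeseries",
    "running_average",
    "assign_hbond_ss",
    "ss_probability_per_residue",
]

COIL, ALPHA, BETA = 0, 1, 2
STATE_NAMES = {COIL: "coil", ALPHA: "alpha", BETA: "beta"}


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone dihedrals in degrees.

    Entries undefined at chain termini are NaN.  ``chain_of_residue`` maps
    each residue column to its chain so consecutive-residue rules never
    cross a chain boundary.
    """

    phi: np.ndarray  # (T, n) degrees, NaN where undefined
    psi: np.ndarray
    chain_of_residue: np.ndarray  # (n,) chain label per residue column

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.chain_of_residue = np.asarray(self.chain_of_residue, dtype=object)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must share a shape")
        if self.phi.ndim != 2:
            raise ValueError("phi/psi must be (T, n_residues)")
        if self.phi.shape[1] != len(self.chain_of_residue):
            raise ValueError("chain_of_residue length mismatch")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


@dataclass
class SSMatrix:
    """Per-frame, per-residue labels with alpha/beta indicator views."""

    labels: np.ndarray  # (T, n) ints in {COIL, ALPHA, BETA}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def delta_alpha(self) -> np.ndarray:
        return (self.labels == ALPHA).astype(float)

    @property
    def delta_beta(self) -> np.ndarray:
        return (self.labels == BETA).astype(float)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]


def _backbone_by_residue(frame: StructureFrame):
    """Ordered (chain, residue) list with N/CA/C/O coordinate lookups."""
    entries = []
    seen = {}
    for k in range(frame.n_atoms):
        key = (frame.chain_id[k], frame.residue_index[k])
        if key not in seen:
            seen[key] = {"chain": frame.chain_id[k], "res": frame.residue_index[k]}
            entries.append(seen[key])
        seen[key][frame.atom_names[k]] = frame.coords[k]
    return entries


def compute_dihedrals(ensemble: Ensemble) -> DihedralSeries:
    """Standard IUPAC phi/psi per residue, each chain independently.

    phi of the first and psi of the last residue of each chain are NaN.
    """
    frame0 = ensemble.frames[0]
    entries0 = _backbone_by_residue(frame0)
    n = len(entries0)
    for e in entries0:
        for name in ("N", "CA", "C"):
            if name not in e:
                raise ValueError(
                    f"residue {e['res']} of chain {e['chain']} lacks backbone atom {name}"
                )
    chains = np.array([e["chain"] for e in entries0], dtype=object)
    T = ensemble.n_frames
    phi = np.full((T, n), np.nan)
    psi = np.full((T, n), np.nan)
    for t, frame in enumerate(ensemble.frames):
        entries = _backbone_by_residue(frame)
        for i in range(n):
            same_prev = i > 0 and entries[i - 1]["chain"] == entries[i]["chain"]
            same_next = i < n - 1 and entries[i + 1]["chain"] == entries[i]["chain"]
            e = entries[i]
            if same_prev:
                phi[t, i] = dihedral_angle(
                    entries[i - 1]["C"], e["N"], e["CA"], e["C"]
                )
            if same_next:
                psi[t, i] = dihedral_angle(
                    e["N"], e["CA"], e["C"], entries[i + 1]["N"]
                )
    return DihedralSeries(phi=phi, psi=psi, chain_of_residue=chains)


def _in_box(phi: np.ndarray, psi: np.ndarray, phi_range, psi_range) -> np.ndarray:
    return (
        (phi >= phi_range[0]) & (phi <= phi_range[1])
        & (psi >= psi_range[0]) & (psi <= psi_range[1])
    )


def assign_dihedral_ss(dihedrals: DihedralSeries, pair_attribution: str = "both") -> SSMatrix:
    """Assign alpha/beta/coil by the two-consecutive-residue dihedral rule.

    A consecutive same-chain residue pair with both (phi, psi) inside the
    alpha box marks alpha (beta box analogous); bounds are inclusive.  With
    ``pair_attribution="both"`` both residues of a satisfying pair are
    marked; with ``"first"`` only the leading residue.
    """
    if pair_attribution not in ("both", "first"):
        raise ValueError("pair_attribution must be 'both' or 'first'")
    phi, psi = dihedrals.phi, dihedrals.psi
    defined = ~np.isnan(phi) & ~np.isnan(psi)
    in_alpha = np.where(defined, _in_box(phi, psi, ALPHA_PHI_RANGE, ALPHA_PSI_RANGE), False)
    in_beta = np.where(defined, _in_box(phi, psi, BETA_PHI_RANGE, BETA_PSI_RANGE), False)
    same_chain = dihedrals.chain_of_residue[:-1] == dihedrals.chain_of_residue[1:]
    pair_alpha = in_alpha[:, :-1] & in_alpha[:, 1:] & same_chain[None, :]
    pair_beta = in_beta[:, :-1] & in_beta[:, 1:] & same_chain[None, :]

    T, n = phi.shape
    mark_alpha = np.zeros((T, n), dtype=bool)
    mark_beta = np.zeros((T, n), dtype=bool)
    mark_alpha[:, :-1] |= pair_alpha
    mark_beta[:, :-1] |= pair_beta
    if pair_attribution == "both":
        mark_alpha[:, 1:] |= pair_alpha
        mark_beta[:, 1:] |= pair_beta
    labels = np.full((T, n), COIL, dtype=int)
    labels[mark_alpha] = ALPHA
    labels[mark_beta] = BETA  # disjoint boxes: a residue never earns both
    return SSMatrix(labels=labels)


def ss_fraction_timeseries(ss: SSMatrix, window: float, frame_times: np.ndarray):
    """Windowed secondary-structure fractions.

    Returns (window_start_times, fraction_alpha, fraction_beta) where each
    fraction is the mean of the state indicator over all residues and all
    frames falling in [s, s + window).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.shape[0] != ss.n_frames:
        raise ValueError("frame_times length mismatch")
    if window <= 0:
        raise ValueError("window must be positive")
    spacing = np.min(np.diff(frame_times)) if len(frame_times) > 1 else 0.0
    if len(frame_times) > 1 and window < spacing:
        raise ValueError("window smaller than frame spacing")
    t0, t1 = frame_times[0], frame_times[-1]
    n_windows = max(1, int(np.ceil((t1 - t0 + 1e-12) / window)))
    starts = t0 + window * np.arange(n_windows)
    frac_a = np.full(n_windows, np.nan)
    frac_b = np.full(n_windows, np.nan)
    da, db = ss.delta_alpha, ss.delta_beta
    for w, s in enumerate(starts):
        mask = (frame_times >= s) & (frame_times < s + window)
        if w == n_windows - 1:  # include the final frame at the right edge
            mask |= frame_times == t1
        if mask.any():
            frac_a[w] = da[mask].mean()
            frac_b[w] = db[mask].mean()
    return starts, frac_a, frac_b


def running_average(series: np.ndarray, width: int = 10) -> np.ndarray:
    """Centered moving average ignoring NaNs; width in samples."""
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    half = width // 2
    for i in range(len(series)):
        lo, hi = max(0, i - half), min(len(series), i + half + 1)
        chunk = series[lo:hi]
        if np.any(~np.isnan(chunk)):
            out[i] = np.nanmean(chunk)
    return out


# ---------------------------------------------------------------------------
# Reduced hydrogen-bond (Kabsch-Sander) assignment
# ---------------------------------------------------------------------------

_HB_Q1Q2_F = 0.084 * 332.0  # kcal/mol * Angstrom, partial charge product * factor
_HB_CUTOFF = -0.5  # kcal/mol


def _hbond_matrix(entries) -> np.ndarray:
    """hb[i, j] True if the CO of residue i bonds the NH of residue j."""
    n = len(entries)
    # amide H: 1.01 A from N, anti to the carbonyl O of the preceding residue
    h_pos = [None] * n
    for j in range(1, n):
        if entries[j]["chain"] != entries[j - 1]["chain"]:
            continue
        prev = entries[j - 1]
        if "C" not in prev or "O" not in prev or "N" not in entries[j]:
            continue
        direction = prev["C"] - prev["O"]
        direction = direction / np.linalg.norm(direction)
        h_pos[j] = entries[j]["N"] + 0.101 * direction  # nm
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if "C" not in entries[i] or "O" not in entries[i]:
            continue
        c, o = entries[i]["C"], entries[i]["O"]
        for j in range(n):
            if h_pos[j] is None or abs(i - j) < 1:
                continue
            if entries[i]["chain"] == entries[j]["chain"] and abs(
                entries[i]["res"] - entries[j]["res"]
            ) < 2 and i != j:
                # adjacent residues cannot H-bond in the Kabsch-Sander scheme
                continue
            nn, h = entries[j]["N"], h_pos[j]
            # distances in Angstrom for the electrostatic formula
            r_on = np.linalg.norm(o - nn) * 10.0
            r_ch = np.linalg.norm(c - h) * 10.0
            r_oh = np.linalg.norm(o - h) * 10.0
            r_cn = np.linalg.norm(c - nn) * 10.0
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9
            else:
                energy = _HB_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_CUTOFF:
                hb[i, j] = True
    return hb


def assign_hbond_ss(frame: StructureFrame) -> np.ndarray:
    """Reduced DSSP-style labels ('H', 'E', 'C') per residue.

    Helix from runs of i->i+4 hydrogen bonds, strand from parallel or
    antiparallel bridge patterns, everything else coil.
    """
    entries = _backbone_by_residue(frame)
    n = len(entries)
    for e in entries:
        if "O" not in e:
            raise ValueError(
                f"residue {e['res']} of chain {e['chain']} lacks a carbonyl O"
            )
    hb = _hbond_matrix(entries)
    labels = np.array(["C"] * n, dtype=object)

    # 4-turns: CO(i) -> NH(i+4) within one chain
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if entries[i]["chain"] == entries[i + 4]["chain"] and hb[i, i + 4]:
            turn4[i] = True
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            labels[i : i + 4] = "H"

    # bridges
    def bonded(i, j):
        return 0 <= i < n and 0 <= j < n and hb[i, j]

    for i in range(1, n - 1):
        for j in range(i + 2, n - 1):
            parallel = (bonded(i - 1, j) and bonded(j, i + 1)) or (
                bonded(j - 1, i) and bonded(i, j + 1)
            )
            antiparallel = (bonded(i, j) and bonded(j, i)) or (
                bonded(i - 1, j + 1) and bonded(j - 1, i + 1)
            )
            if parallel or antiparallel:
                if labels[i] != "H":
                    labels[i] = "E"
                if labels[j] != "H":
                    labels[j] = "E"
    return labels


def ss_probability_per_residue(ensemble: Ensemble, method: str = "dihedral") -> dict:
    """Per-chain, per-residue probabilities of each secondary-structure class.

    Returns {chain: (residue_indices, {class: probability array})}; classes
    are 'alpha'/'beta'/'coil' for the dihedral method and 'H'/'E'/'C' for
    the hydrogen-bond method.  Probabilities sum to 1 per residue.
    """
    if method not in ("dihedral", "hbond"):
        raise ValueError("method must be 'dihedral' or 'hbond'")
    frame0 = ensemble.frames[0]
    out: dict = {}
    if method == "dihedral":
        series = compute_dihedrals(ensemble)
        ss = assign_dihedral_ss(series)
        for chain in frame0.chains:
            cols = np.where(series.chain_of_residue == chain)[0]
            sub = ss.labels[:, cols]
            out[chain] = (
                frame0.residues_of_chain(chain),
                {
                    "alpha": (sub == ALPHA).mean(axis=0),
                    "beta": (sub == BETA).mean(axis=0),
                    "coil": (sub == COIL).mean(axis=0),
                },
            )
    else:
        entries = _backbone_by_residue(frame0)
        chains_per_res = np.array([e["chain"] for e in entries], dtype=object)
        all_labels = np.stack([assign_hbond_ss(f) for f in ensemble.frames])
        for chain in frame0.chains:
            cols = np.where(chains_per_res == chain)[0]
            sub = all_labels[:, cols]
            out[chain] = (
                frame0.residues_of_chain(chain),
                {
                    "H": (sub == "H").mean(axis=0),
                    "E": (sub == "E").mean(axis=0),
                    "C": (sub == "C").mean(axis=0),
                },
            )
    return out
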