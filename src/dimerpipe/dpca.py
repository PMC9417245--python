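"""Dihedral PCA and free-energy landscapes on the leading two components."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Ensemble
from .secondary_structure import DihedralSeries, compute_dihedrals

__all__ = [
    "DPCAModel",
    "EnergyLandscape",
    "dihedral_features",
    "fit_dpca",
    "project",
    "energy_landscape",
    "pooled_landscape",
]


@dataclass
class DPCAModel:
    """PCA over per-residue (cos phi, sin phi, cos psi, sin psi) features."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray  # non-increasing
    feature_columns: np.ndarray  # residue column per feature block


@dataclass
class EnergyLandscape:
    """Free energy (kT units) over a 2D grid of the first two components."""

    counts: np.ndarray
    free_energy: np.ndarray  # -ln(P / P_max); inf on empty bins
    x_edges: np.ndarray
    y_edges: np.ndarray
    minima: list = field(default_factory=list)  # (ix, iy, dG, representative frame)
    temperature: float = 300.0


def dihedral_features(series: DihedralSeries) -> tuple[np.ndarray, np.ndarray]:
    """sin/cos feature matrix (T, 4m) over residues with both angles defined."""
    defined = ~np.isnan(series.phi).any(axis=0) & ~np.isnan(series.psi).any(axis=0)
    cols = np.where(defined)[0]
    if len(cols) == 0:
        raise ValueError("no residues with fully defined dihedrals")
    phi = np.radians(series.phi[:, cols])
    psi = np.radians(series.psi[:, cols])
    feats = np.empty((series.n_frames, 4 * len(cols)))
    feats[:, 0::4] = np.cos(phi)
    feats[:, 1::4] = np.sin(phi)
    feats[:, 2::4] = np.cos(psi)
    feats[:, 3::4] = np.sin(psi)
    return feats, cols


def fit_dpca(ensemble: Ensemble) -> DPCAModel:
    """Fit PCA on mean-centred sin/cos dihedral features.

    Component signs are fixed by making the largest-magnitude loading of
    each component positive.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least two frames")
    feats, cols = dihedral_features(compute_dihedrals(ensemble))
    mean = feats.mean(axis=0)
    centered = feats - mean
    if np.allclose(centered, 0):
        # degenerate but legal: identical frames, all variances zero
        n_feat = feats.shape[1]
        comps = np.eye(n_feat)
        return DPCAModel(mean=mean, components=comps,
                         explained_variance=np.zeros(n_feat), feature_columns=cols)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s ** 2 / (feats.shape[0] - 1)
    comps = vt
    for k in range(comps.shape[0]):
        idx = np.argmax(np.abs(comps[k]))
        if comps[k, idx] < 0:
            comps[k] = -comps[k]
    return DPCAModel(mean=mean, components=comps,
                     explained_variance=variances, feature_columns=cols)


def project(model: DPCAModel, ensemble: Ensemble, n_components: int = 2) -> np.ndarray:
    """Project an ensemble onto the leading components; (T, n_components)."""
    feats, cols = dihedral_features(compute_dihedrals(ensemble))
    if feats.shape[1] != len(model.mean):
        raise ValueError("ensemble topology does not match the fitted model")
    centered = feats - model.mean
    k = min(n_components, model.components.shape[0])
    return centered @ model.components[:k].T


def _find_minima(free_energy: np.ndarray, depth_threshold: float,
                 min_separation: int) -> list[tuple[int, int, float]]:
    nx, ny = free_energy.shape
    candidates = []
    for i in range(nx):
        for j in range(ny):
            g = free_energy[i, j]
            if not np.isfinite(g):
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny:
                        if free_energy[ii, jj] < g:
                            is_min = False
            if is_min and g <= depth_threshold:
                candidates.append((i, j, float(g)))
    candidates.sort(key=lambda c: c[2])
    accepted: list[tuple[int, int, float]] = []
    for i, j, g in candidates:
        if all(max(abs(i - a), abs(j - b)) >= min_separation for a, b, _ in accepted):
            accepted.append((i, j, g))
    return accepted


def energy_landscape(projections: np.ndarray, bins: int = 64,
                     temperature: float = 300.0, depth_threshold: float = 0.5,
                     min_separation: int = 2,
                     edges: tuple[np.ndarray, np.ndarray] | None = None) -> EnergyLandscape:
    """2D occupancy histogram turned into dG = -ln(P/P_max) in kT units.

    Minima are local minima of dG over 8-neighbourhoods with dG at most
    ``depth_threshold`` above the modal bin, separated by at least
    ``min_separation`` bins; each carries the index of the frame whose
    projection lies nearest its bin centre.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.ndim != 2 or projections.shape[1] < 2:
        raise ValueError("projections must be (T, >=2)")
    if projections.shape[0] < 1:
        raise ValueError("need at least one projection")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x, y = projections[:, 0], projections[:, 1]
    if edges is not None:
        counts, xe, ye = np.histogram2d(x, y, bins=edges)
    else:
        pad = 1e-9
        counts, xe, ye = np.histogram2d(
            x, y, bins=bins,
            range=[[x.min() - pad, x.max() + pad], [y.min() - pad, y.max() + pad]],
        )
    with np.errstate(divide="ignore"):
        free_energy = -np.log(counts / counts.max())
    minima_bins = _find_minima(free_energy, depth_threshold, min_separation)
    minima = []
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    for i, j, g in minima_bins:
        center = np.array([xc[i], yc[j]])
        rep = int(np.argmin(np.sum((projections[:, :2] - center) ** 2, axis=1)))
        minima.append((i, j, g, rep))
    return EnergyLandscape(counts=counts, free_energy=free_energy,
                           x_edges=xe, y_edges=ye, minima=minima,
                           temperature=temperature)


def pooled_landscape(ensembles: list[Ensemble], bins: int = 64,
                     temperature: float = 300.0, **kwargs) -> tuple[DPCAModel, EnergyLandscape]:
    """Concatenate ensembles, refit the dPCA model and recompute the landscape."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    pooled = ensembles[0]
    for e in ensembles[1:]:
        pooled = pooled.concat(e)
    model = fit_dpca(pooled)
    proj = project(model, pooled)
    return model, energy_landscape(proj, bins=bins, temperature=temperature, **kwargs)
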