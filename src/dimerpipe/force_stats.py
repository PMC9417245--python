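"""Statistics on rupture datasets: mixture fits, peak patterns, KS checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core_io import RuptureDataset

__all__ = [
    "GaussianFit",
    "ComparisonReport",
    "normalize_positions",
    "fit_gaussian_peaks",
    "peak_pattern",
    "ks_compare",
    "validation_report",
    "DEFAULT_CONTOUR_LENGTH",
]

#: default contour length: 41 residues x 0.4 nm per residue
RESIDUE_CONTOUR_NM = 0.4
DEFAULT_CONTOUR_LENGTH = 41 * RESIDUE_CONTOUR_NM


@dataclass
class GaussianFit:
    """Gaussian-mixture summary of a 1D sample (components sorted by mean)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float

    @property
    def n_components(self) -> int:
        return len(self.means)


@dataclass
class ComparisonReport:
    statistic: float
    p_value: float
    alpha: float
    n_a: int
    n_b: int
    variable: str
    similar: bool = field(init=False)

    def __post_init__(self) -> None:
        self.similar = self.p_value > self.alpha


def normalize_positions(dataset: RuptureDataset,
                        contour_length: float = DEFAULT_CONTOUR_LENGTH) -> RuptureDataset:
    """Divide rupture positions (nm) by a contour length.

    Values landing outside [0, 1] are clamped for storage but their count is
    recorded on the returned dataset as ``n_out_of_range``.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    if contour_length <= 0:
        raise ValueError("contour length must be positive")
    scaled = dataset.positions / contour_length
    out_of_range = int(np.sum((scaled < 0) | (scaled > 1)))
    result = RuptureDataset(
        forces=dataset.forces.copy(),
        positions=np.clip(scaled, 0.0, 1.0),
        label=dataset.label,
        normalized=True,
    )
    result.n_out_of_range = out_of_range  # type: ignore[attr-defined]
    return result


def fit_gaussian_peaks(sample: np.ndarray, max_components: int = 3,
                       seed: int = 0) -> GaussianFit:
    """EM mixture fit with the component count chosen by BIC (1..max)."""
    sample = np.asarray(sample, dtype=float).ravel()
    if len(sample) < 10:
        raise ValueError("need at least 10 observations")
    if np.isclose(sample.std(), 0):
        raise ValueError("degenerate sample with zero variance")
    x = sample.reshape(-1, 1)
    best = None
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gm)
    bic, gm = best
    order = np.argsort(gm.means_.ravel())
    return GaussianFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        log_likelihood=float(gm.score(x) * len(sample)),
        bic=float(bic),
    )


_REGION_NAMES = ("N-terminal", "central", "C-terminal")


def region_of(center: float) -> str:
    """Map a normalized position to N-terminal/central/C-terminal thirds."""
    if center < 1 / 3:
        return _REGION_NAMES[0]
    if center < 2 / 3:
        return _REGION_NAMES[1]
    return _REGION_NAMES[2]


def peak_pattern(dataset: RuptureDataset, max_components: int = 3,
                 seed: int = 0) -> list[tuple[float, str]]:
    """Mixture peak centres of the normalized interaction pattern.

    Returns (center, region) tuples sorted by center ascending.
    """
    if not dataset.normalized:
        raise ValueError("peak_pattern expects normalized positions")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    fit = fit_gaussian_peaks(dataset.positions, max_components=max_components, seed=seed)
    return [(float(m), region_of(m)) for m in fit.means]


def ks_compare(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
               variable: str = "force") -> ComparisonReport:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    ``similar`` means the test fails to reject at ``alpha`` (p > alpha).
    Exact p-values for small samples, asymptotic otherwise (scipy 'auto').
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 observations per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return ComparisonReport(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        n_a=len(a),
        n_b=len(b),
        variable=variable,
    )


def validation_report(candidates: list[RuptureDataset], reference: RuptureDataset,
                      alpha: float = 0.05, decision: str = "bonferroni",
                      max_components: int = 3, seed: int = 0) -> list[dict]:
    """Rank candidate rupture datasets against a reference.

    Per candidate, forces and positions are each compared with a two-sample
    KS test.  The "statistically similar" flag is a conjunction over both
    variables; with ``decision="bonferroni"`` each test uses alpha/2 (so the
    family-wise dissimilarity call is controlled at alpha), with
    ``decision="per-test"`` each uses alpha directly.  Candidates are ranked
    by Fisher-combined p-value, descending.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if decision not in ("bonferroni", "per-test"):
        raise ValueError("decision must be 'bonferroni' or 'per-test'")
    per_test_alpha = alpha / 2 if decision == "bonferroni" else alpha
    rows = []
    for cand in candidates:
        force_cmp = ks_compare(cand.forces, reference.forces, per_test_alpha, "force")
        pos_cmp = ks_compare(cand.positions, reference.positions, per_test_alpha, "position")
        with np.errstate(divide="ignore"):
            fisher = -2 * (np.log(max(force_cmp.p_value, 1e-300))
                           + np.log(max(pos_cmp.p_value, 1e-300)))
        combined_p = float(stats.chi2.sf(fisher, df=4))
        rows.append({
            "label": cand.label,
            "n": len(cand),
            "force_ks": force_cmp,
            "position_ks": pos_cmp,
            "force_fit": fit_gaussian_peaks(cand.forces, max_components, seed=seed),
            "position_fit": fit_gaussian_peaks(cand.positions, max_components, seed=seed),
            "combined_p": combined_p,
            "similar": force_cmp.similar and pos_cmp.similar,
        })
    rows.sort(key=lambda r: -r["combined_p"])
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
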