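"""K redundancy index and image-histogram summaries of error correlation.

The K index condenses a p x p correlation matrix into one number in [0, 1]
measuring how far its eigenvalue spectrum departs from the uncorrelated
ideal.  With EV_m = lambda_m / sum(lambda) the explained variance of the
m-th principal component,

    K = sum_m |EV_m - 1/p|  /  (2 (p - 1) / p)

K = 0 when all variables are uncorrelated (all EV_m = 1/p) and K = 1 under
perfect correlation (a single nonzero eigenvalue).  When the underlying
error matrix has rank r < p — fewer effective replicates than channels —
the correlation matrix has at most r nonzero eigenvalues and K cannot fall
below the *imbedded correlation*

    K_min(p, r) = (p - r) / (p - 1),

attained when the r nonzero explained variances are equal.  The distance
K - K_min, rather than K itself, therefore measures the error correlation
actually attributable to the experiment; preprocessing that drives K close
to the imbedded value has removed essentially all correctable structure.

The correlation surface is also summarized as a gray-scale image via
g = (rho + 1)/2 (so rho = -1, 0, 1 map to gray 0, 0.5, 1); an unstructured
error yields a symmetric histogram centered on 0.5, plus the unit-diagonal
spike at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .exceptions import DomainError, FormatError

__all__ = [
    "KIndexResult",
    "HistogramSummary",
    "k_index",
    "k_from_eigenvalues",
    "imbedded_k",
    "image_histogram",
]


@dataclass(frozen=True)
class KIndexResult:
    eigenvalues: np.ndarray  # descending, negatives clipped at 0
    explained_variance: np.ndarray  # sums to 1
    k: float
    p: int
    k_min: float | None = None  # imbedded minimum for the stated rank
    rank: int | None = None

    @property
    def distance_to_imbedded(self) -> float | None:
        """K - K_min: the correlation attributable to the experiment."""
        return None if self.k_min is None else self.k - self.k_min


@dataclass(frozen=True)
class HistogramSummary:
    bin_edges: np.ndarray  # covers [0, 1] exactly
    counts: np.ndarray  # sums to the pixel count
    total_pixels: int
    mode_gray: float  # center of the fullest bin
    skewness: float
    tail_mass: dict[float, float]  # threshold -> fraction beyond it


def k_from_eigenvalues(eigenvalues: np.ndarray) -> float:
    """K index from a correlation-matrix eigenvalue spectrum.

    Negative numerical eigenvalues are clipped at zero before normalizing
    to explained variances (a correlation matrix from rank-deficient data
    is PSD in exact arithmetic; small negatives are round-off).
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    p = lam.size
    if p < 2:
        raise DomainError("K index needs at least 2 variables")
    total = lam.sum()
    if total <= 0:
        raise DomainError("eigenvalue spectrum sums to zero")
    ev = lam / total
    return float(np.abs(ev - 1.0 / p).sum() / (2.0 * (p - 1) / p))


def k_index(corr: np.ndarray, rank: int | None = None,
            sym_tol: float = 1e-8) -> KIndexResult:
    """K index of a correlation matrix (eigendecomposition route).

    ``corr`` must be square and symmetric with unit diagonal on included
    channels; rows/columns that are entirely NaN (channels excluded
    upstream for vanishing variance) are dropped before the
    eigendecomposition.  If ``rank`` is given, the imbedded minimum
    K_min(p, rank) is attached for comparison.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise FormatError(f"correlation matrix must be square, got {c.shape}")
    keep = ~np.all(np.isnan(c), axis=0)
    c = c[np.ix_(keep, keep)]
    if np.isnan(c).any():
        raise FormatError("correlation matrix has NaNs outside excluded channels")
    if np.abs(c - c.T).max() > sym_tol:
        raise FormatError("correlation matrix is not symmetric")
    p = c.shape[0]
    lam = np.sort(np.linalg.eigvalsh(0.5 * (c + c.T)))[::-1]
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise FormatError("matrix is strongly indefinite; not a correlation matrix")
    lam = np.clip(lam, 0.0, None)
    ev = lam / lam.sum()
    k = k_from_eigenvalues(lam)
    k_min = imbedded_k(p, rank) if rank is not None else None
    return KIndexResult(eigenvalues=lam, explained_variance=ev, k=k, p=p,
                        k_min=k_min, rank=rank)


def imbedded_k(p: int, r: int) -> float:
    """Minimum attainable K for a p-variable correlation matrix of rank r.

    Closed form (p - r)/(p - 1), cross-checked against the direct K
    evaluation on the minimally-correlated eigenvalue spectrum (r equal
    nonzero eigenvalues p/r, the remainder zero); the two routes must
    agree to 1e-12.
    """
    if not (1 <= r <= p):
        raise DomainError(f"rank r={r} must satisfy 1 <= r <= p={p}")
    if p < 2:
        raise DomainError("imbedded K needs p >= 2")
    closed = (p - r) / (p - 1)
    lam = np.zeros(p)
    lam[:r] = p / r
    direct = k_from_eigenvalues(lam)
    if abs(closed - direct) > 1e-12:  # pragma: no cover - internal consistency
        raise AssertionError(
            f"imbedded-K routes disagree: closed {closed} vs direct {direct}"
        )
    return closed


def image_histogram(
    corr: np.ndarray,
    n_bins: int = 256,
    include_diagonal: bool = True,
    tail_thresholds: tuple[float, ...] = (0.1, 0.9),
    range_tol: float = 1e-9,
) -> HistogramSummary:
    """Gray-level histogram of the correlation surface viewed as an image.

    Each entry rho maps to gray g = (rho + 1)/2; the histogram uses
    ``n_bins`` equal-width bins covering [0, 1] with a right-inclusive last
    bin, so counts always sum to the pixel count.  The unit diagonal is
    included by default (it is part of the image); pass
    ``include_diagonal=False`` to histogram off-diagonal structure only.
    NaN entries (excluded channels) are dropped from the pixel count.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise FormatError(f"correlation matrix must be square, got {c.shape}")
    if not include_diagonal:
        c = c.copy()
        np.fill_diagonal(c, np.nan)
    vals = c[~np.isnan(c)]
    if vals.size and (vals.min() < -1.0 - range_tol or vals.max() > 1.0 + range_tol):
        raise DomainError(
            f"correlation entries outside [-1, 1]: range "
            f"[{vals.min():.6g}, {vals.max():.6g}]"
        )
    gray = np.clip((vals + 1.0) / 2.0, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(gray, bins=edges)
    mode_bin = int(np.argmax(counts))
    mode_gray = float(0.5 * (edges[mode_bin] + edges[mode_bin + 1]))
    if gray.size > 2 and np.ptp(gray) > 1e-15:
        skew = float(sstats.skew(gray))
    else:
        skew = 0.0  # degenerate (constant) image
    tails = {
        float(t): float(((gray > t).mean() if t >= 0.5 else (gray < t).mean()))
        for t in tail_thresholds
    }
    return HistogramSummary(
        bin_edges=edges, counts=counts, total_pixels=int(gray.size),
        mode_gray=mode_gray, skewness=skew, tail_mass=tails,
    )
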