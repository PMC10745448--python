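"""Replicate-based multivariate measurement-error estimation.

The error matrix E is obtained by subtracting from each spectrum the mean
of its replicate group (by default the sample x session x background-timing
cell); the pooled error covariance is

    Sigma_cov = E' E / (n - g)

where g is the number of groups — the classical pooled (within-group)
covariance with n - g degrees of freedom.  Pooling across sessions keeps
the between-session offsets out of the error estimate while accumulating
enough replicates for a usable estimate.  The correlation surface
Sigma_cor is derived from Sigma_cov; channels with vanishing variance
(which arise, e.g., after derivative edge truncation) are excluded and
listed rather than propagated as NaNs.

Because preprocessing and replicate-mean subtraction do not commute, error
surfaces for a preprocessing variant must be computed by re-running the
pipeline on the spectra, not by transforming a raw error matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateSpectrumError,
    InsufficientReplicatesError,
    SelectionError,
)
from .spectra import SpectraSet

__all__ = [
    "ErrorMatrix",
    "ErrorSurfaces",
    "DEFAULT_REPLICATE_GROUP",
    "error_matrix",
    "pooled_covariance",
    "correlation_matrix",
    "error_surfaces",
]

#: Default replicate-grouping cell: replicates share a sample, a session and
#: a background-timing condition.
DEFAULT_REPLICATE_GROUP: tuple[str, ...] = ("sample", "session", "background_timing")

#: Channels whose error variance falls below this fraction of the maximum
#: variance are excluded from the correlation surface.
VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class ErrorMatrix:
    """Replicate-mean-subtracted residual spectra with rank bookkeeping."""

    residuals: np.ndarray  # n x p
    group_factors: tuple[str, ...]
    group_sizes: dict[tuple[str, ...], int]
    dof: int  # pooled degrees of freedom, n - g
    rank_bound: int  # min(n - g, p): attainable rank of E
    wavelengths: np.ndarray

    @property
    def n(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


@dataclass(frozen=True)
class ErrorSurfaces:
    """Pooled error covariance and (optionally) correlation surfaces."""

    cov: np.ndarray  # p x p, squared reflectance units
    dof: int
    wavelengths: np.ndarray
    cor: np.ndarray | None = None  # p x p, NaN on excluded channels
    excluded_channels: tuple[int, ...] = ()

    @property
    def diagonal_profile(self) -> np.ndarray:
        """Per-channel error variance (the Sigma_cov diagonal)."""
        return np.diag(self.cov)


def error_matrix(s: SpectraSet, replicate_group=DEFAULT_REPLICATE_GROUP) -> ErrorMatrix:
    """Subtract from each spectrum the mean of its replicate group.

    Every group must contain at least two rows; a singleton cell is an
    error (one replicate carries no information about spread) and the
    offending cell is named.
    """
    replicate_group = tuple(replicate_group)
    df = s.design.table
    for f in replicate_group:
        if f not in df.columns:
            raise SelectionError(f"unknown factor {f!r}; have {list(df.columns)}")
    e = np.empty_like(s.x)
    sizes: dict[tuple[str, ...], int] = {}
    for key, idx in df.groupby(list(replicate_group), sort=True).indices.items():
        key = key if isinstance(key, tuple) else (key,)
        if len(idx) < 2:
            raise InsufficientReplicatesError(
                f"replicate cell {dict(zip(replicate_group, key))} has "
                f"{len(idx)} row(s); >= 2 required"
            )
        block = s.x[idx]
        e[idx] = block - block.mean(axis=0)
        sizes[key] = int(len(idx))
    # rank of E is at most n - g, but never exceeds the channel count
    # (relevant after derivative edge truncation shrinks p below n - g)
    return ErrorMatrix(
        residuals=e,
        group_factors=replicate_group,
        group_sizes=sizes,
        dof=s.n - len(sizes),
        rank_bound=min(s.n - len(sizes), s.p),
        wavelengths=s.grid.values,
    )


def pooled_covariance(e: ErrorMatrix) -> ErrorSurfaces:
    """Pooled error covariance Sigma_cov = E'E/(n - g) with dof n - g."""
    dof = e.dof
    if dof < 1:
        raise InsufficientReplicatesError(
            f"pooled covariance needs n - g >= 1, got n={e.n}, g={e.n_groups}"
        )
    cov = e.residuals.T @ e.residuals / dof
    cov = 0.5 * (cov + cov.T)
    return ErrorSurfaces(cov=cov, dof=dof, wavelengths=e.wavelengths)


def correlation_matrix(surfaces: ErrorSurfaces) -> ErrorSurfaces:
    """Derive Sigma_cor from Sigma_cov.

    Sigma_cor(i,j) = Sigma_cov(i,j)/sqrt(Sigma_cov(i,i) Sigma_cov(j,j)).
    Channels with variance below ``VARIANCE_TOL`` times the maximum
    variance are excluded (rows/columns set to NaN) and listed.
    """
    var = np.diag(surfaces.cov).copy()
    vmax = var.max() if var.size else 0.0
    if vmax <= 0:
        raise DegenerateSpectrumError("all channels have zero error variance")
    excluded = np.flatnonzero(var < VARIANCE_TOL * vmax)
    keep = var >= VARIANCE_TOL * vmax
    d = np.where(keep, np.sqrt(var), np.nan)
    cor = surfaces.cov / np.outer(d, d)
    cor[np.ix_(keep, keep)] = np.clip(cor[np.ix_(keep, keep)], -1.0, 1.0)
    np.fill_diagonal(cor, np.where(keep, 1.0, np.nan))
    return ErrorSurfaces(
        cov=surfaces.cov,
        dof=surfaces.dof,
        wavelengths=surfaces.wavelengths,
        cor=cor,
        excluded_channels=tuple(int(i) for i in excluded),
    )


def error_surfaces(s: SpectraSet, replicate_group=DEFAULT_REPLICATE_GROUP) -> ErrorSurfaces:
    """Convenience: error matrix -> pooled covariance -> correlation."""
    return correlation_matrix(pooled_covariance(error_matrix(s, replicate_group)))
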