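"""Data model and I/O for design-annotated replicate spectra.

The central container is :class:`SpectraSet`: a reflectance matrix
(acquisitions x wavelength channels) aligned row-for-row with a design table
of categorical experimental factors (sample, session, replicate order,
background timing, power supply, ...).  Everything downstream — preprocessing,
ASCA, error-covariance estimation — consumes and returns this container, so
row/design alignment is enforced here once.

On-disk format: a wide CSV whose header row holds the wavelength grid in nm,
paired with a design CSV whose header names the factors; rows are matched by
position.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import (
    AlignmentError,
    FormatError,
    InsufficientReplicatesError,
    RankError,
    SelectionError,
)

__all__ = [
    "WavelengthGrid",
    "DesignTable",
    "SpectraSet",
    "ReplicateStats",
    "read_spectra_csv",
    "write_spectra_csv",
    "subset",
    "replicate_stats",
    "flag_gross_outliers",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered channel centers in nm; strictly increasing, length >= 2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise FormatError(f"wavelength grid needs >= 2 channels, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("wavelength grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, idx):
        return self.values[idx]


@dataclass(frozen=True)
class DesignTable:
    """One row per acquisition; columns are categorical experimental factors.

    Levels are stored as strings; no missing values are allowed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.shape[1] < 1:
            raise FormatError("design table needs at least one factor column")
        if df.isna().any().any():
            raise FormatError("design table contains missing values")
        df = df.astype(str)
        df.index = pd.RangeIndex(len(df))
        object.__setattr__(self, "table", df)

    @property
    def factors(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n(self) -> int:
        return len(self.table)

    def levels(self, factor: str) -> list[str]:
        if factor not in self.table.columns:
            raise SelectionError(f"unknown factor {factor!r}; have {self.factors}")
        return sorted(self.table[factor].unique())

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class SpectraSet:
    """Reflectance matrix + wavelength grid + design table, aligned by row."""

    x: np.ndarray
    grid: WavelengthGrid
    design: DesignTable
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 2:
            raise FormatError(f"spectra matrix must be 2-D, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise FormatError("spectra matrix contains non-finite values")
        if x.shape[1] != len(self.grid):
            raise AlignmentError(
                f"matrix has {x.shape[1]} channels but grid has {len(self.grid)}"
            )
        if x.shape[0] != self.design.n:
            raise AlignmentError(
                f"matrix has {x.shape[0]} rows but design has {self.design.n}"
            )
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def with_matrix(self, x: np.ndarray, grid: WavelengthGrid | None = None,
                    step: str | None = None) -> "SpectraSet":
        """Return a copy with a new matrix (and optionally grid), recording
        the transformation *step* in provenance."""
        prov = self.provenance + ((step,) if step else ())
        return SpectraSet(x=x, grid=grid or self.grid, design=self.design,
                          provenance=prov)

    def take(self, rows: np.ndarray, step: str | None = None) -> "SpectraSet":
        rows = np.asarray(rows)
        df = self.design.table.iloc[rows].reset_index(drop=True)
        prov = self.provenance + ((step,) if step else ())
        return SpectraSet(x=self.x[rows], grid=self.grid,
                          design=DesignTable(df), provenance=prov)


@dataclass(frozen=True)
class ReplicateStats:
    """Per-channel descriptive statistics across replicates of one group.

    RSD = 100*sd/mean and S/N = mean/sd wherever both are defined; channels
    with zero mean or zero sd are flagged ``undefined`` instead of producing
    infinities.
    """

    group: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    rsd: np.ndarray
    snr: np.ndarray
    undefined: np.ndarray  # boolean mask, True where RSD / S/N are undefined
    n_replicates: int


def read_spectra_csv(spectra_path, design_path) -> SpectraSet:
    """Read a wide spectra CSV (header = wavelengths in nm) and a design CSV.

    Rows are matched by position; a row-count mismatch raises
    :class:`AlignmentError` naming both counts.
    """
    try:
        spec_df = pd.read_csv(spectra_path, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"cannot parse spectra CSV {spectra_path}: {exc}") from exc
    try:
        wavelengths = np.array([float(c) for c in spec_df.columns])
    except ValueError as exc:
        raise FormatError(
            f"spectra CSV header must be numeric wavelengths, got {list(spec_df.columns)[:5]}..."
        ) from exc
    grid = WavelengthGrid(wavelengths)

    matrix = np.empty(spec_df.shape, dtype=float)
    for j, col in enumerate(spec_df.columns):
        cells = spec_df[col].to_numpy()
        try:
            # numpy's strtod is correctly rounded, so written values
            # round-trip bit-identically
            matrix[:, j] = cells.astype(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(spec_df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna())[0])
            raise FormatError(
                f"non-numeric cell at data row {row}, column {col!r} of {spectra_path}"
            ) from None

    design_df = pd.read_csv(design_path, header=0, dtype=str)
    if len(design_df) != matrix.shape[0]:
        raise AlignmentError(
            f"design has {len(design_df)} rows but spectra matrix has "
            f"{matrix.shape[0]} rows"
        )
    return SpectraSet(x=matrix, grid=grid, design=DesignTable(design_df))


def write_spectra_csv(s: SpectraSet, spectra_path, design_path) -> None:
    """Write the CSV pair consumed by :func:`read_spectra_csv`.

    Uses repr-precision floats so a write-then-read round-trip is
    bit-identical.
    """
    cols = [repr(float(w)) for w in s.grid.values]
    pd.DataFrame(s.x, columns=cols).to_csv(spectra_path, index=False)
    s.design.table.to_csv(design_path, index=False)


def subset(s: SpectraSet, selector: Mapping[str, object]) -> SpectraSet:
    """Select the rows matching every ``factor -> level(s)`` clause.

    Levels may be a single value or a sequence; values are compared as
    strings, matching the design-table storage convention.  An empty result
    triggers a warning rather than an error.
    """
    mask = np.ones(s.n, dtype=bool)
    df = s.design.table
    for factor, levels in selector.items():
        if factor not in df.columns:
            raise SelectionError(f"unknown factor {factor!r}; have {list(df.columns)}")
        if isinstance(levels, (str, bytes)) or not isinstance(levels, Sequence):
            levels = [levels]
        levels = [str(v) for v in levels]
        known = set(df[factor].unique())
        unknown = [v for v in levels if v not in known]
        if unknown:
            raise SelectionError(
                f"factor {factor!r} has no level(s) {unknown}; have {sorted(known)}"
            )
        mask &= df[factor].isin(levels).to_numpy()
    if not mask.any():
        warnings.warn("subset selector matched no rows", stacklevel=2)
    return s.take(np.flatnonzero(mask))


def replicate_stats(
    s: SpectraSet, group_by: Sequence[str]
) -> dict[tuple[str, ...], ReplicateStats]:
    """Per-group, per-channel mean, sample sd, RSD (%) and S/N across replicates.

    Standard deviation uses the sample (n-1) denominator.  Channels where the
    sd or the mean vanishes are flagged undefined (RSD/S-N set to NaN there)
    rather than propagating infinities.
    """
    group_by = list(group_by)
    df = s.design.table
    for f in group_by:
        if f not in df.columns:
            raise SelectionError(f"unknown factor {f!r}; have {list(df.columns)}")
    out: dict[tuple[str, ...], ReplicateStats] = {}
    for key, idx in df.groupby(group_by, sort=True).indices.items():
        key = key if isinstance(key, tuple) else (key,)
        block = s.x[idx]
        if block.shape[0] < 2:
            raise InsufficientReplicatesError(
                f"group {key} has only {block.shape[0]} row(s); >= 2 required"
            )
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        # relative tolerance: identical replicates can leave O(eps) sd
        undefined = (sd <= 1e-12 * np.abs(mean)) | (mean == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rsd = np.where(undefined, np.nan, 100.0 * sd / mean)
            snr = np.where(undefined, np.nan, mean / sd)
        out[key] = ReplicateStats(
            group=key, mean=mean, sd=sd, rsd=rsd, snr=snr,
            undefined=undefined, n_replicates=int(block.shape[0]),
        )
    return out


def _q_limit_jackson_mudholkar(residual_eigs: np.ndarray, alpha: float) -> float:
    """Upper control limit for the Q (squared residual) statistic."""
    theta1 = residual_eigs.sum()
    theta2 = (residual_eigs**2).sum()
    theta3 = (residual_eigs**3).sum()
    if theta1 <= 0 or theta2 <= 0:
        return np.inf
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = sstats.norm.ppf(1.0 - alpha)
    term = (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if term <= 0:
        return np.inf
    return float(theta1 * term ** (1.0 / h0))


def flag_gross_outliers(
    s: SpectraSet,
    n_components: int | None = None,
    alpha: float = 0.01,
) -> np.ndarray:
    """PCA-based gross-error screening: Hotelling-T2 and Q-residual limits.

    A PCA model is fitted on the mean-centered matrix.  A row is flagged when
    it exceeds either the Hotelling-T2 limit (F-distribution) or the
    Q-residual limit (Jackson-Mudholkar approximation) at confidence
    ``1 - alpha``.  Flags are returned; rows are never dropped silently.

    When ``n_components`` is None, the smallest number of components
    explaining >= 90% of the variance is used.
    """
    x = s.x
    n, p = x.shape
    max_rank = min(n - 1, p)
    xc = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    eigs = sv**2 / (n - 1)  # PCA eigenvalues (sample covariance)

    if n_components is None:
        total = eigs.sum()
        if total == 0:
            return np.zeros(n, dtype=bool)
        cum = np.cumsum(eigs) / total
        n_components = int(np.searchsorted(cum, 0.90) + 1)
        n_components = min(n_components, max_rank - 1) or 1
    if n_components >= max_rank:
        raise RankError(
            f"n_components={n_components} must be < min(n-1, p)={max_rank}"
        )
    if n < n_components + 2:
        raise RankError(f"need n >= n_components + 2, got n={n}")

    k = n_components
    scores = u[:, :k] * sv[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(eigs[:k] > 0, scores**2 / eigs[:k], 0.0).sum(axis=1)
    t2_lim = (
        k * (n - 1) * (n + 1) / (n * (n - k))
        * sstats.f.ppf(1.0 - alpha, k, n - k)
    )

    recon = scores @ vt[:k]
    q = ((xc - recon) ** 2).sum(axis=1)
    q_lim = _q_limit_jackson_mudholkar(eigs[k:], alpha)

    return (t2 > t2_lim) | (q > q_lim)
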