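"""Row-wise and matrix-wise spectral preprocessing operators.

All operators take and return a :class:`~nirerr.spectra.SpectraSet`,
preserve the row/design alignment, and append a step tag to the set's
provenance so any downstream result can state exactly what was applied.

Available steps: mean centering (matrix-wise), standard normal variate
(SNV), multiplicative scatter correction (MSC) and the Savitzky-Golay
derivative filter.  The derivative truncates the half-window channels at
each spectrum edge, where the convolution is not supported, and shortens
the wavelength grid accordingly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import savgol_coeffs

from .exceptions import ConfigError, DegenerateSpectrumError, FormatError
from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "mean_center",
    "snv",
    "msc",
    "savgol_derivative",
    "apply_pipeline",
    "parse_step",
    "STANDARD_VARIANTS",
]


def mean_center(s: SpectraSet) -> SpectraSet:
    """Subtract the column (per-channel) mean spectrum."""
    return s.with_matrix(s.x - s.x.mean(axis=0), step="mean_center")


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: center each spectrum and scale it to unit
    sample standard deviation (n-1 denominator).

    Removes per-spectrum additive offsets and multiplicative scatter.
    Raises :class:`DegenerateSpectrumError` for constant rows.
    """
    mean = s.x.mean(axis=1, keepdims=True)
    sd = s.x.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DegenerateSpectrumError(
            f"constant spectrum at row(s) {flat.tolist()}: SNV undefined"
        )
    return s.with_matrix((s.x - mean) / sd, step="snv")


def msc(s: SpectraSet, reference: np.ndarray | str = "mean",
        b_tol: float = 1e-12) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x = a + b*ref (ordinary least squares);
    the corrected spectrum is (x - a)/b.  ``reference`` is either an
    explicit length-p spectrum or ``"mean"`` for the mean spectrum of the
    set.  A fitted |b| below ``b_tol`` aborts with the offending row.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ConfigError(f"unknown MSC reference {reference!r}")
        ref = s.x.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (s.p,):
            raise FormatError(f"reference has shape {ref.shape}, expected ({s.p},)")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference spectrum has zero variance")
    xc = s.x - s.x.mean(axis=1, keepdims=True)
    b = (xc @ ref_c) / denom
    small = np.flatnonzero(np.abs(b) < b_tol)
    if small.size:
        raise DegenerateSpectrumError(
            f"MSC slope below tolerance at row(s) {small.tolist()}"
        )
    a = s.x.mean(axis=1) - b * ref.mean()
    corrected = (s.x - a[:, None]) / b[:, None]
    return s.with_matrix(corrected, step="msc")


def savgol_derivative(
    s: SpectraSet,
    window: int = 7,
    polyorder: int = 2,
    derivorder: int = 1,
    per_nm: bool = False,
) -> SpectraSet:
    """Savitzky-Golay derivative filter applied per spectrum.

    The derivative scale is per channel-index step by default (the common
    chemometrics convention; downstream analyses interpret shapes, not
    units); ``per_nm=True`` divides by the mean channel spacing instead.
    The (window-1)/2 channels at each edge, where the local polynomial fit
    is unsupported, are removed from both the matrix and the grid.
    """
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ConfigError(f"polyorder {polyorder} must be < window {window}")
    if derivorder > polyorder:
        raise ConfigError(f"derivorder {derivorder} must be <= polyorder {polyorder}")
    if s.p < window:
        raise FormatError(f"spectra have {s.p} channels; window {window} too wide")
    delta = float(np.diff(s.grid.values).mean()) if per_nm else 1.0
    coeffs = savgol_coeffs(window, polyorder, deriv=derivorder, delta=delta)
    half = (window - 1) // 2
    # 'valid' convolution == truncation of the unsupported edge channels
    out = np.apply_along_axis(
        lambda row: np.convolve(row, coeffs, mode="valid"), 1, s.x
    )
    grid = WavelengthGrid(s.grid.values[half:-half])
    return s.with_matrix(
        out, grid=grid, step=f"savgol({window},{polyorder},{derivorder})"
    )


def parse_step(step) -> tuple[str, tuple]:
    """Normalize a pipeline step descriptor.

    Accepts ``"snv"``, ``"mean_center"``, ``"msc"``, ``("savgol", 7, 2, 1)``
    or the string form ``"savgol:7:2:1"``.
    """
    if isinstance(step, str):
        if step.startswith("savgol"):
            parts = step.split(":")
            args = tuple(int(v) for v in parts[1:]) if len(parts) > 1 else ()
            return "savgol", args
        return step, ()
    name, *args = step
    return str(name), tuple(args)


_STEP_FUNCS = {
    "mean_center": lambda s, *a: mean_center(s),
    "snv": lambda s, *a: snv(s),
    "msc": lambda s, *a: msc(s, *a) if a else msc(s),
    "savgol": lambda s, *a: savgol_derivative(s, *a),
}


def apply_pipeline(s: SpectraSet, steps: Sequence) -> SpectraSet:
    """Apply an ordered list of preprocessing steps; the applied sequence is
    recorded in the output's provenance."""
    out = s
    for step in steps:
        name, args = parse_step(step)
        if name not in _STEP_FUNCS:
            raise ConfigError(f"unknown preprocessing step {name!r}")
        out = _STEP_FUNCS[name](out, *args)
    return out


#: Named preprocessing variants used throughout error-structure comparisons:
#: raw data, scatter correction, and the first-derivative filter
#: (window 7, polynomial order 2).
STANDARD_VARIANTS: dict[str, list] = {
    "raw": [],
    "snv": ["snv"],
    "first_derivative": [("savgol", 7, 2, 1)],
}
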