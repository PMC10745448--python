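"""Synthetic full-factorial replicate spectra with structured measurement noise.

Emulates replicate acquisitions of solid pharmaceutical samples on
miniaturized NIR reflectance instruments.  Two presets mirror common
acquisition campaigns:

* :func:`avaspec_like` — 15 replicates x 4 samples x 3 sessions x 2
  background timings on a 236-channel grid over 972–1701 nm (360 spectra);
* :func:`neospectra_like` — the same crossed with 2 power-supply states on a
  74-channel grid over 1351–2559 nm (720 spectra).

Each simulated spectrum is

    x_i = m_i * [baseline(sample) + session_offset + drift + supply_offset]
          + a_i + eps_i

with log-normal multiplicative scatter ``m_i``, Gaussian additive offset
``a_i`` and noise ``eps_i`` drawn from a configurable channel-correlated,
heteroscedastic covariance (the generator's ground truth, exposed as
:func:`target_error_covariance` so estimator recovery can be tested).

Randomness is streamed from a single root seed through per-row substreams,
so the same seed always yields the same spectra and subsetting does not
reshuffle draws.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spectra import DesignTable, SpectraSet, WavelengthGrid

__all__ = [
    "SimConfig",
    "avaspec_like",
    "neospectra_like",
    "build_design",
    "variance_profile",
    "target_error_covariance",
    "simulate_spectra",
    "simulate",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the factorial design and of the noise model.

    Effect magnitudes are in reflectance units (baselines are O(0.2–0.6));
    ``scatter_log_sd`` is the sd of log m_i; ``noise_rho`` is the lag-1
    channel correlation of the banded noise component; ``smooth_weight``
    mixes in a smooth (long-range) correlated drift component.
    """

    # spectral axis
    n_channels: int = 236
    wavelength_range: tuple[float, float] = (972.0, 1701.0)
    # factor levels
    n_samples: int = 4
    n_sessions: int = 3
    n_replicates: int = 15
    background_timings: tuple[str, ...] = ("per-sample", "session-start")
    power_supply: tuple[str, ...] = ()  # e.g. ("mains", "battery"); empty = factor absent
    # deterministic effect magnitudes (reflectance units)
    session_offset_scale: float = 0.010
    background_drift_slope: float = 0.0015  # per replicate step, session-start level only
    power_offset_scale: float = 0.008
    # per-spectrum scatter (dominant error source for compact solid samples)
    scatter_log_sd: float = 0.08
    additive_offset_sd: float = 0.002
    # noise covariance: D^(1/2) R D^(1/2), R = w*R_smooth + (1-w)*R_band
    noise_base_sd: float = 0.004
    noise_hetero_amp: float = 1.0  # relative bump height of the sd profile
    noise_rho: float = 0.95
    smooth_weight: float = 0.3
    smooth_length_nm: float = 100.0
    seed: int = 0
    label: str = "generic"

    def __post_init__(self) -> None:
        for name in (
            "session_offset_scale", "background_drift_slope", "power_offset_scale",
            "scatter_log_sd", "additive_offset_sd", "noise_base_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.noise_rho < 1.0):
            raise ConfigError("noise_rho must lie in [0, 1)")
        if not (0.0 <= self.smooth_weight <= 1.0):
            raise ConfigError("smooth_weight must lie in [0, 1]")
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        for name in ("n_samples", "n_sessions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if len(self.background_timings) < 1:
            raise ConfigError("at least one background timing level is required")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_channels)

    @property
    def factor_levels(self) -> dict[str, list[str]]:
        levels = {
            "sample": [f"S{i + 1}" for i in range(self.n_samples)],
            "session": [str(i + 1) for i in range(self.n_sessions)],
            "background_timing": list(self.background_timings),
        }
        if self.power_supply:
            levels["power_supply"] = list(self.power_supply)
        levels["replicate_order"] = [str(i + 1) for i in range(self.n_replicates)]
        return levels


def avaspec_like(**overrides) -> SimConfig:
    """Benchtop-miniature configuration: 236 channels over 972–1701 nm,
    15 x 4 x 3 x 2 factorial (360 spectra)."""
    cfg = SimConfig(label="avaspec-like")
    return replace(cfg, **overrides) if overrides else cfg


def neospectra_like(**overrides) -> SimConfig:
    """Handheld configuration: 74 channels over 1351–2559 nm, the same
    factorial crossed with 2 power-supply states (720 spectra)."""
    cfg = SimConfig(
        n_channels=74,
        wavelength_range=(1351.0, 2559.0),
        power_supply=("mains", "battery"),
        label="neospectra-like",
    )
    return replace(cfg, **overrides) if overrides else cfg


def build_design(cfg: SimConfig) -> DesignTable:
    """Full crossing of the configured factor levels.

    ``replicate_order`` is the innermost (fastest-varying) index, matching
    acquisition order within a session cell.
    """
    levels = cfg.factor_levels
    names = list(levels)
    rows = list(itertools.product(*(levels[f] for f in names)))
    df = pd.DataFrame(rows, columns=names)
    return DesignTable(df)


def variance_profile(cfg: SimConfig) -> np.ndarray:
    """Per-channel noise variance: a baseline floor with a smooth
    heteroscedastic bump in the middle third of the range (stronger noise
    around strong absorbers is typical of NIR reflectance)."""
    w = cfg.wavelengths
    lo, hi = cfg.wavelength_range
    center = lo + 0.55 * (hi - lo)
    width = 0.12 * (hi - lo)
    bump = np.exp(-0.5 * ((w - center) / width) ** 2)
    sd = cfg.noise_base_sd * (1.0 + cfg.noise_hetero_amp * bump)
    return sd**2


def target_error_covariance(cfg: SimConfig) -> np.ndarray:
    """Ground-truth noise covariance Sigma = D^(1/2) R D^(1/2).

    R mixes a banded AR(1)-type correlation (rho^|i-j|) with a unit-diagonal
    smooth squared-exponential kernel; D is the variance profile.  The result
    is symmetrized and, if numerically indefinite, repaired by clipping
    negative eigenvalues at zero (with a warning).
    """
    p = cfg.n_channels
    w = cfg.wavelengths
    idx = np.arange(p)
    r_band = cfg.noise_rho ** np.abs(idx[:, None] - idx[None, :])
    dl = w[:, None] - w[None, :]
    r_smooth = np.exp(-0.5 * (dl / cfg.smooth_length_nm) ** 2)
    r = cfg.smooth_weight * r_smooth + (1.0 - cfg.smooth_weight) * r_band
    d_half = np.sqrt(variance_profile(cfg))
    sigma = d_half[:, None] * r * d_half[None, :]
    sigma = 0.5 * (sigma + sigma.T)
    eigs = np.linalg.eigvalsh(sigma)
    if eigs.min() < -1e-10 * max(eigs.max(), 1e-300):
        warnings.warn("target covariance numerically indefinite; clipping eigenvalues")
        vals, vecs = np.linalg.eigh(sigma)
        sigma = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        sigma = 0.5 * (sigma + sigma.T)
    return sigma


def _sample_baselines(cfg: SimConfig) -> np.ndarray:
    """Deterministic per-sample baseline spectra: sums of Gaussian bands.

    The first two synthetic samples are darker (low reflectance, as for
    colored curved pills), the last two brighter (white compact tablets);
    further samples cycle with shifted bands.
    """
    w = cfg.wavelengths
    lo, hi = cfg.wavelength_range
    span = hi - lo
    base_levels = [0.18, 0.26, 0.52, 0.60]
    band_sets = [
        [(0.25, 0.08, 0.06), (0.60, 0.10, 0.10)],
        [(0.30, 0.09, 0.08), (0.65, 0.09, 0.09)],
        [(0.35, 0.10, 0.12), (0.75, 0.08, 0.08)],
        [(0.40, 0.10, 0.10), (0.80, 0.09, 0.10)],
    ]
    out = np.empty((cfg.n_samples, cfg.n_channels))
    for i in range(cfg.n_samples):
        level = base_levels[i % 4] * (1.0 + 0.05 * (i // 4))
        spec = np.full(cfg.n_channels, level)
        for frac, wid_frac, amp in band_sets[i % 4]:
            center = lo + (frac + 0.02 * (i // 4)) * span
            spec += amp * np.exp(-0.5 * ((w - center) / (wid_frac * span)) ** 2)
        out[i] = spec
    return out


def _smooth_curve(rng: np.random.Generator, w: np.ndarray, scale: float) -> np.ndarray:
    """Random smooth spectral curve of rms amplitude ~scale (low-order
    sinusoids with random phases)."""
    if scale == 0:
        return np.zeros_like(w)
    t = (w - w[0]) / (w[-1] - w[0])
    curve = np.zeros_like(t)
    for k in range(1, 4):
        amp = rng.normal() / k
        phase = rng.uniform(0, 2 * np.pi)
        curve += amp * np.sin(np.pi * k * t + phase)
    rms = np.sqrt((curve**2).mean())
    if rms == 0:
        return np.zeros_like(t)
    return scale * curve / rms


def simulate_spectra(design: DesignTable, cfg: SimConfig) -> SpectraSet:
    """Draw one spectrum per design row under the configured effect and
    noise model.  Deterministic under a fixed ``cfg.seed``."""
    levels = cfg.factor_levels
    df = design.table
    for factor, lv in levels.items():
        if factor not in df.columns:
            raise ConfigError(f"design lacks factor {factor!r} required by config")
        extra = set(df[factor].unique()) - set(lv)
        if extra:
            raise ConfigError(f"design factor {factor!r} has unconfigured levels {extra}")

    w = cfg.wavelengths
    n, p = len(df), cfg.n_channels
    baselines = _sample_baselines(cfg)
    sample_index = {s: i for i, s in enumerate(levels["sample"])}

    root = np.random.SeedSequence(cfg.seed)
    effects_ss, rows_ss = root.spawn(2)
    eff_rng = np.random.default_rng(effects_ss)

    # structural (session / power) offsets: smooth curves fixed by the seed
    session_curves = {
        s: _smooth_curve(eff_rng, w, cfg.session_offset_scale)
        for s in levels["session"]
    }
    power_curves = {}
    if cfg.power_supply:
        # mains-connected acquisition is the reference condition
        power_curves[levels["power_supply"][0]] = np.zeros(p)
        for s in levels["power_supply"][1:]:
            power_curves[s] = _smooth_curve(eff_rng, w, cfg.power_offset_scale)

    sigma = target_error_covariance(cfg)
    vals, vecs = np.linalg.eigh(sigma)
    l_factor = vecs * np.sqrt(np.clip(vals, 0.0, None))  # sigma = L @ L.T

    row_children = rows_ss.spawn(n)
    x = np.empty((n, p))
    rep_col = df["replicate_order"].to_numpy()
    for i in range(n):
        row = df.iloc[i]
        clean = baselines[sample_index[row["sample"]]].copy()
        clean += session_curves[row["session"]]
        if row["background_timing"] == "session-start":
            # backgrounds grow stale over the session: linear drift in order
            clean += cfg.background_drift_slope * (int(rep_col[i]) - 1)
        if cfg.power_supply:
            clean += power_curves[row["power_supply"]]
        rng = np.random.default_rng(row_children[i])
        m = np.exp(rng.normal(0.0, cfg.scatter_log_sd)) if cfg.scatter_log_sd else 1.0
        a = rng.normal(0.0, cfg.additive_offset_sd) if cfg.additive_offset_sd else 0.0
        eps = l_factor @ rng.standard_normal(p)
        x[i] = m * clean + a + eps

    return SpectraSet(
        x=x, grid=WavelengthGrid(w), design=design,
        provenance=(f"simulated:{cfg.label}:seed={cfg.seed}",),
    )


def simulate(cfg: SimConfig) -> SpectraSet:
    """Convenience: build the full-factorial design and simulate it."""
    return simulate_spectra(build_design(cfg), cfg)
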