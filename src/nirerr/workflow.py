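"""End-to-end error-analysis workflow.

One configuration drives the full chain: load (or simulate) replicate
spectra -> screen gross outliers -> apply each preprocessing variant ->
ASCA factor screening with permutation significance -> replicate-based
error surfaces -> K index with imbedded comparison -> image histogram.
Every numeric table is written as CSV and a JSON manifest records the
configuration, seed, software version and a config hash so any table can
be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asca import decompose, permutation_test
from .error_model import DEFAULT_REPLICATE_GROUP, error_matrix, error_surfaces
from .exceptions import ConfigError, NirErrError
from .kindex import image_histogram, k_index
from .preprocess import STANDARD_VARIANTS, apply_pipeline
from .simulate import SimConfig, simulate
from .spectra import SpectraSet, flag_gross_outliers, read_spectra_csv, subset

__all__ = ["WorkflowConfig", "run_workflow", "load_workflow_config"]


@dataclass(frozen=True)
class WorkflowConfig:
    """Configuration of one workflow run.

    Exactly one input source must be set: a spectra/design CSV pair or a
    simulation config.  ``variants`` maps a variant name to a preprocessing
    pipeline (see :mod:`nirerr.preprocess`); ``n_perm=0`` skips the
    permutation tests.
    """

    output_dir: str | Path = "nirerr_out"
    spectra_csv: str | None = None
    design_csv: str | None = None
    sim: SimConfig | None = None
    variants: dict = field(default_factory=lambda: dict(STANDARD_VARIANTS))
    asca_factors: tuple[str, ...] = ("session", "background_timing", "replicate_order")
    asca_interactions: tuple[tuple[str, str], ...] = (
        ("session", "background_timing"),
    )
    error_group: tuple[str, ...] = DEFAULT_REPLICATE_GROUP
    n_perm: int = 2000
    seed: int = 0
    alpha: float = 0.05
    screen_outliers: bool = True
    drop_outliers: bool = False
    outlier_alpha: float = 0.01

    def __post_init__(self) -> None:
        has_csv = self.spectra_csv is not None and self.design_csv is not None
        if has_csv == (self.sim is not None):
            raise ConfigError(
                "configure exactly one input: a spectra/design CSV pair or a simulation"
            )
        if not self.variants:
            raise ConfigError("at least one preprocessing variant is required")


def _load_input(cfg: WorkflowConfig) -> SpectraSet:
    if cfg.sim is not None:
        return simulate(dataclasses.replace(cfg.sim, seed=cfg.seed))
    return read_spectra_csv(cfg.spectra_csv, cfg.design_csv)


def _config_digest(cfg: WorkflowConfig) -> tuple[dict, str]:
    d = dataclasses.asdict(cfg)
    d["output_dir"] = str(d["output_dir"])
    d["variants"] = {k: [list(s) if not isinstance(s, str) else s for s in v]
                     for k, v in cfg.variants.items()}
    blob = json.dumps(d, sort_keys=True, default=str)
    return d, hashlib.sha256(blob.encode()).hexdigest()


def run_workflow(cfg: WorkflowConfig) -> dict:
    """Run the full workflow; returns the manifest (also written to disk).

    Per (sample x preprocessing variant) the outputs are: the ASCA
    percentage/significance table, Sigma_cov and Sigma_cor as square CSVs
    with wavelength labels, the variance diagonal profile, a K-index row
    with the imbedded comparison, and the image-histogram CSV.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_input(cfg)

    samples = data.design.levels("sample") if "sample" in data.design.factors else [None]

    outlier_info: dict[str, list[int]] = {}
    if cfg.screen_outliers:
        for sample in samples:
            sub = subset(data, {"sample": sample}) if sample else data
            flags = flag_gross_outliers(sub, alpha=cfg.outlier_alpha)
            outlier_info[str(sample)] = np.flatnonzero(flags).tolist()
        if cfg.drop_outliers:
            keep = np.ones(data.n, dtype=bool)
            for sample in samples:
                rows = (data.design.table["sample"] == sample) if sample else slice(None)
                idx = np.flatnonzero(rows) if sample else np.arange(data.n)
                keep[idx[outlier_info[str(sample)]]] = False
            data = data.take(np.flatnonzero(keep), step="outliers_dropped")

    asca_rows, k_rows, files = [], [], []
    rng = np.random.default_rng(cfg.seed)
    for variant, steps in cfg.variants.items():
        for sample in samples:
            tag = f"{sample or 'all'}_{variant}"
            try:
                sub = subset(data, {"sample": sample}) if sample else data
                pre = apply_pipeline(sub, steps)

                decomp = decompose(pre, cfg.asca_factors, cfg.asca_interactions)
                for effect, pct in decomp.percentages.items():
                    row = {"sample": sample, "variant": variant,
                           "effect": effect, "percent_ss": pct}
                    if effect != "residual" and cfg.n_perm > 0:
                        res = permutation_test(pre, decomp, effect,
                                               n_perm=cfg.n_perm, seed=rng)
                        row["p_value"] = res.p_value
                        row["significant"] = res.p_value < cfg.alpha
                    asca_rows.append(row)

                em = error_matrix(pre, cfg.error_group)
                surf = error_surfaces(pre, cfg.error_group)
                wl = [f"{w:.4g}" for w in surf.wavelengths]
                cov_path = outdir / f"{tag}_sigma_cov.csv"
                pd.DataFrame(surf.cov, index=wl, columns=wl).to_csv(cov_path)
                cor_path = outdir / f"{tag}_sigma_cor.csv"
                pd.DataFrame(surf.cor, index=wl, columns=wl).to_csv(cor_path)
                diag_path = outdir / f"{tag}_variance_diagonal.csv"
                pd.DataFrame({"wavelength_nm": surf.wavelengths,
                              "error_variance": surf.diagonal_profile}
                             ).to_csv(diag_path, index=False)
                files += [cov_path.name, cor_path.name, diag_path.name]

                kres = k_index(surf.cor, rank=em.rank_bound)
                k_rows.append({
                    "sample": sample, "variant": variant, "k": kres.k,
                    "k_imbedded": kres.k_min,
                    "distance": kres.distance_to_imbedded,
                    "p_variables": kres.p, "rank": em.rank_bound,
                })

                hist = image_histogram(surf.cor)
                hist_path = outdir / f"{tag}_histogram.csv"
                pd.DataFrame({
                    "bin_left": hist.bin_edges[:-1],
                    "bin_right": hist.bin_edges[1:],
                    "count": hist.counts,
                }).to_csv(hist_path, index=False)
                files.append(hist_path.name)
            except NirErrError as exc:
                raise type(exc)(
                    f"workflow stage failed for sample={sample} variant={variant}: {exc}"
                ) from exc

    asca_path = outdir / "asca_effects.csv"
    pd.DataFrame(asca_rows).to_csv(asca_path, index=False)
    k_path = outdir / "k_index.csv"
    pd.DataFrame(k_rows).to_csv(k_path, index=False)
    files += [asca_path.name, k_path.name]

    cfg_dict, digest = _config_digest(cfg)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": digest,
        "permutation_scheme": "free permutation of tested-effect labels over rows",
        "outliers_flagged": outlier_info,
        "outliers_dropped": cfg.drop_outliers,
        "outputs": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_workflow_config(path) -> WorkflowConfig:
    """Build a :class:`WorkflowConfig` from a TOML file.

    A ``[sim]`` table configures the synthetic generator (keys mirror
    :class:`~nirerr.simulate.SimConfig`); top-level keys mirror
    :class:`WorkflowConfig`.  Preprocessing variants are given as
    ``[variants]`` with step lists, e.g. ``snv = ["snv"]`` or
    ``deriv = ["savgol:7:2:1"]``.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = None
    if "sim" in raw:
        sim_raw = dict(raw.pop("sim"))
        for key in ("wavelength_range", "background_timings", "power_supply"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimConfig(**sim_raw)
    variants = raw.pop("variants", None)
    kwargs = {}
    for key in ("asca_factors", "error_group"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    if "asca_interactions" in raw:
        kwargs["asca_interactions"] = tuple(
            tuple(pair) for pair in raw.pop("asca_interactions")
        )
    kwargs.update(raw)
    if variants is not None:
        kwargs["variants"] = {k: list(v) for k, v in variants.items()}
    return WorkflowConfig(sim=sim, **kwargs)
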