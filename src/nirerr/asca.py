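"""ANOVA-simultaneous component analysis (ASCA).

The design-annotated spectra matrix is decomposed, after grand-mean
centering, into additive effect matrices — one per experimental factor and
per requested two-way interaction — plus a residual:

    X - 1 m'  =  sum_k  X_k  +  E

A main-effect matrix assigns to each row the mean spectrum of its factor
level; an interaction matrix assigns the cell mean minus both main effects.
Effect importance is the percentage of the total sum of squares carried by
each matrix.  Significance is assessed by permuting the tested factor's
level labels over rows and recomputing its sum of squares.  Each effect
matrix can be explored through a PCA sub-model whose scores are augmented
with the projected residuals for visualization.

For balanced designs the effect matrices are mutually orthogonal and the
sums of squares are exactly additive; mildly unbalanced designs (e.g. after
outlier removal) are handled with cell-mean estimators under a warning, and
additivity is then only approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    ConfoundingError,
    DegenerateFactorError,
    RankError,
    SelectionError,
)
from .spectra import SpectraSet

__all__ = [
    "AscaDecomposition",
    "AscaSubmodel",
    "PermutationResult",
    "decompose",
    "permutation_test",
    "submodel",
]


def _effect_name(effect) -> str:
    if isinstance(effect, str):
        return effect
    return "x".join(effect)


@dataclass(frozen=True)
class AscaDecomposition:
    """Grand mean, per-effect matrices, residual, and sum-of-squares table."""

    grand_mean: np.ndarray
    effects: dict[str, np.ndarray]  # effect name -> n x p matrix
    residual: np.ndarray
    ss: dict[str, float]
    ss_residual: float
    ss_total: float
    percentages: dict[str, float]  # includes "residual"
    factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    design: pd.DataFrame
    balanced: bool

    @property
    def effect_names(self) -> list[str]:
        return list(self.effects)


@dataclass(frozen=True)
class AscaSubmodel:
    """PCA sub-model of a single effect matrix.

    ``scores`` are the pure effect scores (level means projected on the
    loadings, collapsing to one point per level); ``augmented_scores`` add
    the projected residuals and are the default visualization, since pure
    effect scores carry no within-level spread.
    """

    effect: str
    loadings: np.ndarray  # p x c, orthonormal columns
    scores: np.ndarray  # n x c
    augmented_scores: np.ndarray  # n x c
    explained_variance: np.ndarray  # length c, fractions of the effect SS
    centroids: dict[str, np.ndarray]  # level (or cell) -> length-c centroid


@dataclass(frozen=True)
class PermutationResult:
    effect: str
    observed_ss: float
    n_permutations: int
    null_ss: np.ndarray
    p_value: float
    scheme: str = "free permutation of the tested effect's labels over rows"


def _level_codes(df: pd.DataFrame, factors) -> np.ndarray:
    """Integer cell codes for one factor or a factor tuple."""
    if isinstance(factors, str):
        return pd.factorize(df[factors])[0]
    code = pd.factorize(df[factors[0]])[0]
    for f in factors[1:]:
        nxt = pd.factorize(df[f])[0]
        code = _combine_codes(code, nxt)
    return code


def _combine_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Dense joint codes for two integer code arrays."""
    joint = a * (b.max() + 1) + b
    return np.unique(joint, return_inverse=True)[1]


def _group_mean_matrix(xc: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """n x p matrix assigning to each row its group's mean row of xc."""
    g = codes.max() + 1
    sums = np.zeros((g, xc.shape[1]))
    np.add.at(sums, codes, xc)
    counts = np.bincount(codes, minlength=g).astype(float)
    means = sums / counts[:, None]
    return means[codes]


def _check_balance(df: pd.DataFrame, factors: tuple[str, ...]) -> bool:
    counts = df.groupby(list(factors), sort=False).size()
    full = np.prod([df[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


def decompose(
    s: SpectraSet,
    factors,
    interactions=(),
) -> AscaDecomposition:
    """Decompose the spectra matrix into design-factor effect matrices.

    Parameters
    ----------
    factors : sequence of design column names (each with >= 2 levels).
    interactions : sequence of factor-name pairs; only two-way interactions
        are supported.
    """
    factors = tuple(factors)
    interactions = tuple(tuple(pair) for pair in interactions)
    df = s.design.table
    for f in factors:
        if f not in df.columns:
            raise SelectionError(f"unknown factor {f!r}; have {list(df.columns)}")
        if df[f].nunique() < 2:
            raise DegenerateFactorError(f"factor {f!r} has a single level")
    for pair in interactions:
        if len(pair) != 2 or any(f not in factors for f in pair):
            raise SelectionError(f"interaction {pair} must pair two model factors")

    codes = {f: _level_codes(df, f) for f in factors}
    for i, f in enumerate(factors):
        for g in factors[i + 1:]:
            both = codes[f] * (codes[g].max() + 1) + codes[g]
            if (np.unique(both).size == np.unique(codes[f]).size
                    == np.unique(codes[g]).size):
                raise ConfoundingError(f"factors {f!r} and {g!r} are confounded")

    balanced = _check_balance(df, factors)
    if not balanced:
        warnings.warn(
            "design is unbalanced across the model factors; cell-mean "
            "estimators are used and sum-of-squares additivity is approximate",
            stacklevel=2,
        )

    grand_mean = s.x.mean(axis=0)
    xc = s.x - grand_mean

    effects: dict[str, np.ndarray] = {}
    for f in factors:
        effects[f] = _group_mean_matrix(xc, codes[f])
    for pair in interactions:
        cell = _group_mean_matrix(xc, _level_codes(df, pair))
        effects[_effect_name(pair)] = cell - effects[pair[0]] - effects[pair[1]]

    residual = xc - sum(effects.values())
    ss = {name: float((m**2).sum()) for name, m in effects.items()}
    ss_residual = float((residual**2).sum())
    ss_total = float((xc**2).sum())
    denom = ss_total if ss_total > 0 else 1.0
    percentages = {name: 100.0 * v / denom for name, v in ss.items()}
    percentages["residual"] = 100.0 * ss_residual / denom

    return AscaDecomposition(
        grand_mean=grand_mean,
        effects=effects,
        residual=residual,
        ss=ss,
        ss_residual=ss_residual,
        ss_total=ss_total,
        percentages=percentages,
        factors=factors,
        interactions=interactions,
        design=df,
        balanced=balanced,
    )


def _main_ss(xc: np.ndarray, codes: np.ndarray) -> float:
    """SS of a main-effect matrix: sum over levels of n_l * ||level mean||^2."""
    g = codes.max() + 1
    sums = np.zeros((g, xc.shape[1]))
    np.add.at(sums, codes, xc)
    counts = np.bincount(codes, minlength=g).astype(float)
    means = sums / counts[:, None]
    return float((counts[:, None] * means**2).sum())


def _interaction_ss(xc: np.ndarray, cf: np.ndarray, cg: np.ndarray) -> float:
    """SS of an interaction matrix under the cell-mean scheme."""
    cell = _group_mean_matrix(xc, _combine_codes(cf, cg))
    main = _group_mean_matrix(xc, cf) + _group_mean_matrix(xc, cg)
    return float(((cell - main) ** 2).sum())


def permutation_test(
    s: SpectraSet,
    decomp: AscaDecomposition,
    effect: str,
    n_perm: int = 2000,
    seed: int | np.random.Generator | None = 0,
) -> PermutationResult:
    """Permutation significance test for one effect.

    The tested factor's level labels (for an interaction: the pair of label
    columns, jointly) are freely permuted over rows ``n_perm`` times; the
    effect's sum of squares is recomputed under the same cell-mean scheme
    each time.  p = (#{null >= observed} + 1)/(n_perm + 1), so p is never
    exactly zero.
    """
    if effect not in decomp.effects:
        raise SelectionError(
            f"effect {effect!r} not in decomposition; have {decomp.effect_names}"
        )
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = decomp.design
    xc = s.x - decomp.grand_mean
    observed = decomp.ss[effect]

    is_interaction = effect not in df.columns
    if is_interaction:
        f, g = effect.split("x")
        cf, cg = _level_codes(df, f), _level_codes(df, g)
    else:
        cmain = _level_codes(df, effect)
    null = np.empty(n_perm)
    n = len(df)
    for b in range(n_perm):
        perm = rng.permutation(n)
        if is_interaction:
            null[b] = _interaction_ss(xc, cf[perm], cg[perm])
        else:
            null[b] = _main_ss(xc, cmain[perm])
    p = (float((null >= observed).sum()) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        effect=effect, observed_ss=observed, n_permutations=n_perm,
        null_ss=null, p_value=p,
    )


def submodel(
    decomp: AscaDecomposition, effect: str, n_components: int = 2
) -> AscaSubmodel:
    """Simultaneous-component (PCA) sub-model of one effect matrix.

    Loadings come from the SVD of the effect matrix; the effect scores are
    its projection on the loadings, and the augmented scores add the
    projected residual matrix E, restoring within-level spread for
    visualization.  Level (or interaction-cell) centroids are means of the
    augmented scores.
    """
    if effect not in decomp.effects:
        raise SelectionError(
            f"effect {effect!r} not in decomposition; have {decomp.effect_names}"
        )
    m = decomp.effects[effect]
    u, sv, vt = np.linalg.svd(m, full_matrices=False)
    tol = max(m.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int((sv > tol).sum())
    if n_components > rank:
        raise RankError(
            f"n_components={n_components} exceeds effect-matrix rank {rank}"
        )
    loadings = vt[:n_components].T
    scores = m @ loadings
    augmented = (m + decomp.residual) @ loadings
    total = float((sv**2).sum())
    explained = (sv[:n_components] ** 2) / (total if total > 0 else 1.0)

    df = decomp.design
    cols = effect.split("x") if effect not in df.columns else [effect]
    labels = df[cols].agg(" x ".join, axis=1) if len(cols) > 1 else df[cols[0]]
    centroids = {
        str(level): augmented[np.flatnonzero(labels == level)].mean(axis=0)
        for level in sorted(labels.unique())
    }
    return AscaSubmodel(
        effect=effect, loadings=loadings, scores=scores,
        augmented_scores=augmented, explained_variance=explained,
        centroids=centroids,
    )
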