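"""ASCA decomposition, permutation significance and sub-models.

The independent oracle is a direct per-channel (elementwise) ANOVA
decomposition: for every channel, level means and cell means are computed
with explicit loops and assembled into effect matrices.
"""

import numpy as np
import pandas as pd
import pytest

import nirerr as ne
from nirerr.exceptions import (
    ConfoundingError,
    DegenerateFactorError,
    RankError,
    SelectionError,
)

from conftest import make_set


def _two_factor_design(n_rep=2):
    """Balanced 2 x 3 crossed design with n_rep replicates per cell."""
    rows = [(a, b) for a in "AB" for b in "123" for _ in range(n_rep)]
    return pd.DataFrame(rows, columns=["f", "g"])


def anova_oracle(x, df, factors, interaction=None):
    """Elementwise ANOVA decomposition by explicit loops (the oracle)."""
    xc = x - x.mean(axis=0)
    n, p = xc.shape
    effects = {}
    for f in factors:
        m = np.zeros_like(xc)
        for lv in df[f].unique():
            idx = np.flatnonzero(df[f] == lv)
            for j in range(p):
                m[idx, j] = xc[idx, j].mean()
        effects[f] = m
    if interaction:
        f, g = interaction
        m = np.zeros_like(xc)
        for lf in df[f].unique():
            for lg in df[g].unique():
                idx = np.flatnonzero((df[f] == lf) & (df[g] == lg))
                for j in range(p):
                    m[idx, j] = xc[idx, j].mean()
        effects[f + "x" + g] = m - effects[f] - effects[g]
    residual = xc - sum(effects.values())
    return effects, residual


class TestDecompose:
    def test_noiseless_two_level_factor_explains_everything(self):
        x = np.array([[1.0, 2.0]] * 3 + [[3.0, 5.0]] * 3)
        s = make_set(x, f=list("aaabbb"))
        dec = ne.decompose(s, ["f"])
        assert dec.ss_residual <= 1e-20
        assert dec.percentages["f"] == pytest.approx(100.0)

    def test_matches_elementwise_anova_oracle(self, rng):
        df = _two_factor_design()
        x = rng.standard_normal((len(df), 4))
        s = make_set(x, design=df)
        dec = ne.decompose(s, ["f", "g"], [("f", "g")])
        effects, residual = anova_oracle(x, df, ["f", "g"], ("f", "g"))
        for name, m in effects.items():
            assert np.allclose(dec.effects[name], m, atol=1e-12)
        assert np.allclose(dec.residual, residual, atol=1e-12)

    def test_ss_additivity_and_percentages(self, rng):
        df = _two_factor_design(n_rep=3)
        s = make_set(rng.standard_normal((len(df), 4)), design=df)
        dec = ne.decompose(s, ["f", "g"], [("f", "g")])
        total = sum(dec.ss.values()) + dec.ss_residual
        assert abs(total - dec.ss_total) <= 1e-8 * dec.ss_total
        assert sum(dec.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_effect_matrices_have_zero_column_means(self, rng):
        df = _two_factor_design()
        dec = ne.decompose(make_set(rng.standard_normal((len(df), 3)), design=df),
                           ["f", "g"])
        for m in dec.effects.values():
            assert np.abs(m.mean(axis=0)).max() <= 1e-12

    def test_main_effects_mutually_orthogonal(self, rng):
        df = _two_factor_design(n_rep=4)
        dec = ne.decompose(make_set(rng.standard_normal((len(df), 5)), design=df),
                           ["f", "g"])
        cross = np.trace(dec.effects["f"].T @ dec.effects["g"])
        scale = np.sqrt(dec.ss["f"] * dec.ss["g"])
        assert abs(cross) <= 1e-8 * max(scale, 1.0)

    def test_row_permutation_invariance_of_ss(self, rng):
        df = _two_factor_design()
        x = rng.standard_normal((len(df), 4))
        dec = ne.decompose(make_set(x, design=df), ["f", "g"])
        perm = rng.permutation(len(df))
        dec2 = ne.decompose(
            make_set(x[perm], design=df.iloc[perm].reset_index(drop=True)),
            ["f", "g"])
        for name in dec.ss:
            assert dec2.ss[name] == pytest.approx(dec.ss[name])

    def test_confounded_factors_rejected(self, rng):
        df = pd.DataFrame({"f": list("aabb"), "g": list("ccdd")})
        with pytest.raises(ConfoundingError):
            ne.decompose(make_set(rng.standard_normal((4, 3)), design=df),
                         ["f", "g"])

    def test_single_level_factor_rejected(self, rng):
        s = make_set(rng.standard_normal((4, 3)), f=list("aaaa"))
        with pytest.raises(DegenerateFactorError):
            ne.decompose(s, ["f"])

    def test_unbalanced_design_warns(self, rng):
        df = pd.DataFrame({"f": list("aaabb"), "g": list("12312")})
        with pytest.warns(UserWarning, match="unbalanced"):
            ne.decompose(make_set(rng.standard_normal((5, 3)), design=df),
                         ["f", "g"])


class TestPermutationTest:
    def test_huge_effect_reaches_minimal_p(self, rng):
        df = _two_factor_design(n_rep=3)
        x = 0.01 * rng.standard_normal((len(df), 4))
        x[df["f"] == "A"] += 5.0  # 50x the noise scale
        s = make_set(x, design=df)
        dec = ne.decompose(s, ["f", "g"])
        res = ne.permutation_test(s, dec, "f", n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_default_permutation_count(self, balanced_session_set):
        import inspect
        sig = inspect.signature(ne.permutation_test)
        assert sig.parameters["n_perm"].default == 2000

    def test_interaction_permutation_runs(self, rng):
        df = _two_factor_design(n_rep=3)
        s = make_set(rng.standard_normal((len(df), 4)), design=df)
        dec = ne.decompose(s, ["f", "g"], [("f", "g")])
        res = ne.permutation_test(s, dec, "fxg", n_perm=50, seed=1)
        assert 0.0 < res.p_value <= 1.0
        assert res.null_ss.shape == (50,)

    def test_unknown_effect_raises(self, rng):
        df = _two_factor_design()
        s = make_set(rng.standard_normal((len(df), 4)), design=df)
        dec = ne.decompose(s, ["f", "g"])
        with pytest.raises(SelectionError):
            ne.permutation_test(s, dec, "h")


class TestSubmodel:
    def test_two_level_geometry(self, rng):
        x = 0.5 + 0.01 * rng.standard_normal((8, 5))
        x[4:] += np.array([0.1, -0.2, 0.3, 0.0, 0.05])
        s = make_set(x, f=list("aaaabbbb"))
        dec = ne.decompose(s, ["f"])
        sub = ne.submodel(dec, "f", n_components=1)
        # loadings along the difference of level means
        diff = dec.effects["f"][4] - dec.effects["f"][0]
        cosine = abs(diff @ sub.loadings[:, 0]) / np.linalg.norm(diff)
        assert cosine == pytest.approx(1.0)
        vals = np.unique(np.round(sub.scores[:, 0], 10))
        assert len(vals) == 2 and vals[0] == pytest.approx(-vals[1])

    def test_augmented_minus_effect_scores_is_projected_residual(self, rng):
        df = _two_factor_design()
        s = make_set(rng.standard_normal((len(df), 4)), design=df)
        dec = ne.decompose(s, ["f", "g"])
        sub = ne.submodel(dec, "g", n_components=2)
        assert np.allclose(sub.augmented_scores - sub.scores,
                           dec.residual @ sub.loadings, atol=1e-12)

    def test_loadings_orthonormal_and_ev_monotone(self, rng):
        df = _two_factor_design(n_rep=4)
        s = make_set(rng.standard_normal((len(df), 6)), design=df)
        dec = ne.decompose(s, ["f", "g"])
        sub = ne.submodel(dec, "g", n_components=2)
        assert np.allclose(sub.loadings.T @ sub.loadings, np.eye(2), atol=1e-12)
        assert sub.explained_variance.sum() <= 1.0 + 1e-12
        assert sub.explained_variance[0] >= sub.explained_variance[1]

    def test_null_factor_centroids_near_zero(self, rng):
        # no injected effect: augmented-score centroids scatter around 0
        df = _two_factor_design(n_rep=20)
        s = make_set(0.5 + 0.05 * rng.standard_normal((len(df), 6)), design=df)
        dec = ne.decompose(s, ["f", "g"])
        sub = ne.submodel(dec, "g", n_components=1)
        spread = sub.augmented_scores[:, 0].std()
        for c in sub.centroids.values():
            assert abs(c[0]) <= spread  # within one sd of the score cloud

    def test_rank_error(self, rng):
        s = make_set(rng.standard_normal((6, 4)), f=list("aaabbb"))
        dec = ne.decompose(s, ["f"])
        with pytest.raises(RankError):
            ne.submodel(dec, "f", n_components=2)
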