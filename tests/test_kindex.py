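"""K redundancy index, imbedded correlation and image histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirerr as ne
from nirerr.exceptions import DomainError, FormatError


def brute_force_k(corr):
    """Direct-summation oracle: eigenvalues -> EVs -> sum of |EV - 1/p|."""
    lam = np.linalg.eigvalsh(corr)
    lam = np.where(lam < 0, 0.0, lam)
    p = corr.shape[0]
    ev = lam / lam.sum()
    acc = 0.0
    for v in ev:
        acc += abs(v - 1.0 / p)
    return acc / (2.0 * (p - 1) / p)


class TestKIndex:
    def test_identity_gives_zero(self):
        assert ne.k_index(np.eye(10)).k == 0.0

    def test_perfect_correlation_gives_one(self):
        assert ne.k_index(np.ones((10, 10))).k == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        e = rng.standard_normal((10, 20))  # more channels than rows
        corr = np.corrcoef(e, rowvar=False)
        res = ne.k_index(corr)
        assert res.k == pytest.approx(brute_force_k(corr), abs=1e-12)

    def test_invariant_under_simultaneous_permutation(self, rng):
        e = rng.standard_normal((15, 8))
        corr = np.corrcoef(e, rowvar=False)
        perm = rng.permutation(8)
        assert (ne.k_index(corr[np.ix_(perm, perm)]).k
                == pytest.approx(ne.k_index(corr).k, abs=1e-12))

    def test_explained_variance_sums_to_one(self, rng):
        corr = np.corrcoef(rng.standard_normal((12, 6)), rowvar=False)
        res = ne.k_index(corr)
        assert res.explained_variance.sum() == pytest.approx(1.0)
        assert res.eigenvalues.min() >= 0.0

    def test_shape_and_symmetry_errors(self):
        with pytest.raises(FormatError):
            ne.k_index(np.ones((3, 4)))
        bad = np.eye(4)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(FormatError):
            ne.k_index(bad)

    def test_rank_deficient_k_respects_imbedded_floor(self, rng):
        p = 20
        for _ in range(50):
            r = int(rng.integers(2, p))
            e = rng.standard_normal((r, p))
            e -= e.mean(axis=0)  # centering drops one dof
            corr = ne.correlation_matrix(
                ne.ErrorSurfaces(cov=e.T @ e / (r - 1), dof=r - 1,
                                 wavelengths=np.arange(float(p)))).cor
            k = ne.k_index(corr).k
            assert k >= ne.imbedded_k(p, r - 1) - 1e-10


class TestImbeddedK:
    def test_benchtop_configuration_value(self):
        # 236 channels, 45 pooled replicates minus 3 session means -> rank 42
        assert ne.imbedded_k(236, 42) == pytest.approx(0.826, abs=5e-4)

    def test_handheld_configuration_value(self):
        # 74 channels, 45 replicates
        assert ne.imbedded_k(74, 45) == pytest.approx(0.397, abs=5e-4)

    def test_limiting_ranks(self):
        assert ne.imbedded_k(10, 10) == 0.0
        assert ne.imbedded_k(10, 1) == 1.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ne.imbedded_k(10, 0)
        with pytest.raises(DomainError):
            ne.imbedded_k(10, 11)

    def test_attached_to_k_index_result(self, rng):
        corr = np.corrcoef(rng.standard_normal((30, 5)), rowvar=False)
        res = ne.k_index(corr, rank=4)
        assert res.k_min == ne.imbedded_k(5, 4)
        assert res.distance_to_imbedded == pytest.approx(res.k - res.k_min)


class TestImageHistogram:
    def test_identity_matrix_forced_counts(self):
        hist = ne.image_histogram(np.eye(10), n_bins=256)
        assert hist.counts.sum() == 100
        assert hist.counts[-1] == 10  # unit diagonal -> gray 1.0, last bin
        mid = np.searchsorted(hist.bin_edges, 0.5, side="right") - 1
        assert hist.counts[mid] == 90  # zeros -> gray 0.5

    def test_gray_mapping_endpoints(self):
        corr = np.array([[1.0, -1.0], [-1.0, 1.0]])
        hist = ne.image_histogram(corr, n_bins=2)
        assert hist.counts.tolist() == [2, 2]  # grays {0, 1}, two each

    def test_counting_oracle_4x4(self):
        corr = np.array([
            [1.0, 0.5, -0.5, 0.0],
            [0.5, 1.0, 0.25, -1.0],
            [-0.5, 0.25, 1.0, 0.75],
            [0.0, -1.0, 0.75, 1.0],
        ])
        n_bins = 8
        hist = ne.image_histogram(corr, n_bins=n_bins)
        # brute-force tally
        expected = np.zeros(n_bins, dtype=int)
        for v in corr.ravel():
            g = (v + 1.0) / 2.0
            b = min(int(g * n_bins), n_bins - 1)
            expected[b] += 1
        assert hist.counts.tolist() == expected.tolist()

    @settings(max_examples=20, deadline=None)
    @given(n_bins=st.integers(2, 512), seed=st.integers(0, 2**16))
    def test_counts_conserve_pixel_count(self, n_bins, seed):
        e = np.random.default_rng(seed).standard_normal((12, 7))
        corr = np.corrcoef(e, rowvar=False)
        hist = ne.image_histogram(corr, n_bins=n_bins)
        assert hist.counts.sum() == 49
        assert hist.bin_edges[0] == 0.0 and hist.bin_edges[-1] == 1.0

    def test_out_of_range_entries_rejected(self):
        with pytest.raises(DomainError):
            ne.image_histogram(np.full((3, 3), 1.5))

    def test_diagonal_exclusion(self):
        hist = ne.image_histogram(np.eye(6), include_diagonal=False)
        assert hist.total_pixels == 30


class TestPreprocessingOrdering:
    def test_scatter_dominated_k_ordering_tendency(self):
        """Raw > SNV > first derivative for scatter-dominated correlated noise
        (checked as a tendency across seeds)."""
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = ne.SimConfig(n_channels=60, n_samples=1, n_sessions=3,
                               n_replicates=12, background_timings=("per-sample",),
                               seed=seed)
            s = ne.simulate(cfg)
            ks = {}
            for name, steps in ne.STANDARD_VARIANTS.items():
                pre = ne.apply_pipeline(s, steps)
                em = ne.error_matrix(pre, ("sample", "session"))
                surf = ne.error_surfaces(pre, ("sample", "session"))
                ks[name] = ne.k_index(surf.cor, rank=em.rank_bound).k
            wins += ks["raw"] > ks["snv"] > ks["first_derivative"]
        assert wins >= 0.8 * n_seeds
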