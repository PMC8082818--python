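import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from pseudode import (
    DegeneratePseudotimeError,
    UncertaintyEstimationError,
    builtin_pseudotime,
    draw_subsamples,
    infer_subsample_pseudotime,
    normalize_pseudotime,
    permute_pseudotime,
    uncertainty_summary,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([2, 4, 6], [0.0, 0.5, 1.0]),
            ([0.0, 0.25, 1.0], [0.0, 0.25, 1.0]),
            ([5, 1, 3], [1.0, 0.0, 0.5]),
        ],
    )
    def test_minmax_rescaling(self, raw, expected):
        np.testing.assert_allclose(normalize_pseudotime(raw).values, expected)

    def test_constant_vector_raises(self):
        with pytest.raises(DegeneratePseudotimeError):
            normalize_pseudotime([1.0, 1.0, 1.0])

    def test_missing_values_raise(self):
        with pytest.raises(ValueError):
            normalize_pseudotime([0.0, np.nan, 1.0])


class TestDrawSubsamples:
    @pytest.mark.parametrize("n,expected", [(500, 400), (390, 312), (10, 8)])
    def test_floor_sizes(self, n, expected):
        sets = draw_subsamples(n, 0.8, B=3, seed=0)
        for idx in sets:
            assert len(idx) == expected
            assert len(np.unique(idx)) == expected

    def test_counter_based_prefix_property(self):
        """The first k subsamples of a large-B run equal a B=k run."""
        big = draw_subsamples(100, 0.8, B=50, seed=3)
        small = draw_subsamples(100, 0.8, B=10, seed=3)
        for a, b in zip(small, big[:10]):
            assert np.array_equal(a, b)

    def test_stratified_group_sizes(self):
        groups = np.repeat(["a", "b", "c"], [50, 30, 20])
        sets = draw_subsamples(100, 0.8, B=5, groups=groups, seed=1)
        for idx in sets:
            assert len(idx) == 80
            # each group contributes at least floor(0.8 * group size)
            for g, size in (("a", 50), ("b", 30), ("c", 20)):
                assert np.sum(groups[idx] == g) >= int(0.8 * size)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            draw_subsamples(100, 1.2, B=2)


class TestBuiltinPseudotime:
    def test_recovers_monotone_gradient(self):
        """Cells whose expression increases along a latent order are ranked
        correctly (up to direction)."""
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 100)
        mu = np.exp(np.log(20) + 2.0 * np.outer(t, rng.uniform(0.5, 1, 30)))
        y = rng.poisson(mu)
        pt = builtin_pseudotime(y)
        # library-size normalization removes part of the shared gradient,
        # so the recovery is near-perfect rather than exact
        assert abs(spearmanr(pt.values, t).statistic) > 0.95

    def test_equivariant_under_cell_permutation(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(5.0, size=(60, 40))
        perm = rng.permutation(60)
        a = builtin_pseudotime(y).values
        b = builtin_pseudotime(y[perm]).values
        np.testing.assert_allclose(b, a[perm], atol=1e-8)

    def test_accuracy_on_simulated_lineage(self):
        from pseudode import simulate_lineage

        ds = simulate_lineage(200, 200, 0.5, "medium", "single", seed=3)
        pt = builtin_pseudotime(ds.counts)
        assert abs(spearmanr(pt.values, ds.true_time).statistic) >= 0.8

    def test_degenerate_matrix_raises(self):
        with pytest.raises(DegeneratePseudotimeError):
            builtin_pseudotime(np.full((10, 5), 3))


class TestInferSubsamples:
    def test_oracle_method_gives_perfect_correlation(self, small_lineage):
        t = small_lineage.true_time

        def oracle(X):
            # identify the included cells by matching rows back to the data
            idx = _match_rows(X, small_lineage.counts)
            return t[idx]

        sets = draw_subsamples(small_lineage.n_cells, 0.8, B=5, seed=0)
        draws = infer_subsample_pseudotime(
            small_lineage.counts, sets, oracle, min_usable=5
        )
        assert draws.n_usable == 5
        for sub in draws.subsamples:
            rho = spearmanr(sub.inferred.values, t[sub.indices]).statistic
            assert abs(rho) == pytest.approx(1.0)

    def test_failures_are_bookkept(self, small_lineage):
        calls = {"n": 0}

        def flaky(X):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("boom")
            return X.sum(axis=1)

        sets = draw_subsamples(small_lineage.n_cells, 0.8, B=5, seed=0)
        with pytest.warns(UserWarning, match="failed"):
            draws = infer_subsample_pseudotime(
                small_lineage.counts, sets, flaky,
                original=normalize_pseudotime(small_lineage.true_time),
                min_usable=4,
            )
        assert draws.n_usable == 4
        assert sum(s.status == "failed" for s in draws.subsamples) == 1

    def test_too_many_failures_abort(self, small_lineage):
        def broken(X):
            raise RuntimeError("always")

        sets = draw_subsamples(small_lineage.n_cells, 0.8, B=4, seed=0)
        with pytest.raises(UncertaintyEstimationError), pytest.warns(UserWarning):
            infer_subsample_pseudotime(
                small_lineage.counts, sets, broken,
                original=normalize_pseudotime(small_lineage.true_time),
                min_usable=2,
            )

    def test_builtin_tracks_truth_across_subsamples(self):
        from pseudode import simulate_lineage

        ds = simulate_lineage(200, 200, 0.5, "medium", "single", seed=4)
        sets = draw_subsamples(200, 0.8, B=10, seed=0)
        draws = infer_subsample_pseudotime(ds.counts, sets, builtin_pseudotime, min_usable=10)
        rhos = [
            abs(spearmanr(s.inferred.values, ds.true_time[s.indices]).statistic)
            for s in draws.subsamples
        ]
        assert np.median(rhos) >= 0.8


class TestPermute:
    def test_multiset_preserved(self, small_lineage):
        draws = _simple_draws(small_lineage, B=4)
        permute_pseudotime(draws, seed=0)
        for sub in draws.subsamples:
            assert np.array_equal(
                np.sort(sub.permuted.values), np.sort(sub.inferred.values)
            )

    def test_all_orderings_equally_likely(self):
        """Over many permutations of a length-4 vector every ordering
        appears with frequency 1/24 within 3 binomial standard errors."""
        from pseudode.pseudotime import PseudotimeDraws, PseudotimeVector, SubsampleDraw

        base = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        n_rep = 3000
        counts = {p: 0 for p in itertools.permutations(range(4))}
        for b in range(n_rep):
            draws = PseudotimeDraws(
                original=PseudotimeVector(base),
                subsamples=[SubsampleDraw(indices=np.arange(4),
                                          inferred=PseudotimeVector(base.copy()))],
            )
            permute_pseudotime(draws, seed=b)
            key = tuple(np.argsort(draws.subsamples[0].permuted.values))
            counts[key] += 1
        p = 1 / 24
        se = np.sqrt(p * (1 - p) / n_rep)
        freqs = np.array([c / n_rep for c in counts.values()])
        assert (np.abs(freqs - p) < 3.8 * se).all()


class TestUncertaintySummary:
    def test_oracle_has_zero_sd(self, small_lineage):
        draws = _simple_draws(small_lineage, B=5)
        summary = uncertainty_summary(draws)
        # per-subsample min-max renormalization introduces a tiny jitter,
        # but an exact oracle leaves essentially no uncertainty
        sd = summary["sd"].dropna()
        assert (sd < 0.02).all()

    def test_reversed_subsample_is_flipped(self, small_lineage):
        draws = _simple_draws(small_lineage, B=4)
        # reverse one subsample's direction: sd should stay ~0, not ~0.5
        sub = draws.subsamples[2]
        sub.inferred.values = 1.0 - sub.inferred.values
        summary = uncertainty_summary(draws)
        assert summary["sd"].dropna().max() < 0.02

    def test_cell_appearance_frequency(self, small_lineage):
        draws = _simple_draws(small_lineage, B=40)
        summary = uncertainty_summary(draws)
        frac = summary["n_subsamples"] / 40
        se = np.sqrt(0.8 * 0.2 / 40)
        assert abs(frac.mean() - 0.8) < 3 * se


def _match_rows(X, full):
    """Index of each row of X in `full` (rows assumed unique)."""
    keys = {tuple(row): i for i, row in enumerate(full)}
    return np.array([keys[tuple(r)] for r in np.asarray(X, dtype=np.int64)])


def _simple_draws(ds, B):
    t = ds.true_time

    def oracle(X):
        return t[_match_rows(X, ds.counts)]

    sets = draw_subsamples(ds.n_cells, 0.8, B=B, seed=0)
    return infer_subsample_pseudotime(
        ds.counts, sets, oracle,
        original=normalize_pseudotime(t), min_usable=B,
    )
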