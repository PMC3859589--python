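import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from metasucc import spatial
from metasucc.similarity import DissimilarityMatrix


def random_distance(rng, n, dim=3):
    return squareform(pdist(rng.normal(size=(n, dim))))


class TestMantel:
    def test_identical_matrices_give_r_one_and_min_p(self):
        rng = np.random.default_rng(0)
        d = random_distance(rng, 10)
        res = spatial.mantel(d, d, permutations=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(1)
        d1, d2 = random_distance(rng, 12), random_distance(rng, 12)
        mine = spatial.mantel(d1, d2, permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(SkbioDM(d1), SkbioDM(d2), permutations=0)
        assert mine.statistic == pytest.approx(float(r_ref), abs=1e-12)

    def test_exhaustive_enumeration_agrees_with_direct_loop(self):
        rng = np.random.default_rng(2)
        d1, d2 = random_distance(rng, 5), random_distance(rng, 5)
        res = spatial.mantel(d1, d2, exhaustive=True)
        iu = np.triu_indices(5, k=1)
        obs = np.corrcoef(d1[iu], d2[iu])[0, 1]
        hits = 0
        for p in itertools.permutations(range(5)):
            perm = d2[np.ix_(p, p)]
            if np.corrcoef(d1[iu], perm[iu])[0, 1] >= obs - 1e-12:
                hits += 1
        assert res.permutations == 120
        assert res.p_value == pytest.approx(hits / 120)

    def test_invariant_to_offsetting_either_matrix(self):
        rng = np.random.default_rng(3)
        d1, d2 = random_distance(rng, 8), random_distance(rng, 8)
        shifted = d2 + 5.0
        np.fill_diagonal(shifted, 0.0)
        a = spatial.mantel(d1, d2, permutations=49, seed=4)
        b = spatial.mantel(d1, shifted, permutations=49, seed=4)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == b.p_value

    def test_seed_reproducibility_and_p_floor(self):
        rng = np.random.default_rng(5)
        d1, d2 = random_distance(rng, 9), random_distance(rng, 9)
        a = spatial.mantel(d1, d2, permutations=199, seed=11)
        b = spatial.mantel(d1, d2, permutations=199, seed=11)
        assert a.p_value == b.p_value >= 1 / 200

    def test_size_mismatch_error(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            spatial.mantel(random_distance(rng, 5), random_distance(rng, 6))


class TestMantelCorrelogram:
    def test_single_class_with_explicit_breaks(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(8, 2))
        d = random_distance(rng, 8)
        out = spatial.mantel_correlogram(d, coords, breaks=[0.0, 1000.0],
                                         permutations=49, seed=0)
        assert len(out) == 1
        assert out.loc[0, "n_pairs"] == 8 * 7 // 2

    def test_spatially_structured_data_significant_at_short_range(self):
        # two tight spatial clusters with distinct composition
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.normal(0, 5, (8, 2)),
                            rng.normal(500, 5, (8, 2))])
        comp = np.vstack([rng.normal(0, 0.1, (8, 3)),
                          rng.normal(3, 0.1, (8, 3))])
        d = squareform(pdist(comp))
        out = spatial.mantel_correlogram(d, coords, breaks=[0, 50, 600],
                                         permutations=199, seed=2)
        first = out.iloc[0]
        assert first.r > 0 and first.p < 0.05

    def test_null_labels_rarely_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(40):
            coords = rng.uniform(0, 100, (12, 2))
            d = random_distance(rng, 12)
            out = spatial.mantel_correlogram(d, coords, permutations=99,
                                             seed=int(rng.integers(2 ** 31)))
            hits += (out["p_corrected"] < 0.05).any()
        assert hits <= 6  # ~5% per correlogram after Holm

    def test_colonization_kernel_creates_short_range_structure(self):
        """With the dispersal kernel on, compositional similarity is
        significant at short distances and absent at long range."""
        from metasucc import data, simulate
        from metasucc.similarity import pairwise_dissimilarity
        stems, sites, _ = simulate.SCENARIOS["paper-like-spatial"](seed=2)
        mat = data.build_abundance_matrix(stems, ("sapling", "tree", "liana"),
                                          "site", min_diameter_cm=1.0)
        dm = pairwise_dissimilarity(mat, "ruzicka")
        coords = sites.loc[dm.units, ["x_m", "y_m"]].to_numpy()
        out = spatial.mantel_correlogram(dm, coords,
                                         breaks=[0, 300, 600, 1200, 2400, 4800],
                                         permutations=199, seed=0)
        first, last = out.iloc[0], out.iloc[-1]
        assert first.r > 0 and first.p_corrected < 0.05
        assert not (last.r > 0 and last.p < 0.05)

    def test_holm_correction_never_below_raw(self):
        p = np.array([0.01, 0.2, 0.04, 0.5])
        adj = spatial._holm(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestPermanova:
    def test_perfect_separation_gives_r2_one(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        res = spatial.permanova(d, ["a"] * 3 + ["b"] * 3, permutations=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(0)
        d = random_distance(rng, 5)
        with pytest.raises(ValueError, match="singleton"):
            spatial.permanova(d, ["a", "a", "a", "a", "b"])

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(1)
        d = random_distance(rng, 15)
        groups = list("aaaaabbbbbccccc")
        mine = spatial.permanova(d, groups, permutations=99, seed=0)
        ref = skbio_permanova(SkbioDM(d), groups, permutations=0)
        assert mine.pseudo_f == pytest.approx(float(ref["test statistic"]),
                                              rel=1e-10)

    def test_exhaustive_enumeration_two_groups_of_three(self):
        rng = np.random.default_rng(2)
        d = random_distance(rng, 6)
        groups = ["a"] * 3 + ["b"] * 3
        res = spatial.permanova(d, groups, exhaustive=True)
        assert res.test.permutations == 20  # C(6,3) distinct label splits
        # direct enumeration over index subsets
        f_obs = res.pseudo_f
        hits = 0
        for subset in itertools.combinations(range(6), 3):
            labels = np.array(["b"] * 6, dtype=object)
            labels[list(subset)] = "a"
            f = spatial.permanova(d, labels, permutations=0, seed=0).pseudo_f
            hits += f >= f_obs - 1e-12
        assert res.test.p_value == pytest.approx(hits / 20)

    def test_euclidean_distance_reproduces_classical_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = rng.normal(size=12)
            g = np.repeat(list("abc"), 4)
            d = np.abs(y[:, None] - y[None, :])
            res = spatial.permanova(d, g, permutations=9, seed=0)
            f_ref = stats.f_oneway(*(y[g == lab] for lab in "abc")).statistic
            assert abs(res.pseudo_f - f_ref) < 1e-10

    def test_linear_coding_has_one_model_df(self):
        rng = np.random.default_rng(4)
        d = random_distance(rng, 9)
        groups = ["SBA-1"] * 3 + ["SBA-2"] * 3 + ["SBA-3"] * 3
        cat = spatial.permanova(d, groups, permutations=49, seed=0)
        lin = spatial.permanova(d, groups, permutations=49, seed=0,
                                coding="linear")
        assert cat.df_model == 2 and lin.df_model == 1

    def test_r2_centered_at_df_ratio_under_label_shuffles(self):
        rng = np.random.default_rng(5)
        d = random_distance(rng, 18)
        r2s = []
        for _ in range(100):
            g = rng.permutation(np.repeat(list("abc"), 6))
            r2s.append(spatial.permanova(d, g, permutations=0, seed=0).r2)
        assert np.mean(r2s) == pytest.approx(2 / 17, abs=0.03)
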