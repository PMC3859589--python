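import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasucc import data, similarity
from metasucc.similarity import (DissimilarityMatrix, chao_jaccard_abundance,
                                 jaccard_presence, morisita_horn,
                                 pairwise_dissimilarity, ruzicka,
                                 seedling_divergence)

pair = st.tuples(
    st.lists(st.integers(0, 50), min_size=2, max_size=15),
    st.lists(st.integers(0, 50), min_size=2, max_size=15),
).map(lambda t: (t[0][: min(len(t[0]), len(t[1]))],
                 t[1][: min(len(t[0]), len(t[1]))])) \
 .filter(lambda t: sum(t[0]) + sum(t[1]) > 0)


def chao_jaccard_oracle(x, y):
    """Independent transcription of the corrected abundance estimator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.sum(), y.sum()
    sh = (x > 0) & (y > 0)
    if not sh.any():
        return 0.0

    def uhat(a, b, na, nb):
        u = (a[sh] / na).sum()
        f1 = int(((b == 1) & sh).sum())
        f2 = int(((b == 2) & sh).sum())
        u += (nb - 1) / nb * f1 / (2 * (f2 if f2 > 0 else f2 + 1)) \
            * (a[sh] / na)[b[sh] == 1].sum()
        return min(u, 1.0)

    u, v = uhat(x, y, n, m), uhat(y, x, m, n)
    if u == 0 or v == 0:
        return 0.0
    return u * v / (u + v - u * v)


class TestRuzicka:
    def test_identity_and_disjoint(self):
        assert ruzicka([3, 1, 0], [3, 1, 0]) == 0.0
        assert ruzicka([3, 0], [0, 2]) == 1.0

    def test_hand_value(self):
        assert ruzicka([2, 0], [1, 1]) == pytest.approx(1 - 1 / 3)

    def test_binary_inputs_reduce_to_presence_jaccard(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x, y = rng.integers(0, 6, 12), rng.integers(0, 6, 12)
            if x.sum() + y.sum() == 0:
                continue
            assert ruzicka((x > 0).astype(int), (y > 0).astype(int)) == \
                pytest.approx(jaccard_presence(x, y))

    @settings(deadline=None, derandomize=True)
    @given(pair)
    def test_symmetric_and_bounded(self, xy):
        x, y = xy
        d = ruzicka(x, y)
        assert d == pytest.approx(ruzicka(y, x))
        assert -1e-12 <= d <= 1 + 1e-12

    def test_both_zero_is_an_error(self):
        with pytest.raises(ValueError):
            ruzicka([0, 0], [0, 0])


class TestJaccardPresence:
    def test_hand_count(self):
        # supports {A,B} vs {B,C}: 1 shared of 3
        assert jaccard_presence([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_identical_supports(self):
        assert jaccard_presence([4, 9], [1, 1]) == 0.0


class TestChaoJaccard:
    def test_identical_singleton_free_is_one(self):
        assert chao_jaccard_abundance([5, 3, 2], [5, 3, 2]) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert chao_jaccard_abundance([5, 0], [0, 3]) == 0.0

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            x = rng.poisson(1.5, 20)
            y = rng.poisson(1.5, 20)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert chao_jaccard_abundance(x, y) == pytest.approx(
                chao_jaccard_oracle(x, y), abs=1e-12)
            checked += 1

    def test_invariant_to_species_order_and_padding(self):
        x, y = np.array([5, 3, 1, 0]), np.array([4, 0, 2, 6])
        base = chao_jaccard_abundance(x, y)
        perm = np.array([2, 0, 3, 1])
        assert chao_jaccard_abundance(x[perm], y[perm]) == pytest.approx(base)
        xp = np.concatenate([x, [0, 0]])
        yp = np.concatenate([y, [0, 0]])
        assert chao_jaccard_abundance(xp, yp) == pytest.approx(base)

    def test_self_similarity_approaches_one_as_singletons_vanish(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(40))
        a = rng.multinomial(3000, p)
        b = rng.multinomial(3000, p)
        assert chao_jaccard_abundance(a, b) > 0.9

    def test_uncorrected_flag_drops_the_correction(self):
        x, y = np.array([5, 3, 1, 0]), np.array([4, 0, 2, 1])
        raw = chao_jaccard_abundance(x, y, corrected=False)
        u = (5 + 1) / 9      # shared species 0 and 2 in x
        v = (4 + 2) / 7
        assert raw == pytest.approx(u * v / (u + v - u * v))

    def test_symmetry(self):
        x, y = np.array([5, 3, 1, 0]), np.array([4, 0, 2, 6])
        assert chao_jaccard_abundance(x, y) == pytest.approx(
            chao_jaccard_abundance(y, x))


class TestDissimilarityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], np.array([[1.0, 0], [0, 0]]))

    def test_pairwise_matrix_properties(self, paper_like):
        stems, _, _ = paper_like
        mat = data.build_abundance_matrix(stems, "liana", "site")
        dm = pairwise_dissimilarity(mat, "ruzicka")
        v = dm.values
        assert np.allclose(v, v.T)
        assert (np.diag(v) == 0).all()
        assert v.max() <= 1.0 + 1e-12

    def test_unknown_index_rejected(self, toy_stems):
        mat = data.build_abundance_matrix(toy_stems, "sapling", "site")
        with pytest.raises(ValueError):
            pairwise_dissimilarity(mat, "bray")


class TestSeedlingDivergence:
    def _traits(self, species, mids):
        return pd.DataFrame({"species_code": species, "life_form": "tree",
                             "dbhmax_mid_cm": mids})

    def _mat(self, arr, units):
        df = pd.DataFrame(arr, index=units,
                          columns=[f"sp{i}" for i in range(arr.shape[1])])
        return data.AbundanceMatrix(df, ("seedling",), "site")

    def test_identical_assemblages_score_one(self):
        arr = np.array([[4, 3, 2], [5, 2, 2]])
        traits = self._traits([f"sp{i}" for i in range(3)], [30.0] * 3)
        ref = self._mat(arr, ["a", "b"])
        out = seedling_divergence({"k1": self._mat(arr, ["a", "b"])}, ref, traits)
        assert out.loc[0, "mean_similarity"] == pytest.approx(1.0)

    def test_canopy_filter_drops_small_statured_species(self):
        # species 0 is a shrub-class species (mid 3 cm) shared by both
        # assemblages; once filtered, the pair shares nothing
        arr = np.array([[10, 0], [10, 0]])
        ref = self._mat(np.array([[10, 5], [10, 5]]), ["a", "b"])
        traits = self._traits(["sp0", "sp1"], [3.0, 30.0])
        out = seedling_divergence({"k": self._mat(arr, ["c", "d"])}, ref, traits)
        assert out.loc[0, "mean_similarity"] == 0.0

    def test_empty_class_named_in_error(self):
        traits = self._traits(["sp0"], [30.0])
        ref = self._mat(np.array([[3]]), ["a"])
        no_units = self._mat(np.zeros((0, 1)), [])
        with pytest.raises(ValueError, match="k9"):
            seedling_divergence({"k9": no_units}, ref, traits)

    def test_unit_without_canopy_stems_scores_zero(self):
        traits = self._traits(["sp0"], [30.0])
        ref = self._mat(np.array([[3]]), ["a"])
        empty = self._mat(np.zeros((1, 1)), ["b"])
        out = seedling_divergence({"k": empty}, ref, traits)
        assert out.loc[0, "mean_similarity"] == 0.0

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(2.0, size=(4, 6)) + 1
        ref = self._mat(rng.poisson(2.0, size=(3, 6)) + 1, ["r1", "r2", "r3"])
        traits = self._traits([f"sp{i}" for i in range(6)], [30.0] * 6)
        out = seedling_divergence({"k": self._mat(arr, list("abcd"))}, ref,
                                  traits, ci="bootstrap", seed=0)
        row = out.iloc[0]
        assert row.ci_low <= row.mean_similarity <= row.ci_high


def test_morisita_horn_identity_and_bounds():
    assert morisita_horn([2, 1], [4, 2]) == pytest.approx(0.0)  # proportional
    rng = np.random.default_rng(1)
    for _ in range(20):
        x, y = rng.integers(0, 9, 10), rng.integers(0, 9, 10)
        if x.sum() == 0 or y.sum() == 0:
            continue
        assert 0 - 1e-9 <= morisita_horn(x, y) <= 1 + 1e-9
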