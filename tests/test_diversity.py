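import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuetax.diversity import (
    DistanceMatrix,
    PermanovaTest,
    bray_curtis,
    chao1,
    distance_matrix,
    jaccard_distance,
    kruskal_wallis,
    pcoa,
    permanova,
    rarefied_chao,
    shannon,
)
from rescuetax.io import AbundanceTable

from conftest import make_relative_table


# ------------------------------------------------------------- oracles

def shannon_oracle(v):
    p = np.asarray(v, dtype=float)
    p = p / p.sum()
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def chao1_oracle(counts):
    c = np.asarray(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def kruskal_oracle(values, groups):
    """Rank-sum H with average ranks and the standard tie correction."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    n = len(values)
    h = 0.0
    for g in set(groups):
        mask = np.asarray(groups) == g
        h += ranks[mask].sum() ** 2 / mask.sum()
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1 - sum(t**3 - t for t in counts) / (n**3 - n)
    return h / correction


# ---------------------------------------------------------------- alpha

class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_single_taxon_is_zero(self):
        assert shannon([1, 0, 0]) == 0.0

    def test_matches_direct_summation(self):
        assert shannon([0.5, 0.3, 0.2]) == pytest.approx(
            shannon_oracle([0.5, 0.3, 0.2]), abs=1e-12)

    def test_scale_invariant(self):
        v = [3.0, 1.0, 6.0]
        assert shannon(v) == pytest.approx(shannon(np.array(v) * 17.3), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0, 0])


class TestChao1:
    def test_hand_computed(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 2*1/(2*2)
        assert chao1([1, 1, 2, 5, 9]) == pytest.approx(5.5)

    def test_no_singletons_returns_observed(self):
        assert chao1([3, 3, 3]) == 3.0
        assert chao1([2, 5, 0, 7]) == 3.0

    def test_matches_formula_on_random_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            c = rng.integers(0, 5, size=8)
            if c.sum() == 0:
                continue
            assert chao1(c) == pytest.approx(chao1_oracle(c), abs=1e-10)

    def test_rejects_relative_data(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([0.5, 0.5])

    def test_chao1_at_least_observed_richness(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            c = rng.integers(0, 6, size=10)
            if c.sum() == 0:
                continue
            assert chao1(c) >= (np.asarray(c) > 0).sum()


class TestRarefiedChao:
    def test_full_depth_equals_plain_chao1(self, toy_counts):
        depth = int(toy_counts.values.sum(axis=1).min())
        out = rarefied_chao(toy_counts, depth=depth, reps=3, seed=0)
        # sample s3 has total 20 = min; its subsample at depth 20 is itself
        assert out["s3"] == pytest.approx(chao1(toy_counts.data.loc["s3"]))

    def test_deterministic_given_seed(self, toy_counts):
        a = rarefied_chao(toy_counts, depth=10, reps=5, seed=42)
        b = rarefied_chao(toy_counts, depth=10, reps=5, seed=42)
        pd.testing.assert_series_equal(a, b)

    def test_depth_beyond_total_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="depth"):
            rarefied_chao(toy_counts, depth=10_000, reps=1, seed=0)

    def test_mean_matches_exhaustive_expectation(self):
        """Monte-Carlo mean vs the exact expectation over all subsamples."""
        counts = np.array([3, 2, 1])
        depth = 2
        # exhaustive: enumerate draws of 2 of the 6 labelled individuals
        individuals = [0] * 3 + [1] * 2 + [2] * 1
        exact = np.mean([
            chao1(np.bincount(pick, minlength=3))
            for pick in itertools.combinations(individuals, depth)
        ])
        table = AbundanceTable(
            data=pd.DataFrame([counts], index=["s"], columns=list("abc")),
            mode="counts")
        mc = rarefied_chao(table, depth=depth, reps=4000, seed=1)["s"]
        assert mc == pytest.approx(exact, abs=0.05)


# ----------------------------------------------------------------- beta

class TestDissimilarities:
    def test_bray_curtis_hand_value(self):
        assert bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(4 / 12)

    def test_bray_curtis_identity_and_disjoint(self):
        assert bray_curtis([1, 2], [1, 2]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0

    def test_jaccard_set_count(self):
        # supports {a,b,c} vs {b,c,d}: 1 - 2/4
        assert jaccard_distance([1, 1, 1, 0], [0, 2, 3, 4]) == pytest.approx(0.5)

    def test_jaccard_identical_and_disjoint_supports(self):
        assert jaccard_distance([1, 2, 0], [5, 1, 0]) == 0.0
        assert jaccard_distance([1, 0], [0, 1]) == 1.0

    def test_both_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            jaccard_distance([0, 0], [0, 0])

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6),
           st.data())
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, x, data):
        y = data.draw(st.lists(st.floats(0, 100), min_size=len(x), max_size=len(x)))
        x, y = np.array(x), np.array(y)
        if x.sum() == 0 or y.sum() == 0:
            return
        for fn in (bray_curtis, jaccard_distance):
            d_xy, d_yx = fn(x, y), fn(y, x)
            assert d_xy == pytest.approx(d_yx, abs=1e-12)
            assert -1e-12 <= d_xy <= 1 + 1e-12

    def test_distance_matrix_contract(self):
        t = make_relative_table([[5, 1, 0], [1, 5, 0], [0, 1, 5]])
        dm = distance_matrix(t, metric="bray_curtis")
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


# ----------------------------------------------------------- ordination

class TestPCoA:
    def test_line_configuration_reproduced(self):
        # points on a line at 0, 3, 5: first axis must recover the spacing
        pts = np.array([0.0, 3.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :]) / 10.0  # scale into [0,1]
        dm = DistanceMatrix(sample_ids=["a", "b", "c"], values=d, metric="jaccard")
        res = pcoa(dm, n_axes=2)
        coords = res.coordinates[:, 0]
        recon = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(recon, d, atol=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_equidistant_triplet_has_equal_eigenvalues(self):
        d = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        dm = DistanceMatrix(sample_ids=list("abc"), values=d, metric="jaccard")
        res = pcoa(dm, n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_embeddable_spectrum_nonnegative(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d = d / (d.max() * 1.01)
        dm = DistanceMatrix(sample_ids=[str(i) for i in range(6)], values=d,
                            metric="jaccard")
        res = pcoa(dm)
        assert (res.eigenvalues >= -1e-9).all()
        # full-rank coordinates reproduce the input distances
        recon = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1)
        np.testing.assert_allclose(recon, d, atol=1e-8)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.ordination import pcoa as sk_pcoa

        t = make_relative_table(np.random.default_rng(5).integers(1, 20, (5, 4)))
        dm = distance_matrix(t)
        ours = pcoa(dm, n_axes=2)
        theirs = sk_pcoa(SkDM(dm.values, ids=[str(s) for s in dm.sample_ids]),
                         number_of_dimensions=2)
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(theirs.samples.values), atol=1e-8)


# ------------------------------------------------------------ permanova

class TestPermanova:
    @pytest.fixture
    def toy_dm(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.2
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d /= d.max() * 1.01
        return DistanceMatrix(sample_ids=[f"s{i}" for i in range(1, 7)],
                              values=d, metric="jaccard")

    def test_exhaustive_matches_monte_carlo(self, toy_dm, toy_design_2groups):
        exact = permanova(toy_dm, toy_design_2groups, method="exhaustive")
        mc = permanova(toy_dm, toy_design_2groups, n_permutations=20_000, seed=3)
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 20_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1 / 20_001

    def test_perfect_separation_r2_near_one(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        dm = DistanceMatrix(sample_ids=[f"s{i}" for i in range(6)], values=d,
                            metric="jaccard")
        res = permanova(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r2_invariant_to_relabeling_within_groups(self, toy_dm,
                                                      toy_design_2groups):
        base = permanova(toy_dm, toy_design_2groups, n_permutations=9, seed=0)
        swapped = toy_design_2groups.copy()
        swapped[["s1", "s3"]] = swapped[["s3", "s1"]].values  # same group
        alt = permanova(toy_dm, swapped, n_permutations=9, seed=0)
        assert alt.r_squared == pytest.approx(base.r_squared)
        assert alt.pseudo_f == pytest.approx(base.pseudo_f)

    def test_statistic_matches_skbio(self, toy_dm, toy_design_2groups):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        ours = permanova(toy_dm, toy_design_2groups, n_permutations=99, seed=0)
        theirs = sk_permanova(
            SkDM(toy_dm.values, ids=list(toy_design_2groups.index)),
            list(toy_design_2groups.values), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_small_group_rejected(self, toy_dm):
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(toy_dm, ["a", "b", "b", "b", "b", "b"], n_permutations=9)

    def test_estimator_interface(self, toy_dm, toy_design_2groups):
        est = PermanovaTest(n_permutations=99, random_state=1)
        est.fit(toy_dm, toy_design_2groups)
        assert 0 <= est.r_squared_ <= 1
        assert est.p_value_ >= 1 / 100
        assert est.get_params()["n_permutations"] == 99


# ------------------------------------------------------- kruskal-wallis

class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_all_tied_returns_zero_one(self):
        h, p = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert (h, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_matches_ranking_oracle_exhaustively(self):
        """All two-group splits of small integer-valued inputs (ties incl.)."""
        for n in (4, 5, 6):
            for values in itertools.product((1, 2, 3), repeat=n):
                groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
                if len(set(values)) == 1:
                    continue
                h, _ = kruskal_wallis(values, groups)
                assert h == pytest.approx(kruskal_oracle(values, groups),
                                          abs=1e-10)
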