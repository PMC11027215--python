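"""Cosine and Word Mover's Distance backends against oracles and invariants."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from cdemap import (
    EmbeddingStore,
    OOVError,
    TokenBag,
    cosine_similarity,
    normalize_text,
    to_token_bag,
    token_similarity,
    toy_embeddings,
    wmd_distance,
    wmd_similarity,
)



def brute_force_wmd(counts_a: tuple, counts_b: tuple, cost) -> float:
    """Independent transport oracle: exhaustive greedy-saturation search.

    Works in integer mass units (counts cross-scaled to a common total) so
    states are exact; at each step any still-active cell may ship
    min(row remainder, column remainder).  Every vertex of the transport
    polytope arises from some such saturation order, and the optimum of the
    LP is attained at a vertex, so the minimum over all orders is exact.
    """
    sa, sb = sum(counts_a), sum(counts_b)
    cost = tuple(tuple(row) for row in cost)

    @lru_cache(maxsize=None)
    def best(ra: tuple, rb: tuple) -> float:
        active = [i for i, v in enumerate(ra) if v]
        if not active:
            return 0.0
        out = math.inf
        for i in active:
            for j, vj in enumerate(rb):
                if not vj:
                    continue
                t = min(ra[i], vj)
                ra2 = ra[:i] + (ra[i] - t,) + ra[i + 1 :]
                rb2 = rb[:j] + (vj - t,) + rb[j + 1 :]
                out = min(out, t * cost[i][j] + best(ra2, rb2))
        return out

    return best(
        tuple(c * sb for c in counts_a), tuple(c * sa for c in counts_b)
    ) / (sa * sb)


class TestTokenBag:
    def test_unique_tokens_counted_once(self):
        bag = to_token_bag("geriatric depression scale feel helpless")
        assert len(bag) == 5 and set(bag.counts.values()) == {1}

    def test_repeated_token_counted_with_multiplicity(self):
        bag = to_token_bag("participant demographics participant marital status")
        assert bag.counts["participant"] == 2
        assert bag.total == 5

    def test_empty_text_gives_empty_bag(self):
        bag = to_token_bag("")
        assert not bag and bag.total == 0

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            TokenBag({"x": 0})


class TestCosine:
    def test_life_satisfaction_pair_scores_six_over_root_48(self):
        """The depression-scale worked pair: 8 vs 6 tokens sharing all 6."""
        a = to_token_bag(
            normalize_text(
                "Behavioral Assessment - Geriatric Depression Scale "
                "Are you basically satisfied with your life?"
            )
        )
        b = to_token_bag(
            normalize_text(
                "Geriatric Depression Scale 1. Are you basically satisfied with your life?"
            )
        )
        score = cosine_similarity(a, b).value
        assert score == pytest.approx(6 / math.sqrt(48), abs=1e-12)
        assert round(score, 1) == 0.9

    def test_feel_helpless_pair_near_reported_value(self):
        """Repeated 'feel helpless' tokens: reported 0.88, pinned ±0.05."""
        a = to_token_bag(normalize_text("Geriatric Depression Scale 8. Do you often feel helpless?"))
        b = to_token_bag(
            normalize_text(
                "Geriatric Depression Scale (GDS) - feel helpless indicator "
                "Do you often feel helpless?"
            )
        )
        assert cosine_similarity(a, b).value == pytest.approx(0.88, abs=0.05)

    def test_repeated_word_depresses_score_below_threshold(self):
        """'Participant' appearing twice keeps a true pair under 0.6."""
        a = to_token_bag(normalize_text("Subject Demographics Marital status"))
        b = to_token_bag(normalize_text("Participant Demographics 4. Participant Marital Status"))
        assert cosine_similarity(a, b).value < 0.6

    def test_identical_bags_score_one(self):
        bag = to_token_bag("left hippocampus volume")
        assert cosine_similarity(bag, bag).value == pytest.approx(1.0)

    def test_disjoint_bags_score_zero(self):
        assert cosine_similarity(to_token_bag("a b"), to_token_bag("c d")).value == 0.0

    def test_either_empty_scores_zero(self):
        assert cosine_similarity(to_token_bag(""), to_token_bag("x")).value == 0.0

    @given(
        st.dictionaries(st.sampled_from("abcdef"), st.integers(1, 4), min_size=1),
        st.dictionaries(st.sampled_from("abcdef"), st.integers(1, 4), min_size=1),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric(self, ca, cb):
        a, b = TokenBag(ca), TokenBag(cb)
        assert cosine_similarity(a, b).value == pytest.approx(
            cosine_similarity(b, a).value
        )


class TestWmdAgainstOracle:
    def test_exact_solver_matches_brute_force_on_200_random_instances(self):
        """Transport LP vs exhaustive vertex enumeration, vocabularies <= 4."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(200):
            n, m = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            vocab = [f"t{k}" for k in range(n + m)]
            store = EmbeddingStore({v: rng.standard_normal(3) for v in vocab})
            ca = tuple(int(c) for c in rng.integers(1, 4, n))
            cb = tuple(int(c) for c in rng.integers(1, 4, m))
            bag_a = TokenBag(dict(zip(vocab[:n], ca)))
            bag_b = TokenBag(dict(zip(vocab[n:], cb)))
            solved = wmd_distance(bag_a, bag_b, store)
            cost = cdist(
                np.stack([store.unit_vector(t) for t in sorted(bag_a)]),
                np.stack([store.unit_vector(t) for t in sorted(bag_b)]),
            )
            ca_sorted = tuple(bag_a.counts[t] for t in sorted(bag_a))
            cb_sorted = tuple(bag_b.counts[t] for t in sorted(bag_b))
            oracle = brute_force_wmd(ca_sorted, cb_sorted, cost)
            worst = max(worst, abs(solved - oracle))
        assert worst <= 1e-9

    def test_self_distance_zero(self, small_store):
        bag = to_token_bag("a b c b")
        assert wmd_distance(bag, bag, small_store) == pytest.approx(0.0, abs=1e-12)

    def test_single_token_bags_reduce_to_unit_vector_distance(self, small_store):
        d = wmd_distance(to_token_bag("a"), to_token_bag("b"), small_store)
        expected = float(
            np.linalg.norm(small_store.unit_vector("a") - small_store.unit_vector("b"))
        )
        assert d == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_triangle_inequality_on_random_triples(self, small_store):
        rng = np.random.default_rng(7)
        tokens = list("abcdefgh")
        for _ in range(25):
            bags = [
                TokenBag(
                    {
                        t: int(c)
                        for t, c in zip(
                            rng.choice(tokens, size=3, replace=False),
                            rng.integers(1, 4, 3),
                        )
                    }
                )
                for _ in range(3)
            ]
            x, y, z = bags
            dxy = wmd_distance(x, y, small_store)
            assert dxy == pytest.approx(wmd_distance(y, x, small_store), abs=1e-9)
            dxz = wmd_distance(x, z, small_store)
            dzy = wmd_distance(z, y, small_store)
            assert dxy <= dxz + dzy + 1e-9

    def test_bounded_by_max_ground_distance(self, small_store):
        a, b = to_token_bag("a b c"), to_token_bag("d e f g")
        cost = cdist(
            np.stack([small_store.unit_vector(t) for t in sorted(a)]),
            np.stack([small_store.unit_vector(t) for t in sorted(b)]),
        )
        assert wmd_distance(a, b, small_store) <= cost.max() + 1e-12

    def test_shared_token_with_equal_weight_never_increases_distance(self, small_store):
        a, b = to_token_bag("a b"), to_token_bag("c d")
        base = wmd_distance(a, b, small_store)
        # append one shared token to both sides (equal relative weight 1/3)
        a2, b2 = to_token_bag("a b e"), to_token_bag("c d e")
        assert wmd_distance(a2, b2, small_store) <= base + 1e-9


class TestWmdSimilarity:
    def test_zero_distance_gives_similarity_one(self, small_store):
        bag = to_token_bag("a b")
        assert wmd_similarity(bag, bag, small_store).value == pytest.approx(1.0)

    def test_unit_distance_gives_half(self):
        # two antipodal-ish tokens at exactly unit ground distance
        store = EmbeddingStore({"x": np.array([1.0, 0.0]), "y": np.array([0.5, math.sqrt(3) / 2])})
        d = wmd_distance(to_token_bag("x"), to_token_bag("y"), store)
        assert d == pytest.approx(1.0, abs=1e-12)
        s = wmd_similarity(to_token_bag("x"), to_token_bag("y"), store)
        assert s.value == pytest.approx(0.5, abs=1e-12)

    def test_fully_oov_pair_scores_zero_with_count(self, small_store):
        s = wmd_similarity(to_token_bag("qq rr"), to_token_bag("a b"), small_store)
        assert s.value == 0.0 and s.oov_dropped == 2

    def test_partial_oov_tokens_are_dropped_not_defaulted(self, small_store):
        full = wmd_similarity(to_token_bag("a b"), to_token_bag("c"), small_store)
        extra = wmd_similarity(to_token_bag("a b zz"), to_token_bag("c"), small_store)
        assert extra.oov_dropped == 1
        assert extra.value == pytest.approx(full.value, abs=1e-12)

    def test_wmd_distance_raises_on_fully_oov_bag(self, small_store):
        with pytest.raises(OOVError):
            wmd_distance(to_token_bag("zz"), to_token_bag("a"), small_store)


class TestTokenSimilarity:
    def test_self_similarity_is_one(self, small_store):
        assert token_similarity("a", "a", small_store) == pytest.approx(1.0)

    def test_synonym_geometry_of_toy_store(self):
        store = toy_embeddings(
            ["mean", "average", "tap", "score"], [["mean", "average"]], seed=3
        )
        assert token_similarity("mean", "average", store) >= 0.95
        assert abs(token_similarity("mean", "tap", store)) <= 0.3

    def test_oov_token_raises(self, small_store):
        with pytest.raises(OOVError, match="triangularis"):
            token_similarity("triangularis", "a", small_store)


class TestEmbeddingStore:
    def test_text_round_trip_with_and_without_header(self, small_store, tmp_path):
        for header in (False, True):
            p = tmp_path / f"vecs_{header}.txt"
            small_store.save_text(p, header=header)
            back = EmbeddingStore.load_text(p)
            assert back.vocabulary == small_store.vocabulary
            for t in small_store.vocabulary:
                np.testing.assert_array_equal(back.vector(t), small_store.vector(t))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingStore({"a": np.ones(3), "b": np.ones(4)})

    def test_oov_membership(self, small_store):
        assert "a" in small_store and "zz" not in small_store
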