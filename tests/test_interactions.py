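import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attnteract.interactions import (InteractionCall, PairAttentionProfile,
                                     active_filters_at, aggregate_profiles,
                                     benjamini_hochberg, call_interactions,
                                     collapse_heads, extract_pair_attention,
                                     family_summary, mann_whitney_test,
                                     overlap_enrichment)


# ---------------------------------------------------------------- collapse
def test_collapse_single_head_is_identity(rng):
    a = rng.random((1, 4, 4))
    np.testing.assert_array_equal(collapse_heads(a), a[0])


def test_collapse_is_elementwise_max():
    a = np.array([[[0.1, 0.9], [0.3, 0.4]], [[0.5, 0.2], [0.1, 0.8]]])
    np.testing.assert_array_equal(collapse_heads(a),
                                  [[0.5, 0.9], [0.3, 0.8]])


def test_collapsed_entries_stay_in_unit_interval(rng):
    a = rng.dirichlet(np.ones(5), size=(3, 5))      # row-stochastic heads
    out = collapse_heads(a)
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert not np.allclose(out.sum(axis=1), 1.0)    # rows need not renormalize


# ----------------------------------------------------------- active filters
def test_all_zero_column_has_no_active_filters():
    pooled = np.zeros((3, 4))
    assert active_filters_at(pooled, 0, np.array([1.0, 2.0, 0.0])).size == 0


def test_active_filter_threshold_oracle():
    pooled = np.array([[0.9, 0.2], [0.3, 0.8]])
    max_act = np.array([1.0, 1.0])
    assert list(active_filters_at(pooled, 0, max_act)) == [0]
    assert list(active_filters_at(pooled, 1, max_act)) == [1]


def test_activation_exactly_at_threshold_is_excluded():
    pooled = np.array([[0.5]])
    assert active_filters_at(pooled, 0, np.array([1.0])).size == 0
    assert list(active_filters_at(pooled + 1e-9, 0, np.array([1.0]))) == [0]


# ------------------------------------------------------------- pair extract
def test_pair_extraction_hand_trace():
    d, f = 4, 3
    collapsed = np.zeros((d, d))
    collapsed[0, 3] = 0.6
    pooled = np.zeros((f, d))
    pooled[1, 0] = 1.0            # filter 1 active at position 0
    pooled[2, 3] = 1.0            # filter 2 active at position 3
    out = extract_pair_attention(collapsed, pooled, np.ones(f), "ex")
    assert out == [((1, 2), 0.6, (0, 3))]


def test_pair_extraction_symmetrizes_and_canonicalizes():
    collapsed = np.array([[0.0, 0.2], [0.7, 0.0]])
    pooled = np.array([[1.0, 0.0], [0.0, 1.0]])     # filter 0 at pos 0, 1 at pos 1
    out = extract_pair_attention(collapsed, pooled, np.ones(2), "ex")
    # value is max over both directions; pair ordered regardless of positions
    assert out == [((0, 1), 0.7, (0, 1))]
    pooled_swapped = pooled[::-1]                   # filter 1 at pos 0, 0 at pos 1
    out2 = extract_pair_attention(collapsed, pooled_swapped, np.ones(2), "ex")
    assert out2[0][0] == (0, 1)


def test_no_active_filters_gives_no_pairs(rng):
    out = extract_pair_attention(rng.random((3, 3)), np.zeros((2, 3)),
                                 np.ones(2), "ex")
    assert out == []


# -------------------------------------------------------------- aggregation
def test_aggregation_applies_attention_cutoff():
    records = [("e1", (0, 1), 0.05, (0, 1)), ("e2", (0, 1), 0.06, (1, 3)),
               ("e1", (1, 2), 0.45, (0, 2))]
    profiles = aggregate_profiles(records, pool_window=6, attn_cutoff=0.10)
    assert set(profiles) == {(1, 2)}


def test_distance_conversion_uses_pool_window():
    records = [("e1", (0, 1), 0.5, (0, 3))]
    prof = aggregate_profiles(records, pool_window=6, attn_cutoff=0.1)[(0, 1)]
    assert prof.distances_bp == [18]
    assert prof.frequency == 1


# ----------------------------------------------------------- Mann-Whitney U
def exact_mwu_oracle(fg, bg):
    """P(U >= observed) by full enumeration of label assignments."""
    pooled = list(fg) + list(bg)
    n1 = len(fg)

    def u_stat(sample_fg, sample_bg):
        u = 0.0
        for a in sample_fg:
            for b in sample_bg:
                u += (a > b) + 0.5 * (a == b)
        return u

    observed = u_stat(fg, bg)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = set(idx)
        u = u_stat([pooled[i] for i in sel],
                   [pooled[i] for i in range(len(pooled)) if i not in sel])
        count += u >= observed - 1e-12
        total += 1
    return count / total


def test_mwu_textbook_case_equals_one_twentieth():
    assert mann_whitney_test([3, 4, 5], [0, 1, 2]) == pytest.approx(0.05)
    assert exact_mwu_oracle([3, 4, 5], [0, 1, 2]) == pytest.approx(0.05)


@given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10 ** 6))
@settings(deadline=None, max_examples=60)
def test_mwu_matches_enumeration_for_small_samples(n1, n2, seed):
    rng = np.random.default_rng(seed)
    # distinct values: the exact null assumes no ties
    values = rng.permutation(100)[: n1 + n2].astype(float)
    fg, bg = values[:n1], values[n1:]
    got = mann_whitney_test(fg, bg)
    assert got == pytest.approx(exact_mwu_oracle(fg, bg), abs=1e-12)


def test_mwu_identical_samples_not_significant():
    assert mann_whitney_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) >= 0.5


def test_mwu_p_decreases_under_positive_shift(rng):
    bg = rng.random(30)
    fg = rng.random(30)
    ps = [mann_whitney_test(fg + shift, bg) for shift in (0.0, 0.5, 1.0)]
    assert ps[0] > ps[1] > ps[2]


def test_mwu_rejects_empty():
    with pytest.raises(ValueError):
        mann_whitney_test([], [1.0])


# -------------------------------------------------------- Benjamini-Hochberg
def bh_oracle(pvalues):
    """Step-up: p * n / rank with a reverse cumulative minimum, capped at 1."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(benjamini_hochberg([0.42]), [0.42])


def test_bh_textbook_sequence():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
       st.integers(0, 10 ** 6))
@settings(deadline=None, max_examples=60)
def test_bh_matches_step_up_oracle_and_is_order_equivariant(pvals, seed):
    got = benjamini_hochberg(pvals)
    np.testing.assert_allclose(got, bh_oracle(pvals), atol=1e-12)
    assert np.all(got >= np.asarray(pvals) - 1e-12)
    perm = np.random.default_rng(seed).permutation(len(pvals))
    permuted = benjamini_hochberg(np.asarray(pvals)[perm])
    np.testing.assert_allclose(permuted, got[perm], atol=1e-12)


# ------------------------------------------------------------------ calling
def make_profile(pair, values, example_ids=None, positions=(0, 3)):
    prof = PairAttentionProfile(pair)
    for i, v in enumerate(values):
        prof.add(v, (example_ids or [f"e{i}" for i in range(len(values))])[i],
                 positions, pool_window=6)
    return prof


def test_call_interactions_maps_dedups_and_drops_self_pairs():
    strong = list(np.linspace(0.5, 0.9, 12))
    weak = list(np.linspace(0.01, 0.05, 12))
    fg = {(0, 1): make_profile((0, 1), strong),
          (2, 3): make_profile((2, 3), strong),     # same TF pair as (0,1)
          (4, 5): make_profile((4, 5), strong),     # maps to (B, B): self pair
          (0, 5): make_profile((0, 5), weak)}       # not significant
    bg = {pair: make_profile(pair, weak) for pair in fg}
    mapping = {0: "A", 1: "B", 2: "A", 3: "B", 4: "B", 5: "B"}
    calls = call_interactions(fg, bg, mapping, alpha=0.05)
    assert [c.tf_pair for c in calls] == [("A", "B")]
    call = calls[0]
    assert call.frequency == 24                     # summed over filter pairs
    assert call.adj_p_value < 0.05 <= 1.0
    assert call.median_distance_bp == 18.0


def test_call_interactions_drops_uncharacterized():
    strong = list(np.linspace(0.5, 0.9, 12))
    weak = list(np.linspace(0.01, 0.05, 12))
    fg = {(0, 1): make_profile((0, 1), strong)}
    bg = {(0, 1): make_profile((0, 1), weak)}
    calls = call_interactions(fg, bg, {0: "A"}, alpha=0.05)
    assert calls == []


def test_call_interactions_requires_background():
    fg = {(0, 1): make_profile((0, 1), [0.5])}
    with pytest.raises(ValueError, match="background"):
        call_interactions(fg, {}, {0: "A", 1: "B"})


def test_interaction_call_invariant():
    with pytest.raises(ValueError):
        InteractionCall((0, 1), ("A", "B"), p_value=0.1, adj_p_value=0.05,
                        max_attention=0.5, frequency=1, median_distance_bp=6.0)


# ------------------------------------------------------------ family summary
def test_family_summary_single_call():
    calls = [InteractionCall((0, 1), ("A", "B"), 0.001, 0.01, 0.5, 3, 12.0)]
    table = family_summary(calls, {"A": "fam1", "B": "fam2"})
    assert len(table) == 1
    assert table.loc[0, "percent"] == 100.0


def test_family_summary_tally_oracle():
    def call(tf1, tf2):
        return InteractionCall((0, 1), (tf1, tf2), 0.001, 0.01, 0.5, 1, 6.0)

    calls = [call("A", "B"), call("C", "B"), call("A", "D"),
             call("B", "A"), call("C", "D")]
    fam = {"A": "f1", "B": "f2", "C": "f1", "D": "f2"}
    table = family_summary(calls, fam)
    counts = {(r.family1, r.family2): r.count for r in table.itertuples()}
    assert counts == {("f1", "f2"): 5}
    assert table["percent"].sum() <= 100.0 + 1e-9


# ------------------------------------------------------- overlap enrichment
def test_overlap_zero_known_pairs_gives_one():
    assert overlap_enrichment({("A", "B")}, set(), universe=10) == 1.0


def test_overlap_hypergeometric_enumeration_oracle():
    # N=10, K=3 known, n=4 predicted, overlap 2:
    # P(X >= 2) = [C(3,2) C(7,2) + C(3,3) C(7,1)] / C(10,4)
    predicted = {("p", str(i)) for i in range(2)} | {("k", "0"), ("k", "1")}
    known = {("k", "0"), ("k", "1"), ("k", "2")}
    expect = (math.comb(3, 2) * math.comb(7, 2)
              + math.comb(3, 3) * math.comb(7, 1)) / math.comb(10, 4)
    got = overlap_enrichment(predicted, known, universe=10)
    assert got == pytest.approx(expect, abs=1e-12)


def test_overlap_complete_containment_bounded():
    pairs = {("A", str(i)) for i in range(4)}
    assert overlap_enrichment(pairs, pairs, universe=4) == pytest.approx(1.0)


def test_overlap_unordered_canonicalization():
    assert overlap_enrichment({("B", "A")}, {("A", "B")}, universe=5) < 1.0
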