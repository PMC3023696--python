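import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssdraw.consensus import (
    ColumnConservation,
    PairClass,
    SequenceWeights,
    alignment_weights,
    classify_pair,
    column_conservation,
    compile_predicate,
    format_nt_range,
    format_percent,
    gsc_weights,
    modular_frequency,
    pairwise_identity_distances,
    upgma_tree,
    var_region_range,
)
from ssdraw.fixtures import FixtureSpec, generate_fixture
from ssdraw.stockholm_io import AnnotatedAlignment, StockholmError


def make_aln(rows, ss=None, labels=None, pk=None):
    n = len(rows[0])
    return AnnotatedAlignment(
        seq_names=[f"s{i}" for i in range(len(rows))],
        rows=list(rows),
        ss_cons=ss or "." * n,
        labels=labels or {},
        pk_lines=pk or {},
    )


def uniform(n):
    return SequenceWeights(np.full(n, 1.0 / n))


# ---------------------------------------------------------------------------
# distances and GSC weights


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        d = pairwise_identity_distances(make_aln(["ACGU", "ACGU"]))
        assert d[0, 1] == 0.0

    def test_half_matching(self):
        d = pairwise_identity_distances(make_aln(["AC", "AG"]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_no_shared_columns_is_distance_one(self):
        d = pairwise_identity_distances(make_aln(["A-", "-A"]))
        assert d[0, 1] == 1.0

    def test_gap_only_overlap_ignored(self):
        d = pairwise_identity_distances(make_aln(["AC-U", "AG-U"]))
        assert d[0, 1] == pytest.approx(1 / 3)


def brute_force_gsc(tree, n):
    """Independent path-sum: each edge's length split among its leaves."""
    raw = np.zeros(n)

    def edges(node, path):
        if node.leaf is not None:
            raw[node.leaf] = sum(length / under for length, under in path)
            return
        for child in node.children:
            edges(child, path + [(node.height - child.height, child.n_leaves)])

    edges(tree, [])
    total = raw.sum()
    return raw / total if total > 0 else np.full(n, 1.0 / n)


class TestGscWeights:
    def test_single_sequence_gets_weight_one(self):
        assert gsc_weights(np.zeros((1, 1))).weights.tolist() == [1.0]

    def test_two_identical_plus_one_distant(self):
        # A,B identical (d=0), C at distance 1: UPGMA heights {0, 0.5};
        # A and B each get 0.5/2 of the shared root edge, C gets 0.5 alone
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        w = gsc_weights(d).weights
        assert w == pytest.approx([0.25, 0.25, 0.5], abs=1e-12)

    def test_n_identical_sequences_share_equally(self):
        for n in (2, 3, 5):
            w = gsc_weights(np.zeros((n, n))).weights
            assert w == pytest.approx([1.0 / n] * n, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 1000), st.integers(2, 5))
    def test_matches_brute_force_path_sum_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.05, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        expected = brute_force_gsc(upgma_tree(d), n)
        assert gsc_weights(d).weights == pytest.approx(expected, abs=1e-9)

    def test_upgma_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(7)
        d = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma_tree(d)

        def heights(node, acc):
            if node.leaf is None:
                acc.append(node.height)
                for c in node.children:
                    heights(c, acc)
            return acc

        ours = sorted(heights(tree, []))
        theirs = sorted(h / 2 for h in linkage(squareform(d), "average")[:, 2])
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_weights_are_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 1.0, size=(5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = np.array([3, 0, 4, 1, 2])
        w = gsc_weights(d).weights
        w_perm = gsc_weights(d[np.ix_(perm, perm)]).weights
        assert w_perm == pytest.approx(w[perm], abs=1e-9)


# ---------------------------------------------------------------------------
# conservation tiers


class TestColumnConservation:
    def weighted_column(self, freqs):
        """Single-column alignment with one row per entry of freqs."""
        rows = [c for c, _ in freqs]
        w = np.array([f for _, f in freqs])
        return make_aln(rows), SequenceWeights(w / w.sum())

    def test_strong_identity_hits_top_tier(self):
        aln, w = self.weighted_column([("A", 0.98), ("G", 0.02)])
        cc = column_conservation(aln, w, 0)
        assert (cc.symbol, cc.identity_tier) == ("A", 97)

    def test_purine_class_with_strict_inequality(self):
        # 50% A + 40% G + 10% C: purine frequency 0.90 is NOT > 0.90
        aln, w = self.weighted_column([("A", 0.5), ("G", 0.4), ("C", 0.1)])
        cc = column_conservation(aln, w, 0)
        assert (cc.symbol, cc.identity_tier) == ("R", 75)

    def test_pyrimidine_class(self):
        aln, w = self.weighted_column([("C", 0.5), ("U", 0.45), ("G", 0.05)])
        cc = column_conservation(aln, w, 0)
        assert (cc.symbol, cc.identity_tier) == ("Y", 90)

    def test_all_gap_column_is_absent(self):
        cc = column_conservation(make_aln(["-", "-"]), uniform(2), 0)
        assert cc.symbol == "absent"
        assert not cc.shown

    def test_presence_only_tiers(self):
        # mixed identities, 80% of weight non-gap -> present at the 75 tier
        aln = make_aln(["A", "C", "G", "U", "-"])
        w = SequenceWeights(np.array([0.2, 0.2, 0.2, 0.2, 0.2]))
        cc = column_conservation(aln, w, 0)
        assert (cc.symbol, cc.presence_tier) == ("present", 75)

    def test_below_half_presence_not_shown(self):
        aln = make_aln(["A", "C", "-", "-", "-"])
        cc = column_conservation(aln, uniform(5), 0)
        assert cc.symbol == "absent"

    def test_identity_computed_among_nongap_rows(self):
        # 2 of 5 rows are gaps; among non-gaps A is 100%
        aln = make_aln(["A", "A", "A", "-", "-"])
        cc = column_conservation(aln, uniform(5), 0)
        assert (cc.symbol, cc.identity_tier, cc.presence_tier) == ("A", 97, 50)

    def test_thresholds_are_adjustable(self):
        aln, w = self.weighted_column([("A", 0.7), ("C", 0.3)])
        assert column_conservation(aln, w, 0).symbol != "A"
        cc = column_conservation(aln, w, 0, thresholds=(0.3, 0.6, 0.8, 0.95))
        assert (cc.symbol, cc.identity_tier) == ("A", 75)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.3))
    def test_tier_is_monotone_in_majority_frequency(self, f, bump):
        tiers = {None: 0, 75: 1, 90: 2, 97: 3}
        aln, _ = self.weighted_column([("A", 1.0), ("C", 1.0)])

        def tier_at(freq):
            w = SequenceWeights(np.array([freq, 1.0 - freq]))
            cc = column_conservation(aln, w, 0)
            return tiers[cc.identity_tier] if cc.symbol == "A" else -1

        hi = min(1.0, f + bump)
        assert tier_at(hi) >= tier_at(f)

    def test_invariants_of_the_result_type(self):
        with pytest.raises(ValueError):
            ColumnConservation("absent", presence_tier=50)
        with pytest.raises(ValueError):
            ColumnConservation("present", identity_tier=75)


# ---------------------------------------------------------------------------
# covariation classes


class TestClassifyPair:
    def paired(self, rows, weights=None):
        aln = make_aln(rows, ss="<>")
        w = weights or uniform(len(rows))
        return classify_pair(aln, w, 0, 1)

    def test_differing_at_both_positions_is_covarying(self):
        assert self.paired(["AU", "CG"]) is PairClass.COVARYING

    def test_differing_at_one_position_is_compatible(self):
        assert self.paired(["AU", "GU"]) is PairClass.COMPATIBLE

    def test_single_pair_type_is_invariant(self):
        assert self.paired(["GC", "GC", "GC"]) is PairClass.INVARIANT

    def test_noncanonical_above_ten_percent_is_unshaded(self):
        rows = ["AA"] * 15 + ["GC"] * 85
        assert self.paired(rows) is PairClass.UNSHADED

    def test_noncanonical_at_exactly_ten_percent_keeps_shading(self):
        rows = ["AA"] * 10 + ["GC"] * 90
        assert self.paired(rows) is PairClass.INVARIANT

    def test_gap_counts_as_noncanonical(self):
        rows = ["-U"] * 2 + ["AU"] * 8
        assert self.paired(rows) is PairClass.UNSHADED

    def test_covarying_found_even_with_compatible_pairs_present(self):
        assert self.paired(["AU", "GU", "GC"]) is PairClass.COVARYING

    def test_row_order_does_not_matter(self):
        rows = ["AU", "GC", "GU", "CG"]
        for perm in itertools.permutations(rows):
            assert self.paired(list(perm)) is PairClass.COVARYING

    def test_unannotated_columns_are_an_error(self):
        aln = make_aln(["AU"], ss="..")
        with pytest.raises(StockholmError, match="not an annotated pair"):
            classify_pair(aln, uniform(1), 0, 1)

    def test_pk_line_pairs_are_annotated(self):
        aln = make_aln(["AU", "GC"], ss="..", pk={"A": "<>"})
        assert classify_pair(aln, uniform(2), 0, 1) is PairClass.COVARYING


# ---------------------------------------------------------------------------
# duplication invariance ties weights to all downstream annotation


def test_duplicating_every_sequence_changes_nothing():
    aln = generate_fixture(
        FixtureSpec(template="hairpin", n_seqs=5, seed=9, covariation_rate=0.4)
    )
    doubled = make_aln(aln.rows + aln.rows, ss=aln.ss_cons)
    w1 = alignment_weights(aln)
    w2 = alignment_weights(doubled)
    for col in range(aln.n_cols):
        a = column_conservation(aln, w1, col)
        b = column_conservation(doubled, w2, col)
        assert (a.symbol, a.identity_tier, a.presence_tier) == (
            b.symbol,
            b.identity_tier,
            b.presence_tier,
        )
    for l, r in aln.pairs():
        assert classify_pair(aln, w1, l, r) is classify_pair(doubled, w2, l, r)


# ---------------------------------------------------------------------------
# modular structures and variable-length regions


class TestModular:
    def test_all_rows_match(self):
        aln = make_aln(["ACGU"] * 4)
        assert modular_frequency(aln, uniform(4), lambda i: True) == 1.0

    def test_31_percent_by_construction(self):
        rows = ["ACGU"] * 31 + ["AC-U"] * 69
        aln = make_aln(rows, labels={"x": 2})
        freq = modular_frequency(aln, uniform(100), "col:x=ACGU")
        assert freq == pytest.approx(0.31)
        assert format_percent(freq) == "31%"

    def test_no_rows_match(self):
        aln = make_aln(["ACGU"] * 4)
        assert modular_frequency(aln, uniform(4), "name:nomatch") == 0.0

    def test_unknown_label_is_an_error(self):
        aln = make_aln(["ACGU"])
        with pytest.raises(StockholmError, match="unknown column label"):
            modular_frequency(aln, uniform(1), "col:z=A")

    def test_boolean_combinations(self):
        aln = make_aln(["ACGU", "GCGU", "AC-U"], labels={"a": 0, "b": 2})
        pred = compile_predicate("col:a=A and not col:b=-", aln)
        assert [pred(i) for i in range(3)] == [True, False, False]
        pred = compile_predicate("( name:s1 or name:s2 ) and col:b=G", aln)
        assert [pred(i) for i in range(3)] == [False, True, False]


class TestVarRegionRange:
    def test_min_max_of_nongap_counts(self):
        aln = make_aln(["------", "AC-G--", "ACGUAC"])
        assert var_region_range(aln, (0, 6)) == (0, 6)
        assert format_nt_range(0, 6) == "0-6 nt"

    def test_constant_length_collapses_label(self):
        aln = make_aln(["ACG", "GGG"])
        assert var_region_range(aln, (0, 3)) == (3, 3)
        assert format_nt_range(3, 3) == "3 nt"

    def test_empty_range_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            var_region_range(make_aln(["ACG"]), (2, 2))
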