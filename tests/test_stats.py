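import io
import math
import random

import numpy as np
import obonet
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interomap import fixtures as F
from interomap import stats as ST

from .oracles import fisher_enumeration, mwu_enumeration


class TestOddsRatio:
    def test_printed_interacting_domain_example(self):
        res = ST.odds_ratio(ST.EnrichmentInput(1653, 2330, 125606, 282517))
        assert round(res.p1, 2) == 0.71
        assert round(res.p2, 2) == 0.44
        assert round(res.odds_ratio, 2) == 3.05

    def test_complementary_noninteracting_example(self):
        res = ST.odds_ratio(ST.EnrichmentInput(677, 2330, 156911, 282517))
        assert round(res.odds_ratio, 2) == 0.33

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=st.integers(1, 99), n=st.integers(100, 1000))
    def test_equal_fractions_give_unity(self, k, n):
        res = ST.odds_ratio(ST.EnrichmentInput(k, 100, k * n, 100 * n))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_degenerate_proportions_flagged(self):
        hi = ST.odds_ratio(ST.EnrichmentInput(10, 10, 5, 100), haldane=True)
        assert hi.degenerate and math.isinf(hi.odds_ratio)
        assert hi.haldane_odds_ratio > 0
        lo = ST.odds_ratio(ST.EnrichmentInput(0, 10, 5, 100))
        assert lo.degenerate and lo.odds_ratio == 0.0

    def test_zero_denominator_fails(self):
        with pytest.raises(ValueError):
            ST.EnrichmentInput(0, 0, 1, 2)


class TestFisherExact:
    def test_five_zero_zero_five_greater(self):
        # upper tail of the most extreme 5+5 table = 1/C(10,5)
        assert ST.fisher_exact(5, 0, 0, 5, "greater") == pytest.approx(1 / 252)

    def test_identical_row_proportions_two_sided(self):
        assert ST.fisher_exact(2, 2, 2, 2, "two") == pytest.approx(1.0)

    def test_matches_enumeration_on_random_tables(self):
        rng = random.Random(5)
        for _ in range(200):
            n = rng.randint(1, 60)
            a = rng.randint(0, n)
            b = rng.randint(0, n - a)
            c = rng.randint(0, n - a - b)
            d = n - a - b - c
            for sided in ("two", "greater"):
                assert ST.fisher_exact(a, b, c, d, sided) == pytest.approx(
                    fisher_enumeration(a, b, c, d, sided), abs=1e-10
                )

    def test_negative_counts_fail(self):
        with pytest.raises(ValueError):
            ST.fisher_exact(-1, 2, 3, 4)


class TestMannWhitneyU:
    def test_identical_samples_p_near_one(self):
        x = list(np.linspace(0, 1, 25))
        _, p = ST.mann_whitney_u(x, x, "two")
        assert p > 0.9

    def test_separated_triples_exact_tail(self):
        u, p = ST.mann_whitney_u([1, 2, 3], [4, 5, 6], "less")
        assert u == 0
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_exact_matches_full_enumeration(self):
        rng = random.Random(11)
        for nx_, ny in [(3, 3), (4, 5), (6, 6), (5, 7)]:
            pooled = rng.sample(range(1000), nx_ + ny)
            x = [v + rng.random() / 10 for v in pooled[:nx_]]
            y = [v + rng.random() / 10 for v in pooled[nx_:]]
            for sided in ("two", "greater", "less"):
                u, p = ST.mann_whitney_u(x, y, sided)
                u_o, p_o = mwu_enumeration(x, y, sided)
                assert u == pytest.approx(u_o)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        _, p_exact = ST.mann_whitney_u(x, y, "two")
        _, p_approx = ST.mann_whitney_u(x, y, "two", exact_max_n=1)
        assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_empty_sample_fails(self):
        with pytest.raises(ValueError):
            ST.mann_whitney_u([], [1.0])


def printed_ddg_records():
    """Records reproducing the published 2x2 counts (116/92/220/358)."""
    rows = []
    rng = random.Random(0)
    spec = [(116, True, 2.5), (92, False, 2.5), (220, True, 0.5), (358, False, 0.5)]
    for n, contacting, base in spec:
        for _ in range(n):
            rows.append(
                ST.DdgRecord("cx", "A", len(rows) + 1,
                             base + rng.random() * 0.4, contacting)
            )
    return rows


class TestDdgAnalysis:
    def test_reproduces_printed_fractions(self):
        d = ST.ddg_analysis(printed_ddg_records(), threshold=1.5)
        assert d.table == (116, 92, 220, 358)
        assert round(d.fraction_contacting_high, 2) == 0.56
        assert round(1 - d.fraction_contacting_high, 2) == 0.44
        assert round(d.fraction_contacting_low, 2) == 0.38

    def test_contacting_enriched_direction_and_significance(self):
        d = ST.ddg_analysis(printed_ddg_records(), threshold=1.5)
        assert d.fraction_contacting_high > d.fraction_contacting_low
        assert d.fisher_greater_p < 1e-4 and d.fisher_two_p < 1e-4
        assert d.utest_p < 0.01

    def test_all_below_threshold_gives_p_one(self):
        records = [
            ST.DdgRecord("c", "A", i + 1, 0.5, i % 2 == 0) for i in range(10)
        ]
        d = ST.ddg_analysis(records, threshold=1.5)
        assert d.table[:2] == (0, 0)
        assert d.fisher_greater_p == pytest.approx(1.0)

    def test_threshold_monotonicity(self):
        records = printed_ddg_records()
        highs = [
            sum(ST.ddg_analysis(records, t).table[:2]) for t in (0.4, 1.5, 2.6)
        ]
        assert highs == sorted(highs, reverse=True)

    def test_empty_class_fails(self):
        with pytest.raises(ValueError):
            ST.ddg_analysis([ST.DdgRecord("c", "A", 1, 1.0, True)] * 5)


@pytest.fixture(scope="module")
def go_dag():
    obo, _ = F.generate_go_fixture()
    return ST.GoDag(obonet.read_obo(io.StringIO(obo)), aspect="BP")


class TestRss:
    def test_identical_leaf_scores_one(self, go_dag):
        assert ST.rss_similarity({"GO:0000004"}, {"GO:0000004"}, go_dag).value == 1.0

    def test_root_only_common_ancestor_scores_zero(self, go_dag):
        # leaf a1 vs leaf b1 share only the root
        assert ST.rss_similarity({"GO:0000004"}, {"GO:0000006"}, go_dag).value == 0.0

    def test_hand_computed_values_on_fixture_dag(self, go_dag):
        # T4 vs T5: lca T2 (depth 1), distances 1+1 -> 1/3
        assert ST.rss_term_pair(go_dag, "GO:0000004", "GO:0000005") == pytest.approx(1 / 3)
        # T7 vs T5: lca T5 (depth 2), distances 1+0 -> 2/3
        assert ST.rss_term_pair(go_dag, "GO:0000007", "GO:0000005") == pytest.approx(2 / 3)
        # T7 vs T6: lca T6 (depth 2), distances 1+0 -> 2/3
        assert ST.rss_term_pair(go_dag, "GO:0000007", "GO:0000006") == pytest.approx(2 / 3)
        # protein-pair score takes the max over term pairs
        score = ST.rss_similarity({"GO:0000004", "GO:0000005"}, {"GO:0000007"}, go_dag)
        assert score.value == pytest.approx(2 / 3)

    def test_symmetry_and_bounds(self, go_dag):
        terms = list(go_dag.parents)
        for t1 in terms:
            for t2 in terms:
                v = ST.rss_term_pair(go_dag, t1, t2)
                assert 0.0 <= v <= 1.0
                assert v == pytest.approx(ST.rss_term_pair(go_dag, t2, t1))

    def test_unknown_terms_skipped_and_empty_flagged(self, go_dag):
        score = ST.rss_similarity({"GO:9999999"}, {"GO:0000004"}, go_dag)
        assert not score.defined


class TestCoexpression:
    def test_proportional_vectors_give_unit_correlation(self):
        expr = F.generate_expression_fixture(["g1"], 50, seed=1)
        expr.loc["g2"] = (expr.loc["g1"] + 1) ** 2 - 1  # log2(g2+1) = 2*log2(g1+1)
        out = ST.coexpression([("g1", "g2")], expr)
        assert out.mean_correlation == pytest.approx(1.0)

    def test_independent_vectors_low_mean_abs_correlation(self):
        genes = [f"g{i}" for i in range(40)]
        expr = F.generate_expression_fixture(genes, 200, seed=4)
        edges = [(genes[i], genes[i + 20]) for i in range(20)]
        out = ST.coexpression(edges, expr)
        assert abs(float(np.mean(np.abs(out.per_edge["r"])))) < 0.2

    def test_unmeasured_endpoint_counted_uncovered(self):
        expr = F.generate_expression_fixture(["g1", "g2"], 30, seed=2)
        out = ST.coexpression([("g1", "g2"), ("g1", "missing")], expr)
        assert out.n_computed == 1 and out.n_uncovered == 1

    def test_constant_vector_skipped(self):
        expr = F.generate_expression_fixture(["g1", "g2"], 30, seed=2)
        expr.loc["g2"] = 7.0
        out = ST.coexpression([("g1", "g2")], expr)
        assert out.n_skipped_constant == 1 and out.n_computed == 0

    def test_designed_correlation_recovered(self):
        expr = F.generate_expression_fixture(
            ["a", "b"], 500, correlated_pairs=[("a", "b", 0.9)], seed=9
        )
        out = ST.coexpression([("a", "b")], expr)
        assert out.mean_correlation == pytest.approx(0.9, abs=0.08)
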