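import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirdmap.enrichment import (
    ContingencyTable,
    adjust_pvalues,
    build_contingency,
    enrich,
    fisher_pvalue,
    odds_ratio,
)
from mirdmap.mapping import AssociationMap, build_db, merge_on_key
from mirdmap.synth import FixtureSpec, generate
from oracles import bh_textbook, bonferroni_textbook, exact_upper_tail, holm_textbook

tables = st.tuples(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
).filter(lambda t: sum(t) > 0)

pvectors = st.lists(
    st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=40
)


class TestContingency:
    def test_hand_count(self):
        db = build_db(
            AssociationMap(
                {
                    "m1": {"d"},
                    "m2": {"x"},
                    "m3": {"d"},
                    "m4": {"x"},
                    "m5": {"x"},
                }
            )
        )
        t = build_contingency(db, {"m1", "m2"}, "d")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 2)
        assert t.n == db.n_mirnas

    def test_degenerate_full_containment(self):
        db = build_db(AssociationMap({"m1": {"d"}, "m2": {"d"}}))
        t = build_contingency(db, {"m1", "m2"}, "d")
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 0)

    def test_random_instances_match_set_algebra(self, synthetic_db):
        rng = random.Random(3)
        mirnas = synthetic_db.mirnas()
        for _ in range(50):
            inp = set(rng.sample(mirnas, rng.randrange(1, 10)))
            d = rng.choice(synthetic_db.diseases())
            t = build_contingency(synthetic_db, inp, d)
            assoc = synthetic_db.inverse[d]
            others = set(mirnas) - inp
            assert t.a == len(inp & assoc)
            assert t.b == len(inp - assoc)
            assert t.c == len(others & assoc)
            assert t.d == len(others - assoc)

    def test_empty_input_rejected(self, tiny_db):
        with pytest.raises(ValueError):
            build_contingency(tiny_db, set(), "Asthma")


class TestFisher:
    def test_worked_example(self):
        p = fisher_pvalue(ContingencyTable(2, 1, 3, 14))
        assert p == pytest.approx(160 / 1140, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert fisher_pvalue(ContingencyTable(0, 3, 4, 10)) == pytest.approx(1.0)

    @given(tables)
    def test_matches_exact_enumeration(self, t):
        a, b, c, d = t
        assert fisher_pvalue(ContingencyTable(a, b, c, d)) == pytest.approx(
            exact_upper_tail(a, b, c, d), abs=1e-12
        )

    @given(tables.filter(lambda t: t[1] >= 1 and t[2] >= 1))
    def test_monotone_in_overlap_at_fixed_margins(self, t):
        a, b, c, d = t
        p_lo = fisher_pvalue(ContingencyTable(a, b, c, d))
        p_hi = fisher_pvalue(ContingencyTable(a + 1, b - 1, c - 1, d + 1))
        assert p_hi <= p_lo + 1e-12


class TestOddsRatio:
    def test_finite_value(self):
        assert odds_ratio(ContingencyTable(2, 1, 3, 14)) == pytest.approx(28 / 3)

    def test_containment_is_infinite(self):
        assert math.isinf(odds_ratio(ContingencyTable(3, 0, 2, 5)))

    def test_zero_and_undefined(self):
        assert odds_ratio(ContingencyTable(0, 2, 3, 4)) == 0.0
        assert math.isnan(odds_ratio(ContingencyTable(0, 2, 0, 4)))


class TestAdjustment:
    def test_bonferroni_example(self):
        assert adjust_pvalues([0.01, 0.2, 0.3, 0.4], "bonferroni")[0] == pytest.approx(0.04)

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )

    @given(pvectors)
    def test_matches_textbook_implementations(self, ps):
        np.testing.assert_allclose(
            adjust_pvalues(ps, "bonferroni"), bonferroni_textbook(ps), atol=1e-12
        )
        np.testing.assert_allclose(adjust_pvalues(ps, "holm"), holm_textbook(ps), atol=1e-12)
        np.testing.assert_allclose(adjust_pvalues(ps, "bh"), bh_textbook(ps), atol=1e-12)

    @given(pvectors)
    def test_holm_dominated_by_bonferroni_and_both_exceed_raw(self, ps):
        raw = np.asarray(ps)
        holm = adjust_pvalues(ps, "holm")
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        assert np.all(holm <= bonf + 1e-12)
        for q in (holm, bonf, bh):
            assert np.all(q >= raw - 1e-12)

    def test_invalid_pvalues_rejected(self):
        for bad in ([0.0, 0.5], [1.2], [float("nan")], []):
            with pytest.raises(ValueError):
                adjust_pvalues(bad)


class TestEnrich:
    def test_planted_containment_ranks_first_with_inf_or(self):
        mg, gd, truth = generate(FixtureSpec(enriched_query_size=4, seed=17))
        merged, _ = merge_on_key(mg, gd)
        db = build_db(merged)
        top = enrich(db, list(truth.enriched_query), alpha=1.0)[0]
        assert top.target == truth.enriched_disease
        assert top.table.b == 0
        assert math.isinf(top.odds_ratio)
        assert math.isinf(top.log2_odds_ratio)

    def test_alpha_one_returns_every_disease(self, synthetic_db):
        recs = enrich(synthetic_db, synthetic_db.mirnas()[:3], alpha=1.0, method="bonferroni")
        assert len(recs) == synthetic_db.n_diseases

    def test_smaller_alpha_is_prefix_of_full_ranking(self, synthetic_db):
        query = synthetic_db.mirnas()[:4]
        full = enrich(synthetic_db, query, alpha=1.0)
        part = enrich(synthetic_db, query, alpha=0.4)
        assert [r.target for r in part] == [r.target for r in full[: len(part)]]
        assert all(r.q <= 0.4 for r in part)

    def test_input_order_and_duplicates_irrelevant(self, synthetic_db):
        query = synthetic_db.mirnas()[:5]
        a = enrich(synthetic_db, query, alpha=1.0)
        b = enrich(synthetic_db, list(reversed(query)) + query[:2], alpha=1.0)
        assert a == b

    def test_case_insensitive_resolution_with_warning_for_rejects(self, synthetic_db):
        query = [synthetic_db.mirnas()[0].upper(), "not-a-mirna"]
        recs = enrich(synthetic_db, query, alpha=1.0)
        assert len(recs) == synthetic_db.n_diseases
        assert all(r.table.a + r.table.b == 1 for r in recs)

    def test_all_unknown_input_is_hard_error(self, synthetic_db):
        with pytest.raises(ValueError, match="nope-1"):
            enrich(synthetic_db, ["nope-1", "nope-2"])

    def test_q_never_below_p(self, synthetic_db):
        for method in ("bh", "holm", "bonferroni"):
            recs = enrich(synthetic_db, synthetic_db.mirnas()[:4], alpha=1.0, method=method)
            assert all(r.q >= r.p - 1e-12 for r in recs)
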