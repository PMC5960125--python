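"""Fisher model, query model and query parsing against independent oracles."""

import random
from fractions import Fraction
from math import comb

import pytest
from scipy.stats import fisher_exact as scipy_fisher

from cnvassoc import (
    ContingencyTable,
    Predicate,
    Query,
    evaluate_predicate,
    fisher_exact_two_sided,
    parse_query,
    run_query_model,
    run_statistical_model,
    segment_regions,
)

from conftest import make_dataset, random_cohort


def fisher_oracle(a, b, c, d):
    """Exact rational minimum-likelihood two-sided Fisher p-value."""
    n1, n2, col, n = a + b, c + d, a + c, a + b + c + d
    def point(x):
        return Fraction(comb(n1, x) * comb(n2, col - x), comb(n, col))
    p_obs = point(a)
    total = sum(
        point(x)
        for x in range(max(0, col - n2), min(col, n1) + 1)
        if point(x) <= p_obs
    )
    return float(min(1, total))


class TestFisher:
    def test_printed_cohort_values(self):
        # 14 vs 27 samples; 3 vs 0 carriers and 4 vs 1 carriers
        assert fisher_exact_two_sided(ContingencyTable(3, 11, 0, 27)) == pytest.approx(
            0.0341, abs=5e-5
        )
        assert fisher_exact_two_sided(ContingencyTable(4, 10, 1, 26)) == pytest.approx(
            0.0387, abs=5e-5
        )

    def test_no_events_single_table(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 14, 0, 27)) == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exact_rational_enumeration(self, seed):
        rng = random.Random(seed)
        n1, n2 = rng.randint(1, 30), rng.randint(1, 30)
        a, c = rng.randint(0, n1), rng.randint(0, n2)
        table = ContingencyTable(a, n1 - a, c, n2 - c)
        assert fisher_exact_two_sided(table) == pytest.approx(
            fisher_oracle(a, n1 - a, c, n2 - c), rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy(self, seed):
        rng = random.Random(1000 + seed)
        a, b, c, d = (rng.randint(0, 25) for _ in range(4))
        if a + b == 0 or c + d == 0:
            pytest.skip("degenerate margin")
        ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        theirs = scipy_fisher([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)

    def test_symmetric_under_simultaneous_swaps(self):
        rng = random.Random(5)
        for _ in range(30):
            a, b, c, d = (rng.randint(0, 15) for _ in range(4))
            if a + b == 0 or c + d == 0:
                continue
            p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(
                fisher_exact_two_sided(ContingencyTable(c, d, a, b)), rel=1e-9
            )
            assert p == pytest.approx(
                fisher_exact_two_sided(ContingencyTable(b, a, d, c)), rel=1e-9
            )


def cohort_with_carriers(n1_carriers, n1, n2_carriers, n2, state="Loss"):
    calls = [(f"P{i}", "chr1", 100, 200, state) for i in range(n1_carriers)]
    calls += [(f"N{i}", "chr1", 100, 200, state) for i in range(n2_carriers)]
    return make_dataset(
        calls, [f"P{i}" for i in range(n1)], [f"N{i}" for i in range(n2)]
    )


class TestStatisticalModel:
    def test_reports_loss_region_below_threshold(self):
        ds = cohort_with_carriers(3, 14, 0, 27)
        results = run_statistical_model(segment_regions(ds), ds, p_threshold=0.05)
        assert len(results) == 1
        r = results[0]
        assert r.event_type == "Loss"
        assert r.p_value == pytest.approx(0.0341, abs=5e-5)
        assert r.group1_freq["Loss"] == (pytest.approx(3 / 14), pytest.approx(3 / 14))

    def test_stricter_threshold_drops_region(self):
        ds = cohort_with_carriers(3, 14, 0, 27)
        assert run_statistical_model(segment_regions(ds), ds, p_threshold=0.01) == []

    def test_each_event_type_reported_separately(self):
        calls = [(f"P{i}", "chr1", 100, 200, "Gain") for i in range(4)]
        calls += [(f"P{i}", "chr1", 100, 200, "LOH") for i in range(4)]
        calls += [("N0", "chr1", 100, 200, "Gain"), ("N1", "chr1", 100, 200, "LOH")]
        ds = make_dataset(
            calls, [f"P{i}" for i in range(14)], [f"N{i}" for i in range(27)]
        )
        results = run_statistical_model(segment_regions(ds), ds, p_threshold=0.05)
        assert sorted(r.event_type for r in results) == ["Gain", "LOH"]
        for r in results:
            assert r.p_value == pytest.approx(0.0387, abs=5e-5)


class TestPredicates:
    def test_gain_fraction_meets_threshold(self):
        sets = [frozenset({"Gain"})] * 3 + [frozenset()] * 11
        assert evaluate_predicate(Predicate("ge", 0.2, "eq", "Gain"), sets)

    def test_mostly_normal_group_matches_ne_normal_cap(self):
        sets = [frozenset({"Loss"})] + [frozenset()] * 26
        assert evaluate_predicate(Predicate("le", 0.1, "ne", "Normal"), sets)

    def test_zero_threshold_ge_always_true(self):
        sets = [frozenset()] * 5
        assert evaluate_predicate(Predicate("ge", 0.0, "eq", "Loss"), sets)

    def test_full_threshold_requires_every_sample(self):
        pred = Predicate("ge", 1.0, "eq", "Gain")
        assert evaluate_predicate(pred, [frozenset({"Gain"})] * 3)
        assert not evaluate_predicate(pred, [frozenset({"Gain"})] * 2 + [frozenset()])

    def test_threshold_above_one_rejected(self):
        with pytest.raises(ValueError):
            Predicate("ge", 1.01, "eq", "Gain")


def naive_query_eval(regions, dataset, query):
    """Per-region, per-sample re-evaluation, independent of the model code."""
    hits = []
    for region in regions:
        ok = True
        for pred, group in ((query.p1, dataset.group1_samples),
                            (query.p2, dataset.group2_samples)):
            n_match = 0
            for s in group:
                states = region.states_of(s)
                if pred.state == "Normal":
                    is_match = len(states) == 0
                else:
                    is_match = pred.state in states
                if pred.match == "ne":
                    is_match = not is_match
                n_match += is_match
            f = Fraction(n_match, len(group))
            R = Fraction(pred.threshold).limit_denominator(10**6)
            if pred.cmp == "ge" and not f >= R:
                ok = False
            if pred.cmp == "le" and not f <= R:
                ok = False
        if ok:
            hits.append((region.chromosome, region.start, region.end))
    return hits


def random_predicate(rng):
    return Predicate(
        rng.choice(["ge", "le"]),
        rng.choice([0.0, 0.1, 0.2, 0.25, 0.4, 0.5, 0.6, 0.75, 0.9, 1.0]),
        rng.choice(["eq", "ne"]),
        rng.choice(["Normal", "Gain", "Loss", "LOH"]),
    )


class TestQueryModel:
    @pytest.mark.parametrize("seed", range(60))
    def test_matches_naive_reevaluation(self, seed):
        rng = random.Random(seed)
        ds = random_cohort(rng)
        regions = segment_regions(ds)
        query = Query(random_predicate(rng), random_predicate(rng))
        got = [(r.chromosome, r.start, r.end) for r in run_query_model(regions, ds, query)]
        assert got == naive_query_eval(regions, ds, query)

    def test_always_true_query_matches_every_region(self):
        rng = random.Random(42)
        ds = random_cohort(rng)
        regions = segment_regions(ds)
        query = Query(Predicate("ge", 0.0, "eq", "Gain"), Predicate("ge", 0.0, "eq", "Gain"))
        assert len(run_query_model(regions, ds, query)) == len(regions)

    def test_tightening_thresholds_never_adds_regions(self):
        rng = random.Random(11)
        for _ in range(10):
            ds = random_cohort(rng)
            regions = segment_regions(ds)
            loose = Query(Predicate("ge", 0.2, "eq", "Loss"), Predicate("le", 0.5, "eq", "Loss"))
            tight = Query(Predicate("ge", 0.6, "eq", "Loss"), Predicate("le", 0.2, "eq", "Loss"))
            loose_hits = {(r.start, r.end, r.chromosome) for r in run_query_model(regions, ds, loose)}
            tight_hits = {(r.start, r.end, r.chromosome) for r in run_query_model(regions, ds, tight)}
            assert tight_hits <= loose_hits

    def test_query_results_carry_no_type_or_p(self):
        ds = cohort_with_carriers(5, 10, 0, 10, state="Gain")
        query = Query(Predicate("ge", 0.2, "eq", "Gain"), Predicate("le", 0.1, "ne", "Normal"))
        results = run_query_model(segment_regions(ds), ds, query)
        assert results
        assert all(r.event_type is None and r.p_value is None for r in results)


class TestParseQuery:
    def test_example_query_text(self):
        q = parse_query("group1 ge 0.2 eq gain; group2 le 0.1 ne normal")
        assert q.p1 == Predicate("ge", 0.2, "eq", "Gain")
        assert q.p2 == Predicate("le", 0.1, "ne", "Normal")

    def test_clause_order_is_by_group_name(self):
        q = parse_query("group2 le 0.1 ne normal; group1 ge 0.2 eq gain")
        assert q.p1.state == "Gain"
        assert q.p2.state == "Normal"

    @pytest.mark.parametrize("text", [
        "group1 ge 1.5 eq gain; group2 le 0.1 ne normal",   # out of range
        "group1 ge 0.2 eq gain",                            # missing clause
        "group1 ge 0.2 eq amplification; group2 le 0.1 ne normal",  # bad state
        "group1 ge 0.2 eq gain; group1 le 0.1 ne normal",   # same group twice
        "group1 gt 0.2 eq gain; group2 le 0.1 ne normal",   # bad comparator
    ])
    def test_rejects_malformed_queries(self, text):
        with pytest.raises(ValueError):
            parse_query(text)
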