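import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import constru as cs
from constru import (
    ConstruError,
    constru_scan,
    correlation_filter,
    parity_score,
    percentile_rank,
    select_candidates,
    tertile_split,
)
from constru.core import ConstruRecord, ConstruTable

from conftest import cytscore_of, scan_genes


class TestTertileSplit:
    def test_exact_thirds(self):
        labels = tertile_split(np.arange(1, 10)).labels
        assert labels.tolist() == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_n10_sizes_from_floor_rule(self):
        # rank r of n=10 -> floor(3r/10): ranks 0-3 -> T1, 4-6 -> T2, 7-9 -> T3
        tert = tertile_split(np.arange(10, 0, -1))
        assert tert.sizes() == {"T1": 4, "T2": 3, "T3": 3}

    def test_ties_follow_input_order(self):
        tert = tertile_split(np.zeros(9))
        assert tert.labels.tolist() == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_too_few_samples(self):
        with pytest.raises(ConstruError):
            tertile_split([1, 2, 3, 4, 5])

    @given(st.integers(min_value=6, max_value=400), st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_sizes_differ_by_at_most_one(self, n, rnd):
        values = np.array([rnd.random() for _ in range(n)])
        sizes = tertile_split(values).sizes()
        assert sum(sizes.values()) == n
        assert max(sizes.values()) - min(sizes.values()) <= 1

    def test_boundaries_bracket_middle_tertile(self):
        v = np.arange(12, dtype=float)
        tert = tertile_split(v)
        b1, b2 = tert.boundaries
        mid = v[tert.mask("T2")]
        assert mid.min() == b1 and b2 > mid.max()


class TestParityScore:
    def test_direct_arithmetic(self):
        assert parity_score(1e-3, 0.5, 0.5, 1.0) == pytest.approx(5.6989700043, abs=1e-10)

    def test_identical_tertiles_give_zero(self):
        assert parity_score(0.01, 0.7, 0.01, 0.7) == 0.0

    def test_uppert_type_gene_negative(self):
        assert parity_score(1.0, 1.0, 1e-4, 0.5) == pytest.approx(-8.0)

    @given(st.floats(1e-12, 1.0), st.floats(0.05, 20), st.floats(1e-12, 1.0), st.floats(0.05, 20))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, p1, h1, p3, h3):
        assert parity_score(p1, h1, p3, h3) == pytest.approx(-parity_score(p3, h3, p1, h1), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(p_t1=0.0, hr_t1=1, p_t3=0.5, hr_t3=1),
        dict(p_t1=0.5, hr_t1=-1, p_t3=0.5, hr_t3=1),
        dict(p_t1=0.5, hr_t1=1, p_t3=1.5, hr_t3=1),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ConstruError):
            parity_score(**bad)


class TestPercentileRank:
    def test_even_spacing(self):
        assert percentile_rank([1, 2, 3, 4, 5]).tolist() == [0, 25, 50, 75, 100]

    def test_tie_average(self):
        assert percentile_rank([2, 2]).tolist() == [50, 50]

    def test_order_independence(self):
        assert percentile_rank([5, 1]).tolist() == [100, 0]

    def test_missing_rejected(self):
        with pytest.raises(ConstruError):
            percentile_rank([np.nan, np.nan])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_spans_range(self, values):
        pct = percentile_rank(values)
        order = np.argsort(values)
        assert (np.diff(pct[order]) >= 0).all()
        assert pct.min() == 0.0 and pct.max() == 100.0


def make_table(gene_stats, cohort="c"):
    """gene_stats: {gene: (parity, cyt_r)}; tertile fits marked converged."""
    records = []
    for g, (parity, r) in gene_stats.items():
        rec = ConstruRecord(gene=g, cyt_correlation=r, parity=parity)
        for t in ("T1", "T2", "T3"):
            rec.tertile_stats[t] = {"hr": 1.0, "p": 0.5, "n": 10, "n_events": 5, "converged": True}
        records.append(rec)
    table = ConstruTable(cohort_name=cohort, score_name="s", covariates=[], records=records)
    from constru.core import _rank_records
    _rank_records(records)
    return table


class TestCorrelationFilter:
    def test_perfectly_correlated_gene_filtered(self):
        table = make_table({"A": (0.0, 1.0), "B": (1.0, 0.0), "C": (2.0, 0.05)})
        out = correlation_filter(table)
        assert out.record("A").filtered_reason == "score-correlated"

    def test_below_threshold_retained(self):
        out = correlation_filter(make_table({"A": (0.0, 0.10), "B": (1.0, 0.0)}))
        assert not out.record("A").filtered

    def test_negative_beyond_threshold_filtered(self):
        out = correlation_filter(make_table({"A": (0.0, -0.16), "B": (1.0, 0.0)}))
        assert out.record("A").filtered_reason == "score-correlated"

    def test_exact_threshold_retained(self):
        # the exclusion rule is strict: > 0.15 or < -0.15
        out = correlation_filter(make_table({"A": (0.0, 0.15), "B": (1.0, -0.15)}))
        assert not out.record("A").filtered and not out.record("B").filtered

    def test_ranks_recomputed_over_survivors(self):
        table = make_table({"A": (0.0, 0.9), "B": (1.0, 0.0), "C": (2.0, 0.0), "D": (3.0, 0.0)})
        out = correlation_filter(table)
        assert np.isnan(out.record("A").parity_percentile)
        assert out.ranked_genes().tolist() == [0.0, 50.0, 100.0]

    def test_invalid_threshold(self):
        with pytest.raises(ConstruError):
            correlation_filter(make_table({"A": (0.0, 0.0), "B": (1.0, 0.0)}), threshold=1.5)


class TestSelectCandidates:
    def table_from_pct(self, pct, cohort):
        # build records whose ranking reproduces the given percentiles
        table = make_table({g: (p, 0.0) for g, p in pct.items()}, cohort)
        for rec in table.records:
            rec.parity_percentile = pct[rec.gene]
        return table

    def test_intersection_rule(self):
        t1 = self.table_from_pct({"X": 1, "Y": 1, "Z": 50}, "a")
        t2 = self.table_from_pct({"X": 1, "Y": 50, "Z": 50}, "b")
        cand = select_candidates([t1, t2], 4)
        assert cand.upperT_genes == {"X"}

    def test_no_shared_extremes_gives_empty_sets(self):
        t1 = self.table_from_pct({"X": 30, "Y": 60}, "a")
        t2 = self.table_from_pct({"X": 70, "Y": 40}, "b")
        cand = select_candidates([t1, t2], 4)
        assert cand.upperT_genes == set() and cand.lowerT_genes == set()

    def test_lowert_selected_at_high_percentiles(self):
        t1 = self.table_from_pct({"X": 99, "Y": 98, "Z": 10}, "a")
        t2 = self.table_from_pct({"X": 97, "Y": 50, "Z": 10}, "b")
        cand = select_candidates([t1, t2], 4)
        assert cand.lowerT_genes == {"X"}

    def test_single_table_rejected(self):
        t1 = self.table_from_pct({"X": 1}, "a")
        with pytest.raises(ConstruError):
            select_candidates([t1], 4)

    def test_cutoff_nesting(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(100)]
        t1 = self.table_from_pct(dict(zip(genes, rng.permutation(100))), "a")
        t2 = self.table_from_pct(dict(zip(genes, rng.permutation(100))), "b")
        sets = {c: select_candidates([t1, t2], c) for c in (2, 4, 6)}
        assert sets[2].upperT_genes <= sets[4].upperT_genes <= sets[6].upperT_genes
        assert sets[2].lowerT_genes <= sets[4].lowerT_genes <= sets[6].lowerT_genes


class TestConstruScan:
    def test_planted_gene_shows_t3_effect(self, planted_spec, planted_scan):
        g = cs.planted_gene_names(planted_spec)[0]
        rec = planted_scan.record(g)
        assert rec.tertile_stats["T3"]["p"] < rec.tertile_stats["T1"]["p"]
        assert rec.tertile_stats["T3"]["hr"] < 1.0

    def test_constant_gene_flagged(self, small_cohort):
        cohort = small_cohort
        expr = cohort.expr.data.copy()
        expr.loc["GENE0001"] = 5.0
        flat = cs.Cohort(cs.ExpressionMatrix(expr), cohort.clinical, cohort.name)
        table = constru_scan(flat, cytscore_of(cohort), genes=["GENE0001", "GENE0002"])
        assert table.record("GENE0001").filtered_reason == "constant"
        assert table.record("GENE0001").tertile_stats == {}

    def test_all_missing_age_dropped_from_models(self, small_cohort):
        clin = small_cohort.clinical.data.copy()
        clin["age"] = np.nan
        cohort = cs.Cohort(small_cohort.expr, cs.ClinicalTable(clin), "no-age")
        table = constru_scan(cohort, cytscore_of(small_cohort), genes=["GENE0001"])
        assert "age" not in table.covariates
        assert table.record("GENE0001").estimable

    def test_scan_deterministic(self, small_cohort):
        genes = scan_genes(small_cohort)[:20]
        score = cytscore_of(small_cohort)
        a = constru_scan(small_cohort, score, genes=genes).to_frame()
        b = constru_scan(small_cohort, score, genes=genes).to_frame()
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_percentiles_cover_unfiltered_records(self, planted_scan):
        ranked = planted_scan.ranked_genes()
        assert ranked.min() == 0.0 and ranked.max() == 100.0
        for rec in planted_scan.records:
            if rec.filtered:
                assert np.isnan(rec.parity_percentile)

    def test_tsv_roundtrip_columns(self, planted_scan, tmp_path):
        path = tmp_path / "table.tsv"
        planted_scan.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        expected = {"gene", "t1_hr", "t1_p", "t1_n", "t1_events", "t2_hr", "t3_hr",
                    "interaction_hr", "interaction_p", "cyt_r", "parity",
                    "parity_percentile", "filtered_reason"}
        assert expected <= set(df.columns)
        assert len(df) == len(planted_scan.records)
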