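import numpy as np
import pytest

from litscape.pubmed_corpus import PublicationRecord
from litscape.topic_net import TopicAssignment
from litscape.trends import (
    annual_counts,
    avg_growth_rate,
    cagr,
    country_shares,
    emerging_terms,
    linear_trend,
    mean_annual,
    mesh_term_trends,
    proportion,
    top_k_share,
    topic_year_heatmap,
)


def _rec(pmid, year, mesh=(), country=None, pub_types=("Journal Article",)):
    return PublicationRecord(
        pmid=str(pmid),
        title="t",
        year=year,
        mesh_terms=list(mesh),
        country=country,
        pub_types=list(pub_types),
    )


class TestAnnualCounts:
    def test_empty_zero_filled(self):
        counts = annual_counts([], (2000, 2003))
        assert list(counts.index) == [2000, 2001, 2002, 2003]
        assert counts.sum() == 0

    def test_matches_generator_sizes(self, small_corpus_pair):
        records, truth = small_corpus_pair
        counts = annual_counts(records, (1996, 2021))
        for year in counts.index:
            assert counts[year] == int((truth.years == year).sum())
        assert counts[::-1].sum() == counts.sum()  # permutation invariant

    def test_out_of_window_dropped(self):
        counts = annual_counts([_rec(1, 1990), _rec(2, 2001)], (2000, 2002))
        assert counts.sum() == 1


class TestArithmetic:
    def test_mean_annual_truncates(self):
        assert mean_annual(60_296, 25) == 2_411
        assert mean_annual(100, 4) == 25
        assert mean_annual(7, 2) == 3
        with pytest.raises(ValueError):
            mean_annual(10, 0)

    def test_growth_rate(self):
        assert avg_growth_rate([100, 100, 100]) == pytest.approx(0.0)
        assert avg_growth_rate([100, 110]) == pytest.approx(10.0)
        series = [120, 90, 180, 200]
        expected = np.mean(
            [(90 - 120) / 120 * 100, (180 - 90) / 90 * 100, (200 - 180) / 180 * 100]
        )
        assert avg_growth_rate(series) == pytest.approx(expected)
        with pytest.raises(ValueError):
            avg_growth_rate([100, 0, 50])
        with pytest.raises(ValueError):
            avg_growth_rate([5])

    def test_cagr(self):
        assert cagr([100, 110, 121]) == pytest.approx(10.0, abs=1e-9)

    def test_linear_trend(self):
        assert linear_trend([1, 2, 3]) == pytest.approx(1.0)
        assert linear_trend([4, 4, 4, 4]) == pytest.approx(0.0)
        # closed-form OLS slope on a small series
        y = np.array([3.0, 5.0, 4.0, 8.0])
        x = np.arange(4.0)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert linear_trend(y) == pytest.approx(slope)

    def test_proportion_reported_values(self):
        assert proportion(37, 118, 1) == 31.4
        assert proportion(21, 90, 1) == 23.3
        assert proportion(0, 50, 1) == 0.0

    def test_proportion_half_away_from_zero(self):
        assert proportion(1, 8, 1) == 12.5
        assert proportion(1, 800, 1) == 0.1  # 0.125 -> 0.1
        assert proportion(5, 4000, 1) == 0.1  # 0.125% rounds half-up
        with pytest.raises(ValueError):
            proportion(5, 0)
        with pytest.raises(ValueError):
            proportion(6, 5)


class TestMeshTrends:
    WINDOW = (2000, 2004)

    @pytest.fixture
    def records(self):
        return [
            _rec(1, 2000, mesh=["Pathology"]),
            _rec(2, 2001, mesh=["Pathology", "MicroRNAs"]),
            _rec(3, 2002, mesh=["MicroRNAs"]),
            _rec(4, 2002, mesh=[]),
            _rec(5, 2003, mesh=["MicroRNAs", "Pathology"]),
        ]

    def test_counts_and_first_year(self, records):
        trends = mesh_term_trends(records, window=self.WINDOW)
        assert trends.counts.loc["Pathology", 2000] == 1
        assert trends.counts.loc["MicroRNAs"].sum() == 3
        assert trends.first_year == {"Pathology": 2000, "MicroRNAs": 2001}

    def test_absent_term_zero_series(self, records):
        trends = mesh_term_trends(records, terms=["KRAS"], window=self.WINDOW)
        assert trends.counts.loc["KRAS"].sum() == 0
        assert "KRAS" not in trends.first_year

    def test_proportions_per_year(self, records):
        trends = mesh_term_trends(records, window=self.WINDOW)
        # 2002: two publications, one carries MicroRNAs
        assert trends.proportions.loc["MicroRNAs", 2002] == pytest.approx(50.0)

    def test_total_occurrence_tally(self, small_corpus_pair):
        records, _ = small_corpus_pair
        trends = mesh_term_trends(records, window=(1996, 2021))
        per_year_sum = trends.counts.sum(axis=0)
        for year in per_year_sum.index:
            expected = sum(
                len(r.mesh_terms) for r in records if r.year == year
            )
            assert per_year_sum[year] == expected

    def test_emergence_years_recovered(self, small_corpus_pair):
        records, truth = small_corpus_pair
        trends = mesh_term_trends(records, window=(1996, 2021))
        for term, spec in truth.mesh_terms.items():
            if term in trends.first_year:
                assert trends.first_year[term] == spec.emergence_year

    def test_pub_type_categories_reuse(self):
        records = [
            _rec(1, 2000, pub_types=["Clinical Trial"]),
            _rec(2, 2000, pub_types=["Clinical Trial", "Multicenter Study"]),
            _rec(3, 2001, pub_types=["Review"]),
        ]
        trends = mesh_term_trends(
            records, window=(2000, 2001), attribute="pub_types"
        )
        assert trends.counts.loc["Clinical Trial", 2000] == 2
        assert trends.counts.loc["Multicenter Study"].sum() == 1


class TestEmergingTerms:
    def test_all_baseline_terms_empty(self):
        records = [_rec(1, 1996, mesh=["A", "B"])]
        trends = mesh_term_trends(records, window=(1996, 2000))
        assert emerging_terms(trends, 1996) == []

    def test_planted_late_terms_found_sorted(self):
        records = (
            [_rec(i, 1996, mesh=["Old"]) for i in range(3)]
            + [_rec(10 + i, 2006, mesh=["MicroRNAs"]) for i in range(5)]
            + [_rec(20 + i, 2010, mesh=["Tumor Microenvironment"]) for i in range(2)]
            + [_rec(30, 2010, mesh=["Aardvark"]), _rec(31, 2011, mesh=["Zebra"])]
        )
        trends = mesh_term_trends(records, window=(1996, 2012))
        got = emerging_terms(trends, 1996)
        assert got == ["MicroRNAs", "Tumor Microenvironment", "Aardvark", "Zebra"]


class TestCountryShares:
    def test_single_country(self):
        records = [_rec(i, 2000, country="Japan") for i in range(4)]
        shares = country_shares(records)
        assert shares.iloc[0]["country"] == "Japan"
        assert shares.iloc[0]["percentage"] == 100.0

    def test_unknown_in_denominator_not_ranking(self):
        records = [_rec(1, 2000, country="Japan")] + [
            _rec(i, 2000, country="Unknown") for i in range(2, 5)
        ]
        shares = country_shares(records)
        assert list(shares["country"]) == ["Japan"]
        assert shares.iloc[0]["percentage"] == 25.0
        assert shares.attrs["unknown"] == 3

    def test_generator_shares_recovered(self, small_corpus_pair):
        records, truth = small_corpus_pair
        shares = country_shares(records)
        total = len(records)
        for _, row in shares.iterrows():
            configured = truth.countries.count(row["country"])
            assert row["count"] == configured
            assert row["percentage"] == proportion(configured, total, 1)

    def test_top_k_share(self):
        records = [_rec(1, 2000, country="Japan"), _rec(2, 2000, country="France")]
        shares = country_shares(records)
        assert top_k_share(shares, 2) == 100.0
        assert top_k_share(shares, 1) == 50.0


class TestHeatmap:
    def test_single_cell(self):
        assignments = [TopicAssignment(str(i), 2, 0, 0.9, 0.1) for i in range(7)]
        mat = topic_year_heatmap(assignments, [2005] * 7, (2004, 2006), n_topics=4)
        assert mat.loc[2, 2005] == 7
        assert mat.values.sum() == 7

    def test_empty(self):
        mat = topic_year_heatmap([], [], (2000, 2001), n_topics=2)
        assert mat.values.sum() == 0

    def test_marginals_match_tallies(self, rng):
        n = 120
        assignments = [
            TopicAssignment(str(i), int(rng.integers(0, 5)), 5, 0.8, 0.1)
            for i in range(n)
        ]
        years = [int(rng.integers(2000, 2005)) for _ in range(n)]
        mat = topic_year_heatmap(assignments, years, (2000, 2004), n_topics=6)
        assert mat.values.sum() == n
        for k in range(6):
            assert mat.loc[k].sum() == sum(
                1 for a in assignments if a.primary_topic == k
            )
        for y in range(2000, 2005):
            assert mat[y].sum() == years.count(y)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            topic_year_heatmap([], [2000], (2000, 2001))
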