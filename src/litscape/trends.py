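"""Publication, category, MeSH-term, country and topic trend analytics.

All per-year tallies are returned as pandas objects whose columns span the
full, contiguous analysis window (zero-filled), so downstream consumers never
have to guess which years are missing.  Percentages use half-away-from-zero
rounding via exact decimal arithmetic, matching how shares are conventionally
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pubmed_corpus import UNKNOWN_COUNTRY, PublicationRecord, resolve_country
from .topic_net import TopicAssignment

__all__ = [
    "annual_counts",
    "mean_annual",
    "avg_growth_rate",
    "cagr",
    "linear_trend",
    "proportion",
    "MeshTrends",
    "mesh_term_trends",
    "emerging_terms",
    "country_shares",
    "top_k_share",
    "topic_year_heatmap",
]


def _year_index(window: tuple[int, int]) -> range:
    start, end = window
    if end < start:
        raise ValueError("window end before start")
    return range(start, end + 1)


def annual_counts(
    records: Sequence[PublicationRecord], window: tuple[int, int]
) -> pd.Series:
    """Publications per year over the window, zero-filled."""
    years = _year_index(window)
    counts = pd.Series(0, index=pd.Index(years, name="year"), dtype=int)
    for rec in records:
        if window[0] <= rec.year <= window[1]:
            counts[rec.year] += 1
    return counts


def mean_annual(total: int, span_years: int) -> int:
    """Integer mean publications/year, truncated (floor) as reported."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    return total // span_years


def avg_growth_rate(series: Sequence[float]) -> float:
    """Arithmetic mean of year-over-year percentage changes."""
    values = list(series)
    if len(values) < 2:
        raise ValueError("need at least two values")
    if values[0] <= 0:
        raise ValueError("first value must be > 0")
    changes = []
    for prev, cur in zip(values, values[1:]):
        if prev == 0:
            raise ValueError("zero intermediate value; growth rate undefined")
        changes.append((cur - prev) / prev * 100.0)
    return float(np.mean(changes))


def cagr(series: Sequence[float]) -> float:
    """Compound annual growth rate (%), the geometric alternative."""
    values = list(series)
    if len(values) < 2 or values[0] <= 0 or values[-1] <= 0:
        raise ValueError("need >= 2 positive endpoint values")
    n = len(values) - 1
    return float(((values[-1] / values[0]) ** (1.0 / n) - 1.0) * 100.0)


def linear_trend(series: Sequence[float]) -> float:
    """Ordinary least-squares slope of count on year (units: per year)."""
    y = np.asarray(list(series), dtype=float)
    if y.size < 2:
        raise ValueError("need at least two values")
    x = np.arange(y.size, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def proportion(part: int, whole: int, decimals: int = 1) -> float:
    """round(100*part/whole, decimals) with half-away-from-zero rounding."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError("need 0 <= part <= whole")
    q = Decimal(part * 100) / Decimal(whole)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Term trends (MeSH descriptors or publication-type categories)
# ---------------------------------------------------------------------------

@dataclass
class MeshTrends:
    """Per-term trend bundle over a year window.

    ``counts``: terms x years publications carrying the term;
    ``proportions``: counts as a percentage of that year's publications;
    ``first_year``: earliest year with a nonzero count (absent terms omitted).
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    first_year: dict[str, int]


def mesh_term_trends(
    records: Sequence[PublicationRecord],
    terms: Optional[Sequence[str]] = None,
    window: tuple[int, int] = (1996, 2021),
    attribute: str = "mesh_terms",
) -> MeshTrends:
    """Per-year counts and proportion series for MeSH terms (or, with
    ``attribute='pub_types'``, for publication-type categories).

    With ``terms=None`` every observed descriptor is tabulated.  Proportions
    divide by the total number of publications that year (x100, 1 decimal is
    left to the caller — values here are exact floats).  The same machinery
    serves arbitrary term lists, e.g. gene symbols searched as descriptors.
    """
    years = list(_year_index(window))
    in_window = [r for r in records if window[0] <= r.year <= window[1]]
    if terms is None:
        observed = sorted({t for r in in_window for t in getattr(r, attribute)})
    else:
        observed = list(terms)
    counts = pd.DataFrame(
        0, index=pd.Index(observed, name="term"), columns=years, dtype=int
    )
    totals = annual_counts(in_window, window)
    wanted = set(observed)
    for rec in in_window:
        for term in getattr(rec, attribute):
            if term in wanted:
                counts.loc[term, rec.year] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        proportions = counts.div(totals.replace(0, np.nan), axis=1) * 100.0
    proportions = proportions.fillna(0.0)
    first_year = {
        term: int(row[row > 0].index[0])
        for term, row in counts.iterrows()
        if (row > 0).any()
    }
    return MeshTrends(counts=counts, proportions=proportions, first_year=first_year)


def emerging_terms(trends: MeshTrends, baseline_year: int) -> list[str]:
    """Terms that first appear after the baseline year.

    Sorted by total count descending, ties broken lexicographically.
    """
    candidates = [
        t for t, fy in trends.first_year.items() if fy > baseline_year
    ]
    totals = trends.counts.sum(axis=1)
    return sorted(candidates, key=lambda t: (-int(totals[t]), t))


# ---------------------------------------------------------------------------
# Countries
# ---------------------------------------------------------------------------

def country_shares(
    records: Sequence[PublicationRecord], decimals: int = 1
) -> pd.DataFrame:
    """Ranked (country, count, percentage) table.

    Records without a resolved country are counted under the unknown sentinel:
    they stay out of the ranking but remain in the denominator, so the listed
    shares describe the whole corpus.  Ties rank alphabetically.
    """
    total = len(records)
    tallies: dict[str, int] = {}
    for rec in records:
        country = rec.country or resolve_country(rec.affiliation)
        tallies[country] = tallies.get(country, 0) + 1
    known = {c: n for c, n in tallies.items() if c != UNKNOWN_COUNTRY}
    rows = [
        {
            "country": c,
            "count": n,
            "percentage": proportion(n, total, decimals) if total else 0.0,
        }
        for c, n in sorted(known.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    df = pd.DataFrame(rows, columns=["country", "count", "percentage"])
    df.attrs["total"] = total
    df.attrs["unknown"] = tallies.get(UNKNOWN_COUNTRY, 0)
    return df


def top_k_share(shares: pd.DataFrame, k: int, decimals: int = 1) -> float:
    """Combined percentage of the k most prolific countries."""
    total = shares.attrs.get("total")
    if total is None or total <= 0:
        raise ValueError("shares table lacks a positive total")
    part = int(shares["count"].head(k).sum())
    return proportion(part, total, decimals)


# ---------------------------------------------------------------------------
# Topic-by-year heatmap
# ---------------------------------------------------------------------------

def topic_year_heatmap(
    assignments: Sequence[TopicAssignment],
    years: Sequence[int],
    window: tuple[int, int],
    n_topics: Optional[int] = None,
) -> pd.DataFrame:
    """Counts of primary-topic documents per (topic, year).

    Rows are topics, columns the contiguous year window; the matrix total
    equals the number of in-window assigned documents.
    """
    if len(assignments) != len(years):
        raise ValueError("assignments and years must be aligned")
    if n_topics is None:
        n_topics = 1 + max((a.primary_topic for a in assignments), default=-1)
    year_axis = list(_year_index(window))
    mat = pd.DataFrame(
        0,
        index=pd.Index(range(n_topics), name="topic"),
        columns=year_axis,
        dtype=int,
    )
    for a, y in zip(assignments, years):
        if window[0] <= y <= window[1]:
            mat.loc[a.primary_topic, y] += 1
    return mat
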