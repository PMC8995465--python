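"""Synthetic PubMed-like corpora with known (planted) topic structure.

The generator emulates what a real MEDLINE download looks like to the rest of
the pipeline — metadata fields, a bag-of-words abstract produced by an LDA
generative process, per-year topic-prevalence drift, country/language/
publication-type label distributions, and a two-stage exclusion structure —
while recording the ground truth (planted topic-word rows, document mixtures,
flagged record ids) needed to score recovery.  Abstracts are synthetic token
streams, not prose: only their word counts matter downstream.

Documents are drawn topic-then-word: a year is assigned from the configured
per-year sizes, theta_d ~ Dirichlet(alpha_true * K * prevalence[year]) (so the
yearly prevalence is the expected mixture), token topics ~ theta_d and words ~
phi_k.  MeSH descriptors attach to documents whose dominant topic matches the
term's topic, never before the term's configured emergence year; each term is
guaranteed at least one occurrence in its emergence year so first-appearance
statistics are exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lxml import etree

from .pubmed_corpus import PublicationRecord

__all__ = [
    "MeshTermSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "make_paper_fixture",
    "write_pubmed_xml",
    "vocabulary_words",
    "aligned_true_phi",
    "PAPER_INITIAL",
    "PAPER_TYPE_EXCLUDED",
    "PAPER_LANGUAGE_EXCLUDED",
    "PAPER_FINAL",
]

# Flowchart accounting of the emulated screening (initial download, the two
# manual exclusion stages, and the survivors).
PAPER_INITIAL = 60_453
PAPER_TYPE_EXCLUDED = 157
PAPER_LANGUAGE_EXCLUDED = 9_642
PAPER_FINAL = 50_654

_EXCLUDED_TYPE_CYCLE = [
    "Meeting Abstract",
    "Proceedings Paper",
    "Correction",
    "Book Review",
    "News Item",
]

_DEFAULT_COUNTRY_SHARES = {
    "United States": 0.27,
    "China": 0.16,
    "Japan": 0.09,
    "Germany": 0.06,
    "Italy": 0.05,
    "United Kingdom": 0.05,
    "France": 0.04,
    "South Korea": 0.03,
    "Canada": 0.03,
    "India": 0.02,
    "Unknown": 0.20,
}


@dataclass(frozen=True)
class MeshTermSpec:
    """A planted MeSH descriptor: which topic carries it, the first year it
    may appear, and the attachment probability given a matching document."""

    topic: int
    emergence_year: int
    prob: float = 0.5


def _default_mesh_terms(K: int, start_year: int) -> dict[str, MeshTermSpec]:
    base = {
        "Pathology": MeshTermSpec(0, start_year, 0.6),
        "Genetics": MeshTermSpec(1, start_year, 0.6),
        "Surgery": MeshTermSpec(2, start_year, 0.6),
        "Metabolism": MeshTermSpec(3, start_year, 0.6),
        "Treatment Outcome": MeshTermSpec(4, start_year, 0.5),
        "MicroRNAs": MeshTermSpec(1, start_year + 10, 0.4),
        "Tumor Microenvironment": MeshTermSpec(3, start_year + 14, 0.4),
        "Immunotherapy": MeshTermSpec(4, start_year + 9, 0.3),
    }
    return {
        term: MeshTermSpec(spec.topic % K, spec.emergence_year, spec.prob)
        for term, spec in base.items()
    }


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic corpus.

    Defaults describe a desk-scale corpus shaped like the emulated download:
    a 1996–2021 window with ~5.4% annual growth in output, five planted
    topics whose prevalence drifts linearly across the window, ~100-token
    abstracts, Northern-Hemisphere-heavy country shares, and exclusion-stage
    flag counts in the same proportions as the real screening (~0.26% type
    exclusions, ~16% language/abstract exclusions).
    """

    K_true: int = 5
    V: int = 200
    D: int = 2000
    doc_length_mean: float = 100.0
    min_doc_length: int = 1
    alpha_true: float = 0.1
    beta_true: float = 0.01
    phi: Optional[np.ndarray] = None
    window: tuple[int, int] = (1996, 2021)
    annual_growth: float = 0.0542
    per_year_counts: Optional[dict[int, int]] = None
    topic_prevalence: Optional[np.ndarray] = None
    country_shares: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRY_SHARES)
    )
    excluded_type_count: Optional[int] = None
    non_english_or_short_count: Optional[int] = None
    mesh_terms: Optional[dict[str, MeshTermSpec]] = None
    seed: int = 0

    def resolved_mesh_terms(self) -> dict[str, MeshTermSpec]:
        if self.mesh_terms is not None:
            return self.mesh_terms
        return _default_mesh_terms(self.K_true, self.window[0])

    def resolved_flag_counts(self) -> tuple[int, int]:
        n_type = (
            self.excluded_type_count
            if self.excluded_type_count is not None
            else round(0.0026 * self.D)
        )
        n_lang = (
            self.non_english_or_short_count
            if self.non_english_or_short_count is not None
            else round(0.16 * (self.D - n_type))
        )
        if n_type + n_lang > self.D:
            raise ValueError("flag counts exceed corpus size")
        return n_type, n_lang

    def resolved_per_year_counts(self) -> dict[int, int]:
        if self.per_year_counts is not None:
            counts = dict(self.per_year_counts)
            if sum(counts.values()) != self.D:
                raise ValueError("per_year_counts must sum to D")
            return counts
        start, end = self.window
        years = list(range(start, end + 1))
        weights = np.power(1.0 + self.annual_growth, np.arange(len(years)))
        weights /= weights.sum()
        raw = weights * self.D
        counts = np.floor(raw).astype(int)
        # largest-remainder allocation so the counts sum exactly to D
        deficit = self.D - int(counts.sum())
        for i in np.argsort(-(raw - counts))[:deficit]:
            counts[i] += 1
        return dict(zip(years, counts.tolist()))

    def resolved_prevalence(self) -> np.ndarray:
        start, end = self.window
        n_years = end - start + 1
        if self.topic_prevalence is not None:
            prev = np.asarray(self.topic_prevalence, dtype=float)
            if prev.shape != (n_years, self.K_true):
                raise ValueError("topic_prevalence must be (n_years, K_true)")
            if not np.allclose(prev.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("topic_prevalence rows must sum to 1")
            return prev
        # linear drift: early topics fade, late topics rise
        p_start = np.arange(self.K_true, 0, -1, dtype=float)
        p_end = np.arange(1, self.K_true + 1, dtype=float)
        p_start /= p_start.sum()
        p_end /= p_end.sum()
        t = np.linspace(0.0, 1.0, n_years)[:, None]
        return (1.0 - t) * p_start + t * p_end


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    phi: np.ndarray
    theta: np.ndarray
    years: np.ndarray
    countries: list[str]
    dominant_topics: np.ndarray
    token_topic_counts: np.ndarray
    expected_topic_prevalence: np.ndarray
    per_year_prevalence: dict[int, np.ndarray]
    type_flagged_pmids: list[str]
    language_flagged_pmids: list[str]
    mesh_terms: dict[str, MeshTermSpec]


def _word(i: int) -> str:
    """Purely alphabetic synthetic vocabulary word for index i.

    Prefixed with "q" so no generated word collides with an English stopword
    (none starts with q) and none is dropped by the preprocessing stage.
    """
    letters = []
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        letters.append(chr(ord("a") + r))
    return "q" + "".join(reversed(letters))


def generate(config: GeneratorConfig) -> tuple[list[PublicationRecord], GroundTruth]:
    """Draw a corpus and its ground truth; fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    K, V, D = config.K_true, config.V, config.D
    start, end = config.window

    if config.phi is not None:
        phi = np.asarray(config.phi, dtype=float)
        if phi.shape != (K, V):
            raise ValueError("phi must be (K_true, V)")
    else:
        phi = rng.dirichlet(np.full(V, config.beta_true), size=K)
    words = [_word(i) for i in range(V)]

    per_year = config.resolved_per_year_counts()
    prevalence = config.resolved_prevalence()
    years = np.concatenate(
        [np.full(per_year[y], y, dtype=int) for y in sorted(per_year)]
    )
    assert years.shape[0] == D

    theta = np.empty((D, K))
    for yi, y in enumerate(sorted(per_year)):
        mask = years == y
        if mask.any():
            conc = np.maximum(config.alpha_true * K * prevalence[yi], 1e-6)
            theta[mask] = rng.dirichlet(conc, size=int(mask.sum()))

    lengths = np.maximum(
        rng.poisson(config.doc_length_mean, size=D), config.min_doc_length
    )
    mesh_specs = config.resolved_mesh_terms()
    country_names = list(config.country_shares)
    country_probs = np.asarray(list(config.country_shares.values()), dtype=float)
    country_probs /= country_probs.sum()
    country_draw = rng.choice(len(country_names), size=D, p=country_probs)

    n_type, n_lang = config.resolved_flag_counts()
    flagged = rng.choice(D, size=n_type + n_lang, replace=False)
    type_flagged = set(flagged[:n_type].tolist())
    lang_flagged = set(flagged[n_type:].tolist())

    records: list[PublicationRecord] = []
    dominant = np.empty(D, dtype=int)
    token_topic_counts = np.zeros(K, dtype=np.int64)
    abstracts: list[str] = []
    for d in range(D):
        z_counts = rng.multinomial(int(lengths[d]), theta[d])
        token_topic_counts += z_counts
        toks: list[str] = []
        for k in np.nonzero(z_counts)[0]:
            widx = rng.choice(V, size=int(z_counts[k]), p=phi[k])
            toks.extend(words[w] for w in widx)
        rng.shuffle(toks)
        abstracts.append(" ".join(toks))
        dominant[d] = int(np.argmax(theta[d]))

    # MeSH attachment: topic- and emergence-year-gated
    mesh_lists: list[list[str]] = [[] for _ in range(D)]
    for term, spec in mesh_specs.items():
        eligible = np.nonzero(
            (dominant == spec.topic) & (years >= spec.emergence_year)
        )[0]
        if eligible.size == 0:
            continue
        hits = eligible[rng.random(eligible.size) < spec.prob]
        for d in hits:
            mesh_lists[d].append(term)
        # guarantee the configured emergence year is observable
        if spec.emergence_year >= start:
            in_em_year = np.nonzero(years == spec.emergence_year)[0]
            if in_em_year.size and not any(
                term in mesh_lists[d] for d in in_em_year
            ):
                mesh_lists[int(rng.choice(in_em_year))].append(term)

    countries: list[str] = []
    type_flagged_pmids: list[str] = []
    lang_flagged_pmids: list[str] = []
    for d in range(D):
        pmid = f"{10_000_000 + d}"
        country = country_names[country_draw[d]]
        countries.append(country)
        affiliation = (
            ""
            if country == "Unknown"
            else f"Department of Oncology, University Hospital, {country}"
        )
        title = f"Synthetic pancreatic cancer study {d}"
        abstract = abstracts[d]
        language = "eng"
        pub_types = ["Journal Article"]
        if d in type_flagged:
            if len(type_flagged_pmids) % 5 == 4:
                title = ""  # missing mandatory metadata
            else:
                pub_types = [
                    _EXCLUDED_TYPE_CYCLE[
                        len(type_flagged_pmids) % len(_EXCLUDED_TYPE_CYCLE)
                    ]
                ]
            type_flagged_pmids.append(pmid)
        elif d in lang_flagged:
            if len(lang_flagged_pmids) % 2 == 0:
                language = "ger"
            else:
                abstract = ""  # incomplete abstract
            lang_flagged_pmids.append(pmid)
        records.append(
            PublicationRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                year=int(years[d]),
                language=language,
                pub_types=pub_types,
                mesh_terms=sorted(mesh_lists[d]),
                affiliation=affiliation,
            )
        )

    year_list = sorted(per_year)
    weights = np.asarray([per_year[y] for y in year_list], dtype=float)
    expected = (prevalence * (weights / weights.sum())[:, None]).sum(axis=0)
    truth = GroundTruth(
        phi=phi,
        theta=theta,
        years=years,
        countries=countries,
        dominant_topics=dominant,
        token_topic_counts=token_topic_counts,
        expected_topic_prevalence=expected,
        per_year_prevalence={y: prevalence[i] for i, y in enumerate(year_list)},
        type_flagged_pmids=type_flagged_pmids,
        language_flagged_pmids=lang_flagged_pmids,
        mesh_terms=mesh_specs,
    )
    return records, truth


def make_paper_fixture(seed: int = 0) -> tuple[list[PublicationRecord], GroundTruth]:
    """The screening-accounting corpus: 60,453 records of which exactly 157
    carry excluded types or missing metadata, and exactly 9,642 of the rest
    are non-English or have incomplete abstracts, leaving 50,654.

    Abstracts are minimal (6 tokens) to keep the fixture fast; surviving
    records therefore pass any abstract-completeness threshold up to 6
    tokens, while flagged short-abstract records are empty.
    """
    config = GeneratorConfig(
        K_true=3,
        V=30,
        D=PAPER_INITIAL,
        doc_length_mean=6.0,
        min_doc_length=6,
        excluded_type_count=PAPER_TYPE_EXCLUDED,
        non_english_or_short_count=PAPER_LANGUAGE_EXCLUDED,
        seed=seed,
    )
    return generate(config)


def vocabulary_words(V: int) -> list[str]:
    """The generator's vocabulary in planted-index order."""
    return [_word(i) for i in range(V)]


def aligned_true_phi(truth: GroundTruth, vocab) -> np.ndarray:
    """Project the planted topic-word rows onto a fitted Vocabulary.

    Words the corpus never realised (hence absent from the vocabulary) carry
    negligible planted mass; rows are renormalised after the projection so
    they remain distributions, comparable to estimated rows by TV distance.
    """
    K, V = truth.phi.shape
    words = vocabulary_words(V)
    out = np.zeros((K, len(vocab)))
    for i, w in enumerate(words):
        j = vocab.index.get(w)
        if j is not None:
            out[:, j] = truth.phi[:, i]
    sums = out.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("a planted topic has no realised vocabulary mass")
    return out / sums


# ---------------------------------------------------------------------------
# XML writer (round-trips through pubmed_corpus.parse_pubmed_xml)
# ---------------------------------------------------------------------------

def write_pubmed_xml(records, path) -> None:
    """Emit a PubMed-article-set XML file with lossless field round-trip."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.year > 0:
            etree.SubElement(pubdate, "Year").text = str(rec.year)
        etree.SubElement(article, "ArticleTitle").text = rec.title or None
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        if rec.affiliation:
            authors = etree.SubElement(article, "AuthorList")
            author = etree.SubElement(authors, "Author")
            aff_info = etree.SubElement(author, "AffiliationInfo")
            etree.SubElement(aff_info, "Affiliation").text = rec.affiliation
        if rec.language:
            etree.SubElement(article, "Language").text = rec.language
        if rec.pub_types:
            ptl = etree.SubElement(article, "PublicationTypeList")
            for pt in rec.pub_types:
                etree.SubElement(ptl, "PublicationType").text = pt
        if rec.mesh_terms:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for term in rec.mesh_terms:
                mh = etree.SubElement(mhl, "MeshHeading")
                etree.SubElement(mh, "DescriptorName").text = term
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
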