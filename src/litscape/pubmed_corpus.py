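"""Reading PubMed-style XML metadata and screening records for analysis.

A bibliometric study starts from a raw download of PubMed/MEDLINE records and
screens them in two stages before any modeling: first by publication type and
missing mandatory metadata, then by language and abstract completeness.  This
module provides the record container, a lossless XML reader, the two filters
with auditable accounting, and affiliation-to-country resolution against a
bundled gazetteer.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from lxml import etree

__all__ = [
    "PublicationRecord",
    "FilterReport",
    "DEFAULT_EXCLUDED_TYPES",
    "UNKNOWN_COUNTRY",
    "parse_pubmed_xml",
    "apply_type_filter",
    "apply_language_abstract_filter",
    "load_gazetteer",
    "resolve_country",
    "filter_year_window",
]

#: Publication types removed in the first screening stage.
DEFAULT_EXCLUDED_TYPES = frozenset(
    {
        "Meeting Abstract",
        "Proceedings Paper",
        "Correction",
        "Book Review",
        "News Item",
    }
)

#: Sentinel returned when an affiliation cannot be resolved to a country.
UNKNOWN_COUNTRY = "Unknown"


@dataclass
class PublicationRecord:
    """Metadata of a single indexed article.

    Only the fields used by the downstream analyses are kept: identifier,
    title, abstract, publication year, language code, publication-type labels,
    MeSH descriptors, raw affiliation text and (optionally) a normalized
    country name.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int = 0
    language: str = "eng"
    pub_types: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    affiliation: str = ""
    country: Optional[str] = None


@dataclass
class FilterReport:
    """Accounting of the two-stage screening (flowchart bookkeeping).

    Satisfies ``initial_count - removed_by_type - removed_by_language_or_abstract
    == final_count`` by construction; :meth:`validate` re-checks it.
    """

    initial_count: int
    removed_by_type: int
    removed_by_language_or_abstract: int
    final_count: int

    def validate(self) -> None:
        counts = (
            self.initial_count,
            self.removed_by_type,
            self.removed_by_language_or_abstract,
            self.final_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative count in filter report: {self}")
        expected = (
            self.initial_count
            - self.removed_by_type
            - self.removed_by_language_or_abstract
        )
        if expected != self.final_count:
            raise ValueError(
                f"filter accounting violated: {self.initial_count} - "
                f"{self.removed_by_type} - {self.removed_by_language_or_abstract} "
                f"!= {self.final_count}"
            )

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FilterReport":
        with open(path) as fh:
            report = cls(**json.load(fh))
        report.validate()
        return report


# ---------------------------------------------------------------------------
# XML reading
# ---------------------------------------------------------------------------

def _text(node) -> str:
    if node is None:
        return ""
    return "".join(node.itertext()).strip()


def parse_pubmed_xml(source) -> list[PublicationRecord]:
    """Parse a PubMed article-set XML document into records.

    ``source`` may be a path or an open binary stream.  One record is produced
    per ``PubmedArticle`` element; optional fields that are absent become empty
    values.  Malformed XML raises ``lxml.etree.XMLSyntaxError``; a duplicated
    PMID raises :class:`ValueError` because identifiers must be unique within
    a corpus.
    """
    tree = etree.parse(source)
    records: list[PublicationRecord] = []
    seen: set[str] = set()
    for art in tree.getroot().iter("PubmedArticle"):
        pmid = _text(art.find(".//MedlineCitation/PMID"))
        if pmid in seen:
            raise ValueError(f"duplicate PMID in corpus: {pmid!r}")
        if pmid:
            seen.add(pmid)
        article = art.find(".//MedlineCitation/Article")
        title = _text(None if article is None else article.find("ArticleTitle"))
        abstract = ""
        if article is not None:
            parts = [_text(t) for t in article.findall("Abstract/AbstractText")]
            abstract = " ".join(p for p in parts if p)
        year_text = _text(
            None
            if article is None
            else article.find("Journal/JournalIssue/PubDate/Year")
        )
        year = int(year_text) if year_text.isdigit() else 0
        language = _text(None if article is None else article.find("Language"))
        pub_types = []
        if article is not None:
            pub_types = [
                _text(pt)
                for pt in article.findall("PublicationTypeList/PublicationType")
                if _text(pt)
            ]
        mesh_terms = [
            _text(d)
            for d in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if _text(d)
        ]
        affiliation = ""
        if article is not None:
            aff = article.find(
                "AuthorList/Author/AffiliationInfo/Affiliation"
            )
            affiliation = _text(aff)
        records.append(
            PublicationRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                year=year,
                language=language or "",
                pub_types=pub_types,
                mesh_terms=mesh_terms,
                affiliation=affiliation,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Screening filters
# ---------------------------------------------------------------------------

def _missing_mandatory(record: PublicationRecord) -> bool:
    # Mandatory metadata for the analysis: identifier, title, publication year.
    return not record.pmid or not record.title or record.year <= 0


def apply_type_filter(
    records: Iterable[PublicationRecord],
    excluded_types: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TYPES,
) -> tuple[list[PublicationRecord], int]:
    """First screening stage: publication type and missing metadata.

    A record is removed iff any of its publication types is in
    ``excluded_types`` or mandatory metadata (pmid, title, year) is missing.
    Returns the kept records, in input order, and the removal count.
    """
    if not excluded_types:
        raise ValueError("excluded_types must be nonempty")
    excluded = set(excluded_types)
    kept: list[PublicationRecord] = []
    removed = 0
    for rec in records:
        if _missing_mandatory(rec) or any(t in excluded for t in rec.pub_types):
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def apply_language_abstract_filter(
    records: Iterable[PublicationRecord],
    min_abstract_tokens: int = 50,
    english_codes: frozenset[str] = frozenset({"eng", "en", "english"}),
) -> tuple[list[PublicationRecord], int]:
    """Second screening stage: non-English language or incomplete abstract.

    "Incomplete" means the tokenized abstract has fewer than
    ``min_abstract_tokens`` tokens (default 50, which removes stubs while
    keeping genuinely short abstracts configurable).  The language field comes
    from the XML ``Language`` element, not from text detection.
    """
    if min_abstract_tokens < 1:
        raise ValueError("min_abstract_tokens must be >= 1")
    from .text_prep import tokenize

    kept: list[PublicationRecord] = []
    removed = 0
    for rec in records:
        if rec.language.lower() not in english_codes:
            removed += 1
        elif len(tokenize(rec.abstract)) < min_abstract_tokens:
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def filter_year_window(
    records: Iterable[PublicationRecord], start_year: int, end_year: int
) -> list[PublicationRecord]:
    """Keep records whose publication year lies in [start_year, end_year]."""
    return [r for r in records if start_year <= r.year <= end_year]


# ---------------------------------------------------------------------------
# Country resolution
# ---------------------------------------------------------------------------

def load_gazetteer() -> dict[str, str]:
    """Load the bundled (variant -> country) gazetteer.

    Variants are lower-case country names, common abbreviations, and US state
    names/postal codes.
    """
    path = importlib.resources.files("litscape.data") / "gazetteer.csv"
    gaz: dict[str, str] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            gaz[row["variant"].strip().lower()] = row["country"].strip()
    return gaz


_SEGMENT_CLEAN = re.compile(r"[.;]+$")


def resolve_country(
    affiliation: str, gazetteer: Optional[dict[str, str]] = None
) -> str:
    """Resolve an affiliation string to a country name.

    Affiliations conventionally end with the country, so comma-separated
    segments are scanned right to left and the first gazetteer hit wins.
    Within a segment, the full segment is matched first, then individual
    tokens; two-letter entries (US postal codes) only match upper-case tokens
    so that prose words such as "in" or "or" cannot trigger them.  Returns
    :data:`UNKNOWN_COUNTRY` when nothing matches.
    """
    if gazetteer is None:
        gazetteer = _default_gazetteer()
    if not affiliation:
        return UNKNOWN_COUNTRY
    # Drop email tails PubMed appends after the address.
    affiliation = re.sub(
        r"\bElectronic address:.*$", "", affiliation, flags=re.IGNORECASE
    )
    segments = [s.strip() for s in affiliation.split(",")]
    for segment in reversed(segments):
        segment = _SEGMENT_CLEAN.sub("", segment).strip()
        if not segment:
            continue
        hit = gazetteer.get(segment.lower())
        if hit:
            return hit
        for token in segment.split():
            token = token.strip(".;()")
            if not token:
                continue
            hit = gazetteer.get(token.lower())
            if hit and (len(token) > 2 or token.isupper()):
                return hit
    return UNKNOWN_COUNTRY


_GAZETTEER_CACHE: Optional[dict[str, str]] = None


def _default_gazetteer() -> dict[str, str]:
    global _GAZETTEER_CACHE
    if _GAZETTEER_CACHE is None:
        _GAZETTEER_CACHE = load_gazetteer()
    return _GAZETTEER_CACHE
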