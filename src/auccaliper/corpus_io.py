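"""Parsing and filtering of PubMed/MEDLINE abstract XML.

Reads MEDLINE-citation XML in the PubMed baseline dialect (optionally
gzip-compressed), builds one :class:`AbstractRecord` per citation with
its labelled abstract sections, MeSH headings and publication types, and
applies a fixed exclusion cascade:

1. empty abstract, or abstract of 10 words or fewer;
2. pharmacokinetic studies (MeSH heading / publication-type indicators)
   — their area-under-curve statistics describe drug exposure, not model
   discrimination;
3. meta-analyses and pooled analyses — not original model results;
4. tutorial papers.

Abstracts surviving the cascade are candidates for inclusion; the final
``no_auc_value`` decision is made after value extraction. The first
matching rule wins, so every abstract has exactly one reason and the
flow-chart counts always balance.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from lxml import etree

from .config import DEFAULT_CONFIG, ExclusionConfig, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "FilterDecision",
    "FlowCounts",
    "EXCLUSION_REASONS",
    "parse_pubmed_xml",
    "write_pubmed_xml",
    "word_count",
    "apply_exclusions",
    "flow_counts",
    "corpus_table",
]

EXCLUSION_REASONS = (
    "empty_or_short_abstract",
    "pharmacokinetic",
    "meta_analysis",
    "tutorial",
    "no_auc_value",
)


@dataclass(frozen=True)
class AbstractRecord:
    """One parsed abstract.

    ``sections`` is an ordered tuple of ``(label, text)`` pairs; labels
    are uppercase-normalized when the source provides them ("RESULTS"),
    empty for unstructured abstracts. A citation with no abstract text
    has no sections at all (and will fail inclusion).
    """

    pmid: str
    title: str = ""
    sections: tuple[tuple[str, str], ...] = ()
    year: int | None = None
    journal: str = ""
    mesh_terms: tuple[str, ...] = ()
    publication_types: tuple[str, ...] = ()

    @property
    def abstract_text(self) -> str:
        return " ".join(t for _, t in self.sections)


@dataclass(frozen=True)
class FilterDecision:
    pmid: str
    status: str  # included | excluded
    reason: str  # one of EXCLUSION_REASONS, or "none" iff included


@dataclass
class FlowCounts:
    """Flow-chart accounting: total = included + sum of exclusions."""

    total: int
    included: int
    excluded: dict[str, int]

    def check(self) -> None:
        if self.included + sum(self.excluded.values()) != self.total:
            raise AssertionError("flow counts do not conserve the total")

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "included": self.included,
            "excluded": dict(self.excluded),
        }


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _open_stream(source: str | Path | bytes | IO[bytes]) -> IO[bytes]:
    if isinstance(source, (str, Path)):
        fh: IO[bytes] = open(source, "rb")
    elif isinstance(source, bytes):
        fh = io.BytesIO(source)
    else:
        fh = source
    head = fh.read(2)
    fh.seek(-len(head), io.SEEK_CUR) if fh.seekable() else None
    if head == b"\x1f\x8b":
        if not fh.seekable():  # pragma: no cover - defensive
            raise ValueError("gzip input must be seekable")
        return gzip.open(fh, "rb")
    return fh


def _text(el: etree._Element | None) -> str:
    if el is None:
        return ""
    return "".join(el.itertext()).strip()


def _citation_to_record(cit: etree._Element) -> AbstractRecord | None:
    pmid = _text(cit.find("PMID"))
    if not pmid:
        logger.warning("citation without PMID skipped")
        return None
    art = cit.find("Article")
    title = _text(art.find("ArticleTitle")) if art is not None else ""
    journal = _text(art.find("Journal/Title")) if art is not None else ""
    year: int | None = None
    if art is not None:
        ytxt = _text(art.find("Journal/JournalIssue/PubDate/Year"))
        if not ytxt:
            # MedlineDate fallback, e.g. "2004 Jan-Feb"
            mdate = _text(art.find("Journal/JournalIssue/PubDate/MedlineDate"))
            ytxt = mdate[:4] if mdate[:4].isdigit() else ""
        if ytxt.isdigit():
            year = int(ytxt)
    sections: list[tuple[str, str]] = []
    if art is not None:
        for at in art.findall("Abstract/AbstractText"):
            label = (at.get("Label") or "").strip().upper()
            body = _text(at)
            if body:
                sections.append((label, body))
    mesh = tuple(
        _text(d)
        for d in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")
        if _text(d)
    )
    ptypes = ()
    if art is not None:
        ptypes = tuple(
            _text(p)
            for p in art.findall("PublicationTypeList/PublicationType")
            if _text(p)
        )
    return AbstractRecord(
        pmid=pmid,
        title=title,
        sections=tuple(sections),
        year=year,
        journal=journal,
        mesh_terms=mesh,
        publication_types=ptypes,
    )


def parse_pubmed_xml(source: str | Path | bytes | IO[bytes]) -> list[AbstractRecord]:
    """Parse MEDLINE-citation XML into records, one per citation.

    ``source`` may be a path, raw bytes, or a binary stream; gzip input
    is detected by its magic bytes. Citations without abstract text
    yield records with empty ``sections``; citations without a PMID are
    skipped with a logged warning. Malformed XML raises ``ValueError``
    naming the position of the error.
    """
    stream = _open_stream(source)
    records: list[AbstractRecord] = []
    try:
        for _, cit in etree.iterparse(stream, tag="MedlineCitation", events=("end",)):
            rec = _citation_to_record(cit)
            if rec is not None:
                records.append(rec)
            cit.clear(keep_tail=True)
    except etree.XMLSyntaxError as err:
        line, col = err.position
        raise ValueError(
            f"malformed XML at line {line}, column {col}: {err.msg}"
        ) from err
    return records


def write_pubmed_xml(
    records: Iterable[AbstractRecord],
    path: str | Path | None = None,
    compress: bool = False,
) -> bytes:
    """Serialize records to the MEDLINE dialect read by ``parse_pubmed_xml``.

    Primarily used by the synthetic-corpus generator so the whole
    pipeline can be exercised from XML; parsing the output reproduces the
    input records exactly (round-trip property).
    """
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art_el = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art_el, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = rec.journal or None
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.year is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.year)
        etree.SubElement(article, "ArticleTitle").text = rec.title or None
        if rec.sections:
            abstract = etree.SubElement(article, "Abstract")
            for label, body in rec.sections:
                at = etree.SubElement(abstract, "AbstractText")
                if label:
                    at.set("Label", label)
                at.text = body
        if rec.publication_types:
            ptl = etree.SubElement(article, "PublicationTypeList")
            for p in rec.publication_types:
                etree.SubElement(ptl, "PublicationType").text = p
        if rec.mesh_terms:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for m in rec.mesh_terms:
                mh = etree.SubElement(mhl, "MeshHeading")
                etree.SubElement(mh, "DescriptorName").text = m
    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if compress:
        payload = gzip.compress(payload, mtime=0)
    if path is not None:
        Path(path).write_bytes(payload)
    return payload


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

def word_count(text: str) -> int:
    """Whitespace-delimited token count (hyphenated words count once)."""
    return len(text.split())


def _matches_any(values: Iterable[str], indicators: Iterable[str]) -> bool:
    vals = [v.casefold() for v in values]
    return any(ind.casefold() in v for ind in indicators for v in vals)


def apply_exclusions(
    record: AbstractRecord,
    rules: ExclusionConfig | PipelineConfig = DEFAULT_CONFIG,
) -> FilterDecision:
    """Apply the exclusion cascade to one abstract; first match wins.

    Records passing every rule get ``status="included"`` with reason
    ``"none"`` — they remain candidates until extraction decides whether
    any AUC value is present.
    """
    rules = rules.exclusions if isinstance(rules, PipelineConfig) else rules
    if word_count(record.abstract_text) <= rules.max_short_words:
        return FilterDecision(record.pmid, "excluded", "empty_or_short_abstract")
    if _matches_any(record.mesh_terms, rules.pharmacokinetic_mesh) or _matches_any(
        record.publication_types, rules.pharmacokinetic_pubtypes
    ):
        return FilterDecision(record.pmid, "excluded", "pharmacokinetic")
    if _matches_any(record.publication_types, rules.meta_analysis_pubtypes) or _matches_any(
        [record.title], rules.meta_analysis_title_keywords
    ):
        return FilterDecision(record.pmid, "excluded", "meta_analysis")
    if _matches_any(record.publication_types, rules.tutorial_pubtypes) or _matches_any(
        [record.title], rules.tutorial_title_keywords
    ):
        return FilterDecision(record.pmid, "excluded", "tutorial")
    return FilterDecision(record.pmid, "included", "none")


def flow_counts(decisions: Iterable[FilterDecision]) -> FlowCounts:
    """Flow-chart accounting over one decision per abstract."""
    seen: set[str] = set()
    excluded = {r: 0 for r in EXCLUSION_REASONS}
    included = 0
    total = 0
    for d in decisions:
        if d.pmid in seen:
            raise ValueError(f"duplicate decision for pmid {d.pmid}")
        seen.add(d.pmid)
        total += 1
        if d.status == "included":
            included += 1
        else:
            excluded[d.reason] += 1
    fc = FlowCounts(total=total, included=included, excluded=excluded)
    fc.check()
    return fc


def corpus_table(
    records: Iterable[AbstractRecord],
    decisions: dict[str, FilterDecision],
) -> pd.DataFrame:
    """Corpus summary table (one row per abstract)."""
    rows = []
    for rec in records:
        d = decisions[rec.pmid]
        rows.append(
            {
                "pmid": rec.pmid,
                "year": rec.year,
                "journal": rec.journal,
                "n_sections": len(rec.sections),
                "decision": d.status,
                "reason": d.reason,
            }
        )
    return pd.DataFrame(
        rows, columns=["pmid", "year", "journal", "n_sections", "decision", "reason"]
    )
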