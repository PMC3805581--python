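"""Link SRA studies to the publications that describe them.

Archive deposits and the articles that analyse them cross-reference one
another through three routes: (a) PubMed IDs cited inside the SRA
metadata itself, (b) SRA accessions mentioned in article full text, and
(c) GEO series/dataset identifiers that bridge an article to a study
whose raw data lives in GEO.  Each route yields (study accession, PMID)
pairs tagged with their provenance; the routes are merged into one
deduplicated publication list.

Full-text mentions that do not resolve to any known study are dropped
and logged: an accession with no corresponding project information is
treated as a false positive, which is what keeps the merged list's
precision high without manual review.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Medline

from .accessions import (
    AccessionKind,
    classify_accession,
    extract_accessions,
    normalize_accession,
)
from .metadata import AccessionGraph, resolve_to_study, study_resolution_map

__all__ = [
    "HTS_MESH_HEADING",
    "HTS_MESH_UI",
    "Provenance",
    "ArticleDocument",
    "GeoRecord",
    "GeoSraBridge",
    "LiteratureLink",
    "EvaluationResult",
    "read_medline",
    "load_articles",
    "read_soft",
    "pmids_from_metadata",
    "pairs_from_fulltext",
    "build_geo_bridge",
    "pairs_via_geo",
    "load_manual_pairs",
    "merge_publication_list",
    "evaluate_pairs",
]

logger = logging.getLogger(__name__)

#: MeSH descriptor marking articles about massively parallel sequencing.
HTS_MESH_HEADING = "High-Throughput Nucleotide Sequencing"
HTS_MESH_UI = "D059014"

_SRA_CITABLE_KINDS = frozenset(
    {
        AccessionKind.SUBMISSION,
        AccessionKind.STUDY,
        AccessionKind.EXPERIMENT,
        AccessionKind.RUN,
        AccessionKind.SAMPLE,
        AccessionKind.ANALYSIS,
    }
)
_GEO_KINDS = frozenset({AccessionKind.GEO_SERIES, AccessionKind.GEO_DATASET})


class Provenance:
    """Provenance tags for literature links, in merge-priority order."""

    METADATA_REF = "metadata_ref"
    FULLTEXT_DIRECT = "fulltext_direct"
    GEO_BRIDGE = "geo_bridge"
    MANUAL = "manual"

    PRIORITY = (METADATA_REF, FULLTEXT_DIRECT, GEO_BRIDGE, MANUAL)

    @classmethod
    def rank(cls, provenance: str) -> int:
        return cls.PRIORITY.index(provenance)


@dataclass
class ArticleDocument:
    """One article: PMID, plain full text, and its MeSH headings."""

    pmid: int
    full_text: str = ""
    mesh_headings: list[str] = field(default_factory=list)
    is_hts: bool = False


@dataclass
class GeoRecord:
    """One GEO series/dataset with its PubMed and SRA cross-references."""

    accession: str
    pubmed_ids: list[int] = field(default_factory=list)
    sra_relations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeoSraBridge:
    """A (GEO accession, SRA study) identifier pair and how it was found."""

    geo_accession: str
    study_accession: str
    source: str  # "from_geo_record" | "from_sra_metadata"


@dataclass(frozen=True)
class LiteratureLink:
    """One (study, PMID) pair with the route that produced it.

    ``raw_accession`` preserves the identifier as originally cited,
    which may be run- or experiment-level, or a GEO accession.
    """

    study_accession: str
    pmid: int
    provenance: str
    raw_accession: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.study_accession, self.pmid)


@dataclass(frozen=True)
class EvaluationResult:
    """Set-comparison of predicted vs gold pairs.

    ``precision``/``recall`` are ``None`` when undefined (empty
    denominator) — deliberately distinct from 0.0.
    """

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]


# ---------------------------------------------------------------------------
# Readers


def _strip_heading(heading: str) -> str:
    """Normalize a MEDLINE MH entry: drop the major-topic star and qualifier."""
    return heading.lstrip("*").split("/", 1)[0].strip()


def read_medline(text: str) -> list[ArticleDocument]:
    """Parse MEDLINE flat-format records (``PMID- `` / ``MH  - `` fields)."""
    articles: list[ArticleDocument] = []
    for record in Medline.parse(io.StringIO(text)):
        pmid_raw = record.get("PMID")
        if not pmid_raw:
            logger.warning("MEDLINE record without PMID skipped")
            continue
        headings = [_strip_heading(h) for h in record.get("MH", [])]
        articles.append(
            ArticleDocument(
                pmid=int(pmid_raw),
                mesh_headings=headings,
                is_hts=HTS_MESH_HEADING in headings or HTS_MESH_UI in headings,
            )
        )
    return articles


def load_articles(medline_path, fulltext_dir=None) -> list[ArticleDocument]:
    """Read a MEDLINE file and attach full texts from ``<pmid>.txt`` files."""
    from pathlib import Path

    with open(medline_path, encoding="utf-8") as handle:
        articles = read_medline(handle.read())
    if fulltext_dir is not None:
        fulltext_dir = Path(fulltext_dir)
        for article in articles:
            path = fulltext_dir / f"{article.pmid}.txt"
            if path.exists():
                article.full_text = path.read_text(encoding="utf-8")
    return articles


def read_soft(text: str) -> list[GeoRecord]:
    """Parse GEO SOFT-format series/dataset records.

    Recognizes ``^SERIES``/``^DATASET`` entity lines, ``!*_pubmed_id``
    attributes, and SRA accessions inside ``!*_relation`` lines.
    """
    records: list[GeoRecord] = []
    current: Optional[GeoRecord] = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("^SERIES") or line.startswith("^DATASET"):
            _, _, value = line.partition("=")
            accession = value.strip()
            cls = classify_accession(accession)
            if cls is None or cls.kind not in _GEO_KINDS:
                logger.warning("ignoring SOFT entity with odd accession %r", accession)
                current = None
                continue
            current = GeoRecord(accession=accession)
            records.append(current)
        elif current is not None and line.startswith("!"):
            key, _, value = line[1:].partition("=")
            key = key.strip().lower()
            value = value.strip()
            if key.endswith("_pubmed_id"):
                try:
                    pmid = int(value)
                except ValueError:
                    logger.warning("non-numeric pubmed id %r in SOFT record", value)
                    continue
                if pmid not in current.pubmed_ids:
                    current.pubmed_ids.append(pmid)
            elif key.endswith("_relation"):
                for match in extract_accessions(value):
                    if match.kind in _SRA_CITABLE_KINDS:
                        current.sra_relations.append(match.text)
    return records


# ---------------------------------------------------------------------------
# The three provenance routes


def pmids_from_metadata(
    graph: AccessionGraph,
) -> tuple[list[LiteratureLink], list[tuple[str, int]]]:
    """Route (a): PubMed IDs cited inside the SRA metadata records.

    Every pubmed cross-link on any object becomes a link against the
    object's resolved study.  Returns ``(links, unresolved)`` where
    ``unresolved`` lists (accession, pmid) for objects that resolve to
    no study — reported, never silently emitted.
    """
    resolution = study_resolution_map(graph)
    links: list[LiteratureLink] = []
    unresolved: list[tuple[str, int]] = []
    for accession, obj in graph.nodes.items():
        if not obj.pubmed_refs:
            continue
        studies = resolution.get(accession, frozenset())
        for pmid in obj.pubmed_refs:
            if not studies:
                unresolved.append((accession, pmid))
                continue
            for study in sorted(studies):
                links.append(
                    LiteratureLink(study, pmid, Provenance.METADATA_REF, accession)
                )
    return links, unresolved


def pairs_from_fulltext(
    articles: Iterable[ArticleDocument],
    graph: AccessionGraph,
    hts_only: bool = True,
) -> tuple[list[LiteratureLink], list[tuple[int, str]]]:
    """Route (b): SRA accessions extracted from article full text.

    Cited accessions are usually run- or experiment-level; each is
    resolved to its study (fanning out over one-to-many links).
    Mentions that resolve to no study are false positives with no
    project behind them: they are dropped from the list and recorded in
    the returned drop log as (pmid, accession) — one entry per mention.

    With ``hts_only`` (the default), only articles carrying the
    high-throughput-sequencing MeSH heading are scanned.
    """
    links: list[LiteratureLink] = []
    dropped: list[tuple[int, str]] = []
    for article in articles:
        if hts_only and not article.is_hts:
            continue
        for match in extract_accessions(article.full_text):
            if match.kind not in _SRA_CITABLE_KINDS:
                continue  # GEO mentions belong to the bridge route
            studies = resolve_to_study(graph, match.text)
            if not studies:
                dropped.append((article.pmid, match.text))
                continue
            for study in sorted(studies):
                links.append(
                    LiteratureLink(
                        study, article.pmid, Provenance.FULLTEXT_DIRECT, match.text
                    )
                )
    return links, dropped


def build_geo_bridge(
    geo_records: Iterable[GeoRecord], graph: AccessionGraph
) -> list[GeoSraBridge]:
    """Pair GEO accessions with SRA studies, from either side.

    Union of (i) SRA accessions referenced by GEO records, resolved to
    studies, and (ii) GEO accessions mentioned in SRA object titles.
    Deduplicated on (geo, study); when both sides discover the same
    pair, the GEO-record provenance wins.
    """
    bridges: dict[tuple[str, str], GeoSraBridge] = {}

    def add(geo: str, study: str, source: str) -> None:
        key = (geo, study)
        existing = bridges.get(key)
        if existing is None or (
            existing.source == "from_sra_metadata" and source == "from_geo_record"
        ):
            bridges[key] = GeoSraBridge(geo, study, source)

    for record in geo_records:
        for relation in record.sra_relations:
            for study in sorted(resolve_to_study(graph, relation)):
                add(record.accession, study, "from_geo_record")

    resolution = study_resolution_map(graph)
    for accession, obj in graph.nodes.items():
        if not obj.title:
            continue
        geo_mentions = [
            m for m in extract_accessions(obj.title) if m.kind in _GEO_KINDS
        ]
        if not geo_mentions:
            continue
        for study in sorted(resolution.get(accession, frozenset())):
            for mention in geo_mentions:
                add(mention.text, study, "from_sra_metadata")
    return sorted(bridges.values(), key=lambda b: (b.geo_accession, b.study_accession))


def pairs_via_geo(
    geo_records: Iterable[GeoRecord],
    articles: Iterable[ArticleDocument],
    bridge: Iterable[GeoSraBridge],
) -> list[LiteratureLink]:
    """Route (c): carry article–GEO citations across the GEO–SRA bridge.

    An article is attached to a GEO record either through the record's
    own ``pubmed_id`` fields or by citing the GEO accession in its full
    text; each such (GEO, PMID) pair crosses every bridge entry for that
    GEO accession to yield a (study, PMID) link.
    """
    geo_pmids: dict[str, set[int]] = {}
    for record in geo_records:
        geo_pmids.setdefault(record.accession, set()).update(record.pubmed_ids)
    for article in articles:
        for match in extract_accessions(article.full_text):
            if match.kind in _GEO_KINDS:
                geo_pmids.setdefault(match.text, set()).add(article.pmid)

    links: list[LiteratureLink] = []
    for entry in bridge:
        for pmid in sorted(geo_pmids.get(entry.geo_accession, ())):
            links.append(
                LiteratureLink(
                    entry.study_accession,
                    pmid,
                    Provenance.GEO_BRIDGE,
                    entry.geo_accession,
                )
            )
    return links


def load_manual_pairs(
    path, graph: AccessionGraph
) -> tuple[list[LiteratureLink], list[tuple[str, int]]]:
    """Read manually curated (accession, pmid) pairs from a TSV side file.

    Curated pairs bypass text extraction but still must resolve to a
    study; rows that do not are returned in the rejects list.
    """
    links: list[LiteratureLink] = []
    rejects: list[tuple[str, int]] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "accession":
                continue
            accession, pmid = row[0].strip(), int(row[1])
            studies = resolve_to_study(graph, accession)
            if not studies:
                rejects.append((accession, pmid))
                continue
            for study in sorted(studies):
                links.append(
                    LiteratureLink(study, pmid, Provenance.MANUAL, accession)
                )
    return links, rejects


# ---------------------------------------------------------------------------
# Merge and evaluation


def merge_publication_list(
    *link_lists: Sequence[LiteratureLink],
) -> list[LiteratureLink]:
    """Union the routes, deduplicated on (study, PMID).

    On collision the highest-priority provenance wins
    (metadata_ref > fulltext_direct > geo_bridge > manual); output is
    sorted by study accession then PMID, so merging is deterministic
    and order-independent.
    """
    merged: dict[tuple[str, int], LiteratureLink] = {}
    for links in link_lists:
        for link in links:
            existing = merged.get(link.key)
            if existing is None or Provenance.rank(link.provenance) < Provenance.rank(
                existing.provenance
            ):
                merged[link.key] = link
    return sorted(merged.values(), key=lambda l: l.key)


def evaluate_pairs(
    predicted: Iterable[tuple[str, int]], gold: Iterable[tuple[str, int]]
) -> EvaluationResult:
    """Precision/recall of a predicted pair set against a gold standard."""
    predicted, gold = set(predicted), set(gold)
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return EvaluationResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
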