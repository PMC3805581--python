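"""SRA metadata object model, accession graph, and archive summaries.

An SRA deposition is described by up to six XML files — submission,
study, experiment, run, sample and analysis — whose records point at one
another by accession: an experiment references its study and sample, a
run its experiment, an analysis its study, and the submission owns every
object it deposited.  This module parses those files into
:class:`MetadataObject` records, assembles the directed reference graph,
resolves any accession to the study ("project") it belongs to, and
derives the archive-level summaries: per-submission metadata
completeness patterns, per-study project summaries, and facet tables by
study type, sequencing platform, or sample species.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional

import networkx as nx

from .accessions import AccessionKind, classify_accession, normalize_accession

__all__ = [
    "MetadataObject",
    "AccessionGraph",
    "CompletenessProfile",
    "ProjectSummary",
    "MetadataParseError",
    "MetadataRecordError",
    "SRA_KINDS",
    "parse_metadata",
    "parse_metadata_file",
    "build_accession_graph",
    "resolve_to_study",
    "study_resolution_map",
    "completeness_profiles",
    "summarize_projects",
    "tabulate_by",
]

logger = logging.getLogger(__name__)

#: The six SRA object kinds, in canonical (Fig.-style) order.
SRA_KINDS: tuple[AccessionKind, ...] = (
    AccessionKind.SUBMISSION,
    AccessionKind.STUDY,
    AccessionKind.EXPERIMENT,
    AccessionKind.RUN,
    AccessionKind.SAMPLE,
    AccessionKind.ANALYSIS,
)

_REF_TAG_KIND = {
    "SUBMISSION_REF": AccessionKind.SUBMISSION,
    "STUDY_REF": AccessionKind.STUDY,
    "EXPERIMENT_REF": AccessionKind.EXPERIMENT,
    "RUN_REF": AccessionKind.RUN,
    "SAMPLE_REF": AccessionKind.SAMPLE,
    "ANALYSIS_REF": AccessionKind.ANALYSIS,
    "SAMPLE_DESCRIPTOR": AccessionKind.SAMPLE,
}


class MetadataParseError(ValueError):
    """Raised for malformed XML; message names the byte offset."""


class MetadataRecordError(ValueError):
    """Raised for a structurally broken record; message names its path."""


@dataclass
class MetadataObject:
    """One parsed SRA metadata record of any of the six kinds."""

    kind: AccessionKind
    accession: str
    title: Optional[str] = None
    study_type: Optional[str] = None          # study records only
    instrument_model: Optional[str] = None    # experiment records only
    taxon_id: Optional[int] = None            # sample records only
    scientific_name: Optional[str] = None     # sample records only
    references: list[tuple[AccessionKind, str]] = field(default_factory=list)
    pubmed_refs: list[int] = field(default_factory=list)
    received_date: Optional[date] = None


@dataclass
class AccessionGraph:
    """Directed reference graph over parsed metadata objects.

    ``dangling`` holds (from, to) pairs whose target record was never
    parsed; they are kept as data rather than silently dropped, because
    unresolvable references are exactly what the downstream
    false-positive filter operates on.
    """

    nodes: dict[str, MetadataObject]
    graph: nx.MultiDiGraph
    dangling: set[tuple[str, str]]


@dataclass(frozen=True)
class CompletenessProfile:
    """One observed presence/absence pattern of the six object kinds.

    ``pattern`` is ordered (submission, study, experiment, run, sample,
    analysis); ``count`` is the number of submissions exhibiting it.
    """

    pattern: tuple[bool, bool, bool, bool, bool, bool]
    count: int


@dataclass
class ProjectSummary:
    """Per-study aggregate over its member experiments/runs/samples."""

    study_accession: str
    title: Optional[str]
    study_type: Optional[str]
    platforms: set[str]
    taxa: set[tuple[Optional[int], Optional[str]]]
    n_experiments: int
    n_runs: int
    submissions: set[str]


# ---------------------------------------------------------------------------
# Parsing


def _byte_offset(document: str, line: int, column: int) -> int:
    lines = document.split("\n")
    return sum(len(l.encode()) + 1 for l in lines[: line - 1]) + column


def _text(elem: Optional[ET.Element]) -> Optional[str]:
    if elem is None or elem.text is None:
        return None
    stripped = elem.text.strip()
    return stripped or None


def _collect_pubmed_refs(record: ET.Element) -> list[int]:
    pmids: list[int] = []
    for xref in record.iter("XREF_LINK"):
        db = xref.get("DB") or _text(xref.find("DB"))
        if db is None or db.lower() != "pubmed":
            continue
        raw = xref.get("ID") or _text(xref.find("ID"))
        if raw is None:
            continue
        for piece in raw.replace(",", " ").split():
            try:
                pmid = int(piece)
            except ValueError:
                logger.warning("ignoring non-numeric pubmed ID %r", piece)
                continue
            if pmid > 0 and pmid not in pmids:
                pmids.append(pmid)
    return pmids


def _collect_references(record: ET.Element) -> list[tuple[AccessionKind, str]]:
    refs: list[tuple[AccessionKind, str]] = []
    for elem in record.iter():
        kind = _REF_TAG_KIND.get(elem.tag)
        if kind is None:
            continue
        accession = elem.get("accession")
        if accession:
            refs.append((kind, accession))
    return refs


def parse_metadata(
    document: str, kind: AccessionKind | str
) -> list[MetadataObject]:
    """Parse one SRA metadata XML document of the given object kind.

    Unknown elements are ignored so that richer real-archive dumps still
    parse.  Malformed XML raises :class:`MetadataParseError` naming the
    byte offset; a record without an ``accession`` attribute raises
    :class:`MetadataRecordError` naming the element path.
    """
    kind = AccessionKind(kind)
    if kind not in SRA_KINDS:
        raise ValueError(f"not an SRA metadata kind: {kind}")
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line, column = exc.position
        raise MetadataParseError(
            f"malformed XML at byte offset {_byte_offset(document, line, column)}"
            f" (line {line}, column {column}): {exc.msg}"
        ) from exc

    record_tag = kind.name  # SUBMISSION, STUDY, ...
    objects: list[MetadataObject] = []
    index = 0
    for record in root:
        if record.tag != record_tag:
            continue
        index += 1
        accession = record.get("accession")
        if not accession:
            raise MetadataRecordError(
                f"record missing accession attribute at "
                f"{root.tag}/{record_tag}[{index}]"
            )
        obj = MetadataObject(kind=kind, accession=accession)

        if kind is AccessionKind.STUDY:
            obj.title = _text(record.find("DESCRIPTOR/STUDY_TITLE")) or _text(
                record.find("TITLE")
            )
            study_type = record.find("DESCRIPTOR/STUDY_TYPE")
            if study_type is None:
                study_type = record.find("STUDY_TYPE")
            if study_type is not None:
                obj.study_type = study_type.get("existing_study_type")
        else:
            obj.title = _text(record.find("TITLE"))

        if kind is AccessionKind.EXPERIMENT:
            for model in record.iter("INSTRUMENT_MODEL"):
                obj.instrument_model = _text(model)
                break
        if kind is AccessionKind.SAMPLE:
            taxon = _text(record.find("SAMPLE_NAME/TAXON_ID"))
            if taxon is not None:
                try:
                    obj.taxon_id = int(taxon)
                except ValueError:
                    logger.warning(
                        "%s: non-numeric TAXON_ID %r ignored", accession, taxon
                    )
            obj.scientific_name = _text(
                record.find("SAMPLE_NAME/SCIENTIFIC_NAME")
            )

        received = record.get("received")
        if received:
            try:
                obj.received_date = date.fromisoformat(received)
            except ValueError:
                logger.warning(
                    "%s: unparseable received date %r ignored", accession, received
                )

        obj.references = _collect_references(record)
        obj.pubmed_refs = _collect_pubmed_refs(record)
        objects.append(obj)
    return objects


def parse_metadata_file(path, kind: AccessionKind | str) -> list[MetadataObject]:
    """Read and parse one metadata XML file (UTF-8)."""
    with open(path, encoding="utf-8") as handle:
        return parse_metadata(handle.read(), kind)


# ---------------------------------------------------------------------------
# Graph construction and resolution


def build_accession_graph(objects: Iterable[MetadataObject]) -> AccessionGraph:
    """Index objects by accession and wire their reference links.

    Duplicate accessions are resolved last-wins with a warning; links to
    absent accessions are recorded in ``dangling``.  Self-references are
    discarded (the graph holds no self-edges).
    """
    nodes: dict[str, MetadataObject] = {}
    for obj in objects:
        accession = normalize_accession(obj.accession)
        if accession in nodes:
            logger.warning("duplicate accession %s: keeping last record", accession)
        nodes[accession] = obj

    graph = nx.MultiDiGraph()
    graph.add_nodes_from(nodes)
    dangling: set[tuple[str, str]] = set()
    for accession, obj in nodes.items():
        for link_kind, target in obj.references:
            target = normalize_accession(target)
            if target == accession:
                continue
            if target in nodes:
                graph.add_edge(accession, target, key=link_kind.value)
            else:
                dangling.add((accession, target))
    return AccessionGraph(nodes=nodes, graph=graph, dangling=dangling)


def _resolve(
    g: AccessionGraph, accession: str, memo: dict[str, frozenset[str]]
) -> frozenset[str]:
    if accession in memo:
        return memo[accession]
    memo[accession] = frozenset()  # cycle guard
    obj = g.nodes[accession]
    kind = obj.kind

    def successors_of_kind(acc: str, want: AccessionKind) -> list[str]:
        return [
            s for s in g.graph.successors(acc) if g.nodes[s].kind is want
        ]

    result: set[str] = set()
    if kind is AccessionKind.STUDY:
        result.add(accession)
    elif kind is AccessionKind.EXPERIMENT:
        result.update(successors_of_kind(accession, AccessionKind.STUDY))
    elif kind is AccessionKind.ANALYSIS:
        result.update(successors_of_kind(accession, AccessionKind.STUDY))
    elif kind is AccessionKind.RUN:
        for exp in successors_of_kind(accession, AccessionKind.EXPERIMENT):
            result.update(_resolve(g, exp, memo))
    elif kind is AccessionKind.SAMPLE:
        # Samples are pointed AT by experiments; walk the edges backwards.
        for pred in g.graph.predecessors(accession):
            if g.nodes[pred].kind is AccessionKind.EXPERIMENT:
                result.update(_resolve(g, pred, memo))
    elif kind is AccessionKind.SUBMISSION:
        for owned in g.graph.successors(accession):
            result.update(_resolve(g, owned, memo))
    memo[accession] = frozenset(result)
    return memo[accession]


def resolve_to_study(g: AccessionGraph, accession: str) -> set[str]:
    """Resolve any accession to the set of study accessions it belongs to.

    Follows the typed reference topology: run -> experiment -> study,
    sample <- experiment -> study, analysis -> study, submission -> each
    owned object.  A study resolves to itself.  May return more than one
    study (relationships are one-to-many) or the empty set when the
    accession is valid but unknown to the graph.

    Raises ``ValueError`` for a token that is not syntactically an SRA
    accession — distinct from "valid but unresolvable", which returns
    the empty set.
    """
    normalized = normalize_accession(accession)
    cls = classify_accession(normalized)
    if cls is None or cls.kind not in SRA_KINDS:
        raise ValueError(f"not a syntactically valid SRA accession: {accession!r}")
    if normalized not in g.nodes:
        return set()
    return set(_resolve(g, normalized, {}))


def study_resolution_map(g: AccessionGraph) -> dict[str, frozenset[str]]:
    """Resolve every node at once (shared memo); accession -> studies."""
    memo: dict[str, frozenset[str]] = {}
    for accession in g.nodes:
        _resolve(g, accession, memo)
    return memo


# ---------------------------------------------------------------------------
# Summaries


def completeness_profiles(g: AccessionGraph) -> list[CompletenessProfile]:
    """Tally which of the six object kinds each submission carries.

    A kind counts as present when the submission (or anything reachable
    from it through reference links) includes a parsed record of that
    kind.  Profiles are returned sorted by count descending, so the head
    of the list is the archive's dominant deposition shapes.
    """
    counts: dict[tuple[bool, ...], int] = {}
    for accession, obj in g.nodes.items():
        if obj.kind is not AccessionKind.SUBMISSION:
            continue
        reachable = {accession} | nx.descendants(g.graph, accession)
        kinds_present = {g.nodes[a].kind for a in reachable}
        pattern = tuple(k in kinds_present for k in SRA_KINDS)
        counts[pattern] = counts.get(pattern, 0) + 1
    return [
        CompletenessProfile(pattern=p, count=c)
        for p, c in sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    ]


def summarize_projects(g: AccessionGraph) -> list[ProjectSummary]:
    """One summary per study, aggregating member experiments and runs.

    Membership is defined by resolution: an experiment or run is a
    member of every study it resolves to.  Sorted by number of
    experiments descending, then accession.
    """
    resolution = study_resolution_map(g)
    summaries: dict[str, ProjectSummary] = {}
    for accession, obj in g.nodes.items():
        if obj.kind is AccessionKind.STUDY:
            summaries[accession] = ProjectSummary(
                study_accession=accession,
                title=obj.title,
                study_type=obj.study_type,
                platforms=set(),
                taxa=set(),
                n_experiments=0,
                n_runs=0,
                submissions=set(),
            )
    for accession, obj in g.nodes.items():
        studies = resolution.get(accession, frozenset())
        for study in studies:
            summary = summaries.get(study)
            if summary is None:
                continue
            if obj.kind is AccessionKind.EXPERIMENT:
                summary.n_experiments += 1
                if obj.instrument_model:
                    summary.platforms.add(obj.instrument_model)
                for succ in g.graph.successors(accession):
                    sample = g.nodes[succ]
                    if sample.kind is AccessionKind.SAMPLE and (
                        sample.taxon_id is not None
                        or sample.scientific_name is not None
                    ):
                        summary.taxa.add(
                            (sample.taxon_id, sample.scientific_name)
                        )
            elif obj.kind is AccessionKind.RUN:
                summary.n_runs += 1
            elif obj.kind is AccessionKind.SUBMISSION:
                summary.submissions.add(accession)
    return sorted(
        summaries.values(),
        key=lambda s: (-s.n_experiments, s.study_accession),
    )


_FACETS = ("study_type", "platform", "taxon")


def tabulate_by(
    projects: Iterable[ProjectSummary], facet: str
) -> list[tuple[str, int]]:
    """Count studies per facet category (study type, platform, species).

    A study contributes once to EACH category it carries, so column
    totals may exceed the number of studies — e.g. a study sampling both
    human and mouse appears under both species.  Sorted by count
    descending, ties by category name.
    """
    if facet not in _FACETS:
        raise ValueError(f"unknown facet {facet!r}; expected one of {_FACETS}")
    counts: dict[str, int] = {}
    for project in projects:
        if facet == "study_type":
            categories = {project.study_type} if project.study_type else set()
        elif facet == "platform":
            categories = set(project.platforms)
        else:
            categories = {
                name if name else f"taxon:{taxon_id}"
                for taxon_id, name in project.taxa
            }
        for category in categories:
            counts[category] = counts.get(category, 0) + 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))
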