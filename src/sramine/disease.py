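"""Disease characterization of SRA studies via MeSH, DO and OMIM.

Articles indexed in MEDLINE carry Medical Subject Headings (MeSH);
joining a study's linked articles against the MeSH vocabulary and
keeping only descriptors in the Diseases [C] branch or the Mental
Disorders [F03] sub-branch yields study–disease annotations.  From
those this module derives a disease frequency list (distinct studies
per descriptor), a hierarchical tree view over the MeSH tree numbers
(the vocabulary's own answer to lexical variation — "breast cancer"
vs "Breast Neoplasms"), and MeSH→OMIM identifier mappings mediated by
Disease Ontology xrefs, from which hyperlinks into the Gendoo disease
feature-profile service are generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .disease_vocab import (  # re-exported parsing layer
    DoTerm,
    MeshDescriptor,
    parse_do_obo,
    parse_mesh_ascii,
)
from .litlink import ArticleDocument, LiteratureLink

__all__ = [
    "MeshDescriptor",
    "DoTerm",
    "DiseaseAnnotation",
    "FrequencyRow",
    "MeshTreeNode",
    "parse_mesh_ascii",
    "parse_do_obo",
    "is_disease_descriptor",
    "annotate_diseases",
    "disease_frequency",
    "build_disease_tree",
    "mesh_to_omim",
    "gendoo_url",
    "DEFAULT_GENDOO_TEMPLATE",
]

logger = logging.getLogger(__name__)

DEFAULT_GENDOO_TEMPLATE = "https://gendoo.dbcls.jp/omim/{omim_id}.html"


@dataclass
class DiseaseAnnotation:
    """One (study, disease descriptor) association with its evidence.

    ``supporting_pmids`` is the non-empty, sorted list of articles that
    carry the heading and are linked to the study.
    """

    study_accession: str
    ui: str
    name: str
    supporting_pmids: list[int]


@dataclass(frozen=True)
class FrequencyRow:
    """One row of the disease frequency list: distinct studies per term."""

    name: str
    ui: str
    n_projects: int
    omim_ids: frozenset[int] = frozenset()


@dataclass
class MeshTreeNode:
    """One position in the MeSH disease hierarchy with study counts.

    ``own_count`` counts studies annotated exactly at this tree number;
    ``rolled_count`` counts DISTINCT studies annotated here or anywhere
    below (a study annotated at two descendants counts once).
    """

    tree_number: str
    ui: str
    name: str
    own_count: int = 0
    rolled_count: int = 0
    children: list["MeshTreeNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tree_number": self.tree_number,
            "ui": self.ui,
            "name": self.name,
            "own_count": self.own_count,
            "rolled_count": self.rolled_count,
            "children": [child.to_dict() for child in self.children],
        }


def is_disease_descriptor(descriptor: MeshDescriptor) -> bool:
    """True iff any tree number lies in the C branch or under F03.

    A single qualifying tree number suffices even when the descriptor
    also lives elsewhere in the hierarchy (any-match semantics).  The
    F03 prefix must end at a code boundary, so an F030-style code would
    not qualify.
    """
    for tn in descriptor.tree_numbers:
        if len(tn) > 1 and tn[0] == "C" and tn[1].isdigit():
            return True
        if tn == "F03" or tn.startswith("F03."):
            return True
    return False


def _vocab_index(vocab: Iterable[MeshDescriptor]) -> dict[str, MeshDescriptor]:
    """Look descriptors up by exact preferred name or by UI."""
    index: dict[str, MeshDescriptor] = {}
    for descriptor in vocab:
        index[descriptor.ui] = descriptor
        index[descriptor.name] = descriptor
    return index


def annotate_diseases(
    links: Iterable[LiteratureLink],
    articles: Iterable[ArticleDocument],
    vocab: Iterable[MeshDescriptor],
) -> list[DiseaseAnnotation]:
    """Join study–article links against disease MeSH headings.

    Each (link, disease-passing heading of the linked article) yields an
    annotation; annotations are merged on (study, UI) with supporting
    PMIDs accumulated.  Headings absent from the vocabulary are logged
    and skipped; lexical variants are deliberately not resolved — the
    tree view handles variation structurally.
    """
    index = _vocab_index(vocab)
    by_pmid = {article.pmid: article for article in articles}
    merged: dict[tuple[str, str], DiseaseAnnotation] = {}
    unknown_logged: set[str] = set()
    for link in links:
        article = by_pmid.get(link.pmid)
        if article is None:
            continue
        for heading in article.mesh_headings:
            descriptor = index.get(heading)
            if descriptor is None:
                if heading not in unknown_logged:
                    logger.warning("MeSH heading not in vocabulary: %r", heading)
                    unknown_logged.add(heading)
                continue
            if not is_disease_descriptor(descriptor):
                continue
            key = (link.study_accession, descriptor.ui)
            annotation = merged.get(key)
            if annotation is None:
                merged[key] = DiseaseAnnotation(
                    study_accession=link.study_accession,
                    ui=descriptor.ui,
                    name=descriptor.name,
                    supporting_pmids=[link.pmid],
                )
            elif link.pmid not in annotation.supporting_pmids:
                annotation.supporting_pmids.append(link.pmid)
    annotations = sorted(merged.values(), key=lambda a: (a.study_accession, a.ui))
    for annotation in annotations:
        annotation.supporting_pmids.sort()
    return annotations


def disease_frequency(
    annotations: Iterable[DiseaseAnnotation],
    omim_map: Optional[Mapping[str, set[int]]] = None,
) -> list[FrequencyRow]:
    """Frequency list: distinct studies per disease descriptor.

    Rows are sorted by project count descending, ties broken by name.
    When ``omim_map`` (from :func:`mesh_to_omim`) is given, each row
    carries the OMIM ids reachable for its descriptor — possibly empty,
    mirroring descriptors with no ontology link.
    """
    studies_by_ui: dict[str, set[str]] = {}
    name_by_ui: dict[str, str] = {}
    for annotation in annotations:
        studies_by_ui.setdefault(annotation.ui, set()).add(
            annotation.study_accession
        )
        name_by_ui[annotation.ui] = annotation.name
    rows = [
        FrequencyRow(
            name=name_by_ui[ui],
            ui=ui,
            n_projects=len(studies),
            omim_ids=frozenset(omim_map.get(ui, set())) if omim_map else frozenset(),
        )
        for ui, studies in studies_by_ui.items()
    ]
    return sorted(rows, key=lambda r: (-r.n_projects, r.name))


def _ancestors(tree_number: str) -> list[str]:
    """All proper prefixes of a dotted tree number, shortest first."""
    parts = tree_number.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts) - 1)]


def build_disease_tree(
    annotations: Iterable[DiseaseAnnotation],
    vocab: Iterable[MeshDescriptor],
) -> list[MeshTreeNode]:
    """Arrange annotations on the MeSH hierarchy with rolled-up counts.

    A descriptor with several tree numbers appears at each of its
    positions.  Every ancestor position is materialized so the forest
    is browsable top-down; ``rolled_count`` at a node is the number of
    distinct studies annotated anywhere in its subtree.  Roots and
    children are sorted by tree number.
    """
    annotations = list(annotations)
    tn_by_ui: dict[str, list[str]] = {}
    descriptor_by_tn: dict[str, MeshDescriptor] = {}
    for descriptor in vocab:
        tn_by_ui[descriptor.ui] = list(descriptor.tree_numbers)
        for tn in descriptor.tree_numbers:
            descriptor_by_tn[tn] = descriptor

    own: dict[str, set[str]] = {}
    for annotation in annotations:
        for tn in tn_by_ui.get(annotation.ui, ()):
            own.setdefault(tn, set()).add(annotation.study_accession)

    all_numbers: set[str] = set()
    for tn in own:
        all_numbers.add(tn)
        all_numbers.update(_ancestors(tn))

    nodes: dict[str, MeshTreeNode] = {}
    for tn in all_numbers:
        descriptor = descriptor_by_tn.get(tn)
        nodes[tn] = MeshTreeNode(
            tree_number=tn,
            ui=descriptor.ui if descriptor else "",
            name=descriptor.name if descriptor else "",
            own_count=len(own.get(tn, ())),
        )

    roots: list[MeshTreeNode] = []
    for tn in sorted(all_numbers):
        parent = ".".join(tn.split(".")[:-1])
        if parent and parent in nodes:
            nodes[parent].children.append(nodes[tn])
        else:
            roots.append(nodes[tn])

    def roll(tn: str) -> set[str]:
        studies = set(own.get(tn, ()))
        for child in nodes[tn].children:
            studies |= roll(child.tree_number)
        nodes[tn].rolled_count = len(studies)
        return studies

    for root in roots:
        roll(root.tree_number)
    for node in nodes.values():
        node.children.sort(key=lambda child: child.tree_number)
    return sorted(roots, key=lambda node: node.tree_number)


def mesh_to_omim(terms: Iterable[DoTerm]) -> dict[str, set[int]]:
    """MeSH UI → OMIM ids, mediated by Disease Ontology xrefs.

    A DO term whose xrefs name both a MeSH descriptor and one or more
    OMIM entries contributes those OMIM ids to that descriptor; ids
    accumulate across terms (union).  A MeSH UI that appears in DO but
    never alongside an OMIM xref maps to the empty set — the "no link
    in the ontology" case, distinct from being absent entirely.
    """
    mapping: dict[str, set[int]] = {}
    for term in terms:
        mesh_uis = [xid for ns, xid in term.xrefs if ns.upper() == "MSH"]
        omim_ids: set[int] = set()
        for ns, xid in term.xrefs:
            if ns.upper() != "OMIM":
                continue
            try:
                omim_ids.add(int(xid))
            except ValueError:
                logger.warning("non-numeric OMIM xref %r on %s", xid, term.doid)
        for ui in mesh_uis:
            mapping.setdefault(ui, set()).update(omim_ids)
    return mapping


def gendoo_url(omim_id: int, template: str = DEFAULT_GENDOO_TEMPLATE) -> str:
    """Hyperlink to the Gendoo disease feature profile for an OMIM entry."""
    if omim_id <= 0:
        raise ValueError(f"OMIM id must be positive, got {omim_id}")
    return template.format(omim_id=omim_id)
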