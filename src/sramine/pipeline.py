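"""End-to-end driver: corpus directory in, published lists out.

Glues the stages together in the order the data flows: parse the six
SRA metadata files and build the accession graph; harvest
(study, PMID) pairs from metadata references, article full text, and
the GEO bridge; merge them into the publication list; then derive the
disease association/frequency/tree artifacts from the linked articles'
MeSH headings.  The CLI, the test suite, and the acceptance script all
run the pipeline through this module, so there is exactly one
definition of "the pipeline".

All writers emit UTF-8 TSV (or JSON for the tree) with stable sort
orders, so identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .disease import (
    DiseaseAnnotation,
    FrequencyRow,
    MeshDescriptor,
    MeshTreeNode,
    annotate_diseases,
    build_disease_tree,
    disease_frequency,
    gendoo_url,
    mesh_to_omim,
    parse_do_obo,
    parse_mesh_ascii,
    DEFAULT_GENDOO_TEMPLATE,
)
from .litlink import (
    ArticleDocument,
    GeoRecord,
    LiteratureLink,
    build_geo_bridge,
    load_articles,
    load_manual_pairs,
    merge_publication_list,
    pairs_from_fulltext,
    pairs_via_geo,
    pmids_from_metadata,
    read_soft,
)
from .metadata import (
    AccessionGraph,
    MetadataObject,
    SRA_KINDS,
    build_accession_graph,
    parse_metadata_file,
)

__all__ = [
    "PipelineResult",
    "load_sra_dir",
    "load_geo_soft",
    "build_publication_list",
    "run_pipeline",
    "write_project_list",
    "write_completeness",
    "write_publication_list",
    "write_drop_log",
    "write_disease_associations",
    "write_disease_frequency",
    "write_disease_tree",
    "write_facet_table",
    "read_publication_list",
    "read_pair_tsv",
]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, ready for report writers."""

    graph: AccessionGraph
    articles: list[ArticleDocument]
    geo_records: list[GeoRecord]
    vocab: list[MeshDescriptor]
    links: list[LiteratureLink]
    drop_log: list[tuple[int, str]]
    unresolved_metadata_refs: list[tuple[str, int]]
    annotations: list[DiseaseAnnotation] = field(default_factory=list)
    frequency: list[FrequencyRow] = field(default_factory=list)
    tree: list[MeshTreeNode] = field(default_factory=list)
    omim_map: dict[str, set[int]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, int]]:
        return {link.key for link in self.links}


def load_sra_dir(sra_dir: Path) -> list[MetadataObject]:
    """Parse every ``<kind>.xml`` present under an SRA metadata directory."""
    sra_dir = Path(sra_dir)
    objects: list[MetadataObject] = []
    for kind in SRA_KINDS:
        path = sra_dir / f"{kind.value}.xml"
        if path.exists():
            objects.extend(parse_metadata_file(path, kind))
    return objects


def load_geo_soft(path: Optional[Path]) -> list[GeoRecord]:
    if path is None or not Path(path).exists():
        return []
    return read_soft(Path(path).read_text(encoding="utf-8"))


def build_publication_list(
    graph: AccessionGraph,
    articles: Sequence[ArticleDocument],
    geo_records: Sequence[GeoRecord],
    *,
    hts_only: bool = True,
    use_geo: bool = True,
    manual_path: Optional[Path] = None,
) -> tuple[list[LiteratureLink], list[tuple[int, str]], list[tuple[str, int]]]:
    """Run the three provenance routes and merge.

    Returns ``(links, drop_log, unresolved_metadata_refs)``; the drop
    log lists full-text mentions rejected by the resolution filter.
    ``use_geo=False`` ablates the GEO bridge route entirely.
    """
    metadata_links, unresolved = pmids_from_metadata(graph)
    fulltext_links, drop_log = pairs_from_fulltext(
        articles, graph, hts_only=hts_only
    )
    route_lists = [metadata_links, fulltext_links]
    if use_geo:
        bridge = build_geo_bridge(geo_records, graph)
        route_lists.append(pairs_via_geo(geo_records, articles, bridge))
    if manual_path is not None:
        manual_links, _rejects = load_manual_pairs(manual_path, graph)
        route_lists.append(manual_links)
    return merge_publication_list(*route_lists), drop_log, unresolved


def run_pipeline(
    corpus_dir: Path,
    *,
    hts_only: bool = True,
    use_geo: bool = True,
    manual_path: Optional[Path] = None,
) -> PipelineResult:
    """Run every stage on a corpus directory (the generator's layout)."""
    corpus_dir = Path(corpus_dir)
    graph = build_accession_graph(load_sra_dir(corpus_dir / "sra"))
    medline = corpus_dir / "articles" / "medline.txt"
    articles = (
        load_articles(medline, corpus_dir / "articles" / "fulltext")
        if medline.exists()
        else []
    )
    geo_records = load_geo_soft(corpus_dir / "geo" / "series.soft")
    links, drop_log, unresolved = build_publication_list(
        graph,
        articles,
        geo_records,
        hts_only=hts_only,
        use_geo=use_geo,
        manual_path=manual_path,
    )
    result = PipelineResult(
        graph=graph,
        articles=articles,
        geo_records=geo_records,
        vocab=[],
        links=links,
        drop_log=drop_log,
        unresolved_metadata_refs=unresolved,
    )
    mesh_path = corpus_dir / "vocab" / "mesh.bin"
    if mesh_path.exists():
        result.vocab = parse_mesh_ascii(mesh_path.read_text(encoding="utf-8"))
        result.annotations = annotate_diseases(links, articles, result.vocab)
        obo_path = corpus_dir / "vocab" / "do.obo"
        if obo_path.exists():
            result.omim_map = mesh_to_omim(
                parse_do_obo(obo_path.read_text(encoding="utf-8"))
            )
        result.frequency = disease_frequency(result.annotations, result.omim_map)
        result.tree = build_disease_tree(result.annotations, result.vocab)
    return result


# ---------------------------------------------------------------------------
# Report writers (stable order, UTF-8, tab-separated, header row)


def _open_writer(path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    handle = open(path, "w", encoding="utf-8", newline="")
    return handle, csv.writer(handle, delimiter="\t", lineterminator="\n")


def write_project_list(projects, path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(
            [
                "study_accession",
                "title",
                "study_type",
                "platforms",
                "taxa",
                "n_experiments",
                "n_runs",
            ]
        )
        for project in projects:
            writer.writerow(
                [
                    project.study_accession,
                    project.title or "",
                    project.study_type or "",
                    ",".join(sorted(project.platforms)),
                    ",".join(
                        name or f"taxon:{taxon_id}"
                        for taxon_id, name in sorted(
                            project.taxa, key=lambda t: (t[1] or "", t[0] or 0)
                        )
                    ),
                    project.n_experiments,
                    project.n_runs,
                ]
            )


def write_completeness(profiles, path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(
            ["submission", "study", "experiment", "run", "sample", "analysis", "count"]
        )
        for profile in profiles:
            writer.writerow(
                ["1" if flag else "0" for flag in profile.pattern] + [profile.count]
            )


def write_publication_list(links, graph: Optional[AccessionGraph], path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(
            ["study_accession", "study_title", "pmid", "provenance", "raw_accession"]
        )
        for link in links:
            title = ""
            if graph is not None:
                node = graph.nodes.get(link.study_accession)
                if node is not None and node.title:
                    title = node.title
            writer.writerow(
                [link.study_accession, title, link.pmid, link.provenance,
                 link.raw_accession]
            )


def write_drop_log(drop_log, path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(["pmid", "accession"])
        for pmid, accession in drop_log:
            writer.writerow([pmid, accession])


def write_disease_associations(
    annotations,
    graph: Optional[AccessionGraph],
    omim_map,
    path: Path,
    gendoo_template: str = DEFAULT_GENDOO_TEMPLATE,
) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(
            [
                "study_accession",
                "study_title",
                "ui",
                "disease_name",
                "supporting_pmids",
                "gendoo_url",
            ]
        )
        for annotation in annotations:
            title = ""
            if graph is not None:
                node = graph.nodes.get(annotation.study_accession)
                if node is not None and node.title:
                    title = node.title
            omim_ids = sorted(omim_map.get(annotation.ui, set())) if omim_map else []
            urls = ";".join(
                gendoo_url(omim_id, gendoo_template) for omim_id in omim_ids
            )
            writer.writerow(
                [
                    annotation.study_accession,
                    title,
                    annotation.ui,
                    annotation.name,
                    ",".join(str(p) for p in annotation.supporting_pmids),
                    urls,
                ]
            )


def write_disease_frequency(rows, path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow(["name", "ui", "n_projects", "omim_ids"])
        for row in rows:
            writer.writerow(
                [row.name, row.ui, row.n_projects,
                 ",".join(str(i) for i in sorted(row.omim_ids))]
            )


def write_disease_tree(tree, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [node.to_dict() for node in tree]
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_facet_table(table, facet: str, path: Path) -> None:
    handle, writer = _open_writer(path)
    with handle:
        writer.writerow([facet, "n_studies"])
        for category, count in table:
            writer.writerow([category, count])


# ---------------------------------------------------------------------------
# Readers for round-tripping published lists


def read_publication_list(path: Path) -> list[LiteratureLink]:
    links: list[LiteratureLink] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            links.append(
                LiteratureLink(
                    study_accession=row["study_accession"],
                    pmid=int(row["pmid"]),
                    provenance=row["provenance"],
                    raw_accession=row["raw_accession"],
                )
            )
    return links


def read_pair_tsv(path: Path) -> set[tuple[str, int]]:
    """Read (study, pmid) pairs from a TSV.

    When a header row names ``study_accession`` and ``pmid`` columns,
    those are used (so publication lists and truth tables both work);
    otherwise pairs are taken from the first two columns.
    """
    pairs: set[tuple[str, int]] = set()
    with open(path, encoding="utf-8", newline="") as handle:
        rows = [r for r in csv.reader(handle, delimiter="\t") if r]
    if not rows:
        return pairs
    study_col, pmid_col, start = 0, 1, 0
    header = rows[0]
    if "study_accession" in header and "pmid" in header:
        study_col = header.index("study_accession")
        pmid_col = header.index("pmid")
        start = 1
    for row in rows[start:]:
        if row[study_col].startswith("#"):
            continue
        try:
            pairs.add((row[study_col], int(row[pmid_col])))
        except (ValueError, IndexError):
            continue  # stray header or malformed row
    return pairs
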