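"""Synthetic SRA/MEDLINE/GEO/vocabulary corpus with ground truth.

The real inputs to this pipeline are bulk snapshots of archive
metadata, literature, and vocabularies that are far too large to ship.
This module generates a structurally faithful miniature corpus in the
exact file dialects the parsers consume — six SRA metadata XML files,
a MEDLINE flat file with per-article full texts, a GEO SOFT series
file, a MeSH ASCII descriptor file, and a Disease Ontology OBO file —
together with a :class:`GroundTruth` record of every link and
annotation deliberately planted, so every pipeline stage can be tested
end-to-end against a known answer.

Key emulated properties of the real archive:

* submissions carry incomplete object sets (completeness mix);
* articles cite accessions at study, experiment or run level, so
  resolution through the accession graph is always exercised;
* a configurable fraction of studies keep raw data in GEO (the
  post-May-2011 deposition policy) and are citable only through GEO
  series identifiers — the bridge route is their sole provenance;
* decoy accessions are syntactically valid but absent from the
  metadata, exercising the resolution-time false-positive filter
  rather than the lexical patterns.
"""

from __future__ import annotations

import math
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

from .litlink import HTS_MESH_HEADING, HTS_MESH_UI

__all__ = ["DiseaseSpec", "CorpusConfig", "GroundTruth", "generate_corpus"]

Pattern = tuple[bool, bool, bool, bool, bool, bool]


@dataclass(frozen=True)
class DiseaseSpec:
    """One vocabulary entry the generator can assign to articles."""

    ui: str
    name: str
    tree_numbers: tuple[str, ...]
    omim: Optional[int] = None


#: Diseases echoing the archive's dominant disease annotations; the
#: lung-neoplasms entry deliberately has no OMIM cross-reference in the
#: generated ontology (the "no link" negative case).
DEFAULT_DISEASE_POOL: tuple[DiseaseSpec, ...] = (
    DiseaseSpec("D001943", "Breast Neoplasms",
                ("C04.588.180", "C17.800.090.500"), 114480),
    DiseaseSpec("D011471", "Prostatic Neoplasms",
                ("C04.588.945.440.770", "C12.294.260.750"), 176807),
    DiseaseSpec("D008175", "Lung Neoplasms",
                ("C04.588.894.797.520", "C08.381.540"), None),
    DiseaseSpec("D008288", "Malaria", ("C03.752.250.552",), None),
    DiseaseSpec("D013203", "Staphylococcal Infections", ("C01.252.410.868",), None),
    DiseaseSpec("D003866", "Depressive Disorder", ("F03.600.300",), 608516),
)

#: Non-disease headings (methodology, organisms, psychology-adjacent
#: F02 terms) used to exercise the branch filter's negative side.
DEFAULT_NONDISEASE_POOL: tuple[DiseaseSpec, ...] = (
    DiseaseSpec("D017422", "Sequence Analysis, DNA", ("E05.393.760.700",)),
    DiseaseSpec("D006801", "Humans", ("B01.050.150.900.649.313.988.400.112.400.400",)),
    DiseaseSpec("D003071", "Cognition", ("F02.463.188",)),
    DiseaseSpec("D005075", "Biological Evolution", ("G05.045",)),
)

_HTS_SPEC = DiseaseSpec(HTS_MESH_UI, HTS_MESH_HEADING, ("L01.453.245.945.400",))

_PLATFORMS = (
    "Illumina HiSeq 2000",
    "Illumina Genome Analyzer II",
    "454 GS FLX Titanium",
    "Illumina MiSeq",
    "AB SOLiD 4 System",
)
_PLATFORM_WEIGHTS = (0.40, 0.25, 0.15, 0.12, 0.08)

_STUDY_TYPES = (
    "Whole Genome Sequencing",
    "Transcriptome Analysis",
    "Metagenomics",
    "Epigenetics",
)
_STUDY_TYPE_WEIGHTS = (0.45, 0.25, 0.15, 0.15)

_TAXA = (
    (9606, "Homo sapiens"),
    (10090, "Mus musculus"),
    (7227, "Drosophila melanogaster"),
    (408172, "marine metagenome"),
    (4932, "Saccharomyces cerevisiae"),
)
_TAXON_WEIGHTS = (0.35, 0.25, 0.15, 0.10, 0.15)

_ARCHIVE_LETTERS = "SED"
_ARCHIVE_WEIGHTS = (0.60, 0.25, 0.15)

#: Presence patterns (submission, study, experiment, run, sample,
#: analysis) and their frequencies: most deposits have everything but
#: the optional analysis file, a tail is missing runs, samples, or all
#: sequencing objects.
DEFAULT_COMPLETENESS_MIX: dict[Pattern, float] = {
    (True, True, True, True, True, False): 0.60,
    (True, True, True, True, True, True): 0.10,
    (True, True, True, True, False, False): 0.10,
    (True, True, True, False, True, False): 0.10,
    (True, True, False, False, False, False): 0.10,
}

DEFAULT_CITATION_LEVEL_MIX: dict[str, float] = {
    "study": 0.40,
    "experiment": 0.30,
    "run": 0.30,
}


@dataclass
class CorpusConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    n_studies: int = 20
    experiments_per_study: tuple[int, int] = (1, 3)
    runs_per_experiment: tuple[int, int] = (1, 2)
    completeness_mix: dict[Pattern, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLETENESS_MIX)
    )
    n_articles: int = 30
    citation_level_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CITATION_LEVEL_MIX)
    )
    decoy_rate: float = 0.0
    geo_fraction: float = 0.0
    metadata_ref_rate: float = 0.3
    hts_heading_rate: float = 1.0
    disease_pool: Sequence[DiseaseSpec] = DEFAULT_DISEASE_POOL
    nondisease_pool: Sequence[DiseaseSpec] = DEFAULT_NONDISEASE_POOL
    date_window: tuple[str, str] = ("2009-01-01", "2012-12-31")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 0 or self.n_articles < 0:
            raise ValueError("counts must be non-negative")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")
        for name in ("geo_fraction", "metadata_ref_rate", "hts_heading_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("completeness_mix", "citation_level_mix"):
            mix = getattr(self, name)
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for oracle comparison."""

    true_pairs: set[tuple[str, int]] = field(default_factory=set)
    geo_only_pairs: set[tuple[str, int]] = field(default_factory=set)
    true_geo_bridge: set[tuple[str, str]] = field(default_factory=set)
    true_disease: dict[tuple[str, str], tuple[int, ...]] = field(default_factory=dict)
    decoy_mentions: list[tuple[int, str]] = field(default_factory=list)
    per_submission_pattern: dict[str, Pattern] = field(default_factory=dict)

    def save(self, truth_dir: Path) -> None:
        truth_dir = Path(truth_dir)
        truth_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            truth_dir / "pairs.tsv",
            ["study_accession", "pmid", "geo_only"],
            [
                [s, str(p), "1" if (s, p) in self.geo_only_pairs else "0"]
                for s, p in sorted(self.true_pairs)
            ],
        )
        _write_tsv(
            truth_dir / "geo_bridge.tsv",
            ["geo_accession", "study_accession"],
            [[g, s] for g, s in sorted(self.true_geo_bridge)],
        )
        _write_tsv(
            truth_dir / "disease.tsv",
            ["study_accession", "ui", "pmids"],
            [
                [s, u, ",".join(str(p) for p in pmids)]
                for (s, u), pmids in sorted(self.true_disease.items())
            ],
        )
        _write_tsv(
            truth_dir / "decoys.tsv",
            ["pmid", "accession"],
            [[str(p), a] for p, a in self.decoy_mentions],
        )
        _write_tsv(
            truth_dir / "patterns.tsv",
            ["submission"] + [k for k in
             ("has_submission", "has_study", "has_experiment",
              "has_run", "has_sample", "has_analysis")],
            [
                [sub] + ["1" if flag else "0" for flag in pattern]
                for sub, pattern in sorted(self.per_submission_pattern.items())
            ],
        )

    @classmethod
    def load(cls, truth_dir: Path) -> "GroundTruth":
        truth_dir = Path(truth_dir)
        truth = cls()
        for row in _read_tsv(truth_dir / "pairs.tsv"):
            pair = (row[0], int(row[1]))
            truth.true_pairs.add(pair)
            if row[2] == "1":
                truth.geo_only_pairs.add(pair)
        for row in _read_tsv(truth_dir / "geo_bridge.tsv"):
            truth.true_geo_bridge.add((row[0], row[1]))
        for row in _read_tsv(truth_dir / "disease.tsv"):
            truth.true_disease[(row[0], row[1])] = tuple(
                int(p) for p in row[2].split(",") if p
            )
        for row in _read_tsv(truth_dir / "decoys.tsv"):
            truth.decoy_mentions.append((int(row[0]), row[1]))
        for row in _read_tsv(truth_dir / "patterns.tsv"):
            truth.per_submission_pattern[row[0]] = tuple(
                flag == "1" for flag in row[1:7]
            )  # type: ignore[assignment]
        return truth


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)] + ["\t".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_tsv(path: Path) -> list[list[str]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    return [line.split("\t") for line in lines[1:] if line]


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    threshold = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Internal build records


@dataclass
class _Study:
    index: int
    letter: str
    accession: str
    submission: str
    pattern: Pattern
    study_type: str
    taxon: tuple[int, str]
    title: str = ""
    experiments: list[tuple[str, str]] = field(default_factory=list)  # (acc, platform)
    runs: list[tuple[str, str]] = field(default_factory=list)  # (acc, experiment)
    samples: list[tuple[str, str]] = field(default_factory=list)  # (acc, experiment)
    analyses: list[str] = field(default_factory=list)
    pubmed_refs: list[int] = field(default_factory=list)
    geo_accession: Optional[str] = None
    geo_has_relation: bool = False
    geo_title_mention: bool = False
    received: Optional[date] = None


def generate_corpus(
    config: CorpusConfig, out_dir: Path
) -> GroundTruth:
    """Write a complete synthetic corpus under ``out_dir``.

    The directory layout is::

        sra/{submission,study,experiment,run,sample,analysis}.xml
        articles/medline.txt  articles/fulltext/<pmid>.txt
        geo/series.soft
        vocab/mesh.bin  vocab/do.obo
        truth/*.tsv

    The same config and seed always produce byte-identical files; the
    returned :class:`GroundTruth` (also persisted under ``truth/``)
    exactly describes what was written.
    """
    out_dir = Path(out_dir)
    rng = random.Random(config.seed)

    start = date.fromisoformat(config.date_window[0])
    end = date.fromisoformat(config.date_window[1])
    window_days = max((end - start).days, 0)

    patterns = list(config.completeness_mix)
    pattern_weights = [config.completeness_mix[p] for p in patterns]

    n_geo = round(config.geo_fraction * config.n_studies)
    geo_indices = set(rng.sample(range(config.n_studies), n_geo)) if n_geo else set()

    studies: list[_Study] = []
    exp_counter = run_counter = sample_counter = analysis_counter = 0
    for i in range(config.n_studies):
        letter = rng.choices(_ARCHIVE_LETTERS, _ARCHIVE_WEIGHTS)[0]
        pattern = rng.choices(patterns, pattern_weights)[0]
        if i in geo_indices:
            # a GEO-bridged study must exist as a study record to be
            # resolvable at all
            pattern = (pattern[0], True) + pattern[2:]
        study = _Study(
            index=i,
            letter=letter,
            accession=f"{letter}RP{100001 + i:06d}",
            submission=f"{letter}RA{100001 + i:06d}",
            pattern=pattern,
            study_type=rng.choices(_STUDY_TYPES, _STUDY_TYPE_WEIGHTS)[0],
            taxon=rng.choices(_TAXA, _TAXON_WEIGHTS)[0],
        )
        study.received = start + timedelta(days=rng.randint(0, window_days))
        if pattern[2]:  # experiments
            for _ in range(rng.randint(*config.experiments_per_study)):
                exp_counter += 1
                exp_acc = f"{letter}RX{100000 + exp_counter:06d}"
                platform = rng.choices(_PLATFORMS, _PLATFORM_WEIGHTS)[0]
                study.experiments.append((exp_acc, platform))
                if pattern[4]:  # samples
                    sample_counter += 1
                    study.samples.append(
                        (f"{letter}RS{100000 + sample_counter:06d}", exp_acc)
                    )
                if pattern[3]:  # runs
                    for _ in range(rng.randint(*config.runs_per_experiment)):
                        run_counter += 1
                        study.runs.append(
                            (f"{letter}RR{100000 + run_counter:06d}", exp_acc)
                        )
        if pattern[5]:  # analysis
            analysis_counter += 1
            study.analyses.append(f"{letter}RZ{100000 + analysis_counter:06d}")
        if i in geo_indices:
            study.geo_accession = f"GSE{10001 + i}"
            study.geo_has_relation = rng.random() < 0.7
            study.geo_title_mention = (
                not study.geo_has_relation or rng.random() < 0.3
            )
        title = f"{study.study_type} of {study.taxon[1]}"
        if study.geo_title_mention:
            title += f" (GEO series {study.geo_accession})"
        study.title = title
        # the realized pattern reflects what will actually be written
        # (e.g. runs require experiments, whatever the drawn pattern said)
        study.pattern = (
            pattern[0],
            pattern[1],
            bool(study.experiments),
            bool(study.runs),
            bool(study.samples),
            bool(study.analyses),
        )
        studies.append(study)

    truth = GroundTruth()
    for study in studies:
        if study.pattern[0]:
            truth.per_submission_pattern[study.submission] = study.pattern
        if study.geo_accession and study.pattern[1] and (
            study.geo_has_relation or study.geo_title_mention
        ):
            truth.true_geo_bridge.add((study.geo_accession, study.accession))

    # ------------------------------------------------------------------
    # Articles
    citable = [s for s in studies if s.pattern[1]]
    levels = list(config.citation_level_mix)
    level_weights = [config.citation_level_mix[l] for l in levels]
    geo_record_pmids: dict[str, list[int]] = {}
    articles: list[dict] = []
    decoy_counter = 0
    for j in range(config.n_articles):
        pmid = 20000001 + j
        art: dict = {"pmid": pmid, "headings": [], "citations": [], "sentences": []}
        hts = rng.random() < config.hts_heading_rate
        if hts:
            art["headings"].append(_HTS_SPEC.name)
        n_dis = rng.choice((0, 1, 1, 2))
        diseases = (
            rng.sample(list(config.disease_pool), min(n_dis, len(config.disease_pool)))
            if config.disease_pool
            else []
        )
        art["headings"].extend(d.name for d in diseases)
        n_non = rng.randint(0, 2)
        if config.nondisease_pool and n_non:
            art["headings"].extend(
                d.name
                for d in rng.sample(
                    list(config.nondisease_pool),
                    min(n_non, len(config.nondisease_pool)),
                )
            )

        study = rng.choice(citable) if citable else None
        if study is not None:
            if study.geo_accession:
                cite_in_text = rng.random() < 0.7
                record_pmid = (not cite_in_text) or rng.random() < 0.5
                if cite_in_text:
                    art["citations"].append(study.geo_accession)
                if record_pmid:
                    geo_record_pmids.setdefault(study.geo_accession, []).append(pmid)
                pair = (study.accession, pmid)
                truth.true_pairs.add(pair)
                truth.geo_only_pairs.add(pair)
            else:
                meta_ref = (not hts) or rng.random() < config.metadata_ref_rate
                if meta_ref:
                    study.pubmed_refs.append(pmid)
                available = ["study"]
                if study.experiments:
                    available.append("experiment")
                if study.runs:
                    available.append("run")
                level = rng.choices(levels, level_weights)[0]
                if level not in available:
                    level = "study"
                if level == "study":
                    cited = study.accession
                elif level == "experiment":
                    cited = rng.choice(study.experiments)[0]
                else:
                    cited = rng.choice(study.runs)[0]
                if hts or rng.random() < 0.5:
                    art["citations"].append(cited)
                truth.true_pairs.add((study.accession, pmid))
            for spec in diseases:
                key = (study.accession, spec.ui)
                pmids = set(truth.true_disease.get(key, ()))
                pmids.add(pmid)
                truth.true_disease[key] = tuple(sorted(pmids))

        for _ in range(_poisson(rng, config.decoy_rate)):
            decoy_counter += 1
            decoy = f"SRR{900000 + decoy_counter:06d}"
            art["citations"].append(decoy)
            truth.decoy_mentions.append((pmid, decoy))
        articles.append(art)

    # ------------------------------------------------------------------
    # Write everything
    _write_sra_xml(out_dir / "sra", studies)
    _write_articles(out_dir / "articles", articles)
    _write_soft(out_dir / "geo", studies, geo_record_pmids)
    _write_vocab(out_dir / "vocab", config)
    truth.save(out_dir / "truth")
    return truth


# ---------------------------------------------------------------------------
# Writers


def _write_xml(path: Path, root: ET.Element) -> None:
    ET.indent(root)
    path.write_text(
        ET.tostring(root, encoding="unicode") + "\n", encoding="utf-8"
    )


_VENDOR_TAGS = {"Illumina": "ILLUMINA", "454": "LS454", "AB": "ABI_SOLID"}


def _write_sra_xml(sra_dir: Path, studies: list[_Study]) -> None:
    sra_dir.mkdir(parents=True, exist_ok=True)

    submission_set = ET.Element("SUBMISSION_SET")
    study_set = ET.Element("STUDY_SET")
    experiment_set = ET.Element("EXPERIMENT_SET")
    run_set = ET.Element("RUN_SET")
    sample_set = ET.Element("SAMPLE_SET")
    analysis_set = ET.Element("ANALYSIS_SET")

    for study in studies:
        samples_by_exp = {exp: acc for acc, exp in study.samples}
        if study.pattern[1]:
            elem = ET.SubElement(study_set, "STUDY", accession=study.accession)
            descriptor = ET.SubElement(elem, "DESCRIPTOR")
            ET.SubElement(descriptor, "STUDY_TITLE").text = study.title
            ET.SubElement(
                descriptor, "STUDY_TYPE", existing_study_type=study.study_type
            )
            if study.pubmed_refs:
                links = ET.SubElement(elem, "STUDY_LINKS")
                for pmid in study.pubmed_refs:
                    xref = ET.SubElement(
                        ET.SubElement(links, "STUDY_LINK"), "XREF_LINK"
                    )
                    ET.SubElement(xref, "DB").text = "pubmed"
                    ET.SubElement(xref, "ID").text = str(pmid)
        for exp_acc, platform in study.experiments:
            elem = ET.SubElement(
                experiment_set, "EXPERIMENT", accession=exp_acc
            )
            ET.SubElement(elem, "TITLE").text = f"{platform} sequencing"
            ET.SubElement(elem, "STUDY_REF", accession=study.accession)
            design = ET.SubElement(elem, "DESIGN")
            if exp_acc in samples_by_exp:
                ET.SubElement(
                    design, "SAMPLE_DESCRIPTOR", accession=samples_by_exp[exp_acc]
                )
            platform_elem = ET.SubElement(elem, "PLATFORM")
            vendor = ET.SubElement(platform_elem, _VENDOR_TAGS.get(
                platform.split()[0], "UNSPECIFIED"))
            ET.SubElement(vendor, "INSTRUMENT_MODEL").text = platform
        for run_acc, exp_acc in study.runs:
            elem = ET.SubElement(run_set, "RUN", accession=run_acc)
            ET.SubElement(elem, "EXPERIMENT_REF", accession=exp_acc)
        for sample_acc, _ in study.samples:
            elem = ET.SubElement(sample_set, "SAMPLE", accession=sample_acc)
            name = ET.SubElement(elem, "SAMPLE_NAME")
            ET.SubElement(name, "TAXON_ID").text = str(study.taxon[0])
            ET.SubElement(name, "SCIENTIFIC_NAME").text = study.taxon[1]
        for analysis_acc in study.analyses:
            elem = ET.SubElement(analysis_set, "ANALYSIS", accession=analysis_acc)
            ET.SubElement(elem, "STUDY_REF", accession=study.accession)
        if study.pattern[0]:
            elem = ET.SubElement(
                submission_set,
                "SUBMISSION",
                accession=study.submission,
                received=study.received.isoformat() if study.received else "",
            )
            if study.pattern[1]:
                ET.SubElement(elem, "STUDY_REF", accession=study.accession)
            for exp_acc, _ in study.experiments:
                ET.SubElement(elem, "EXPERIMENT_REF", accession=exp_acc)
            for run_acc, _ in study.runs:
                ET.SubElement(elem, "RUN_REF", accession=run_acc)
            for sample_acc, _ in study.samples:
                ET.SubElement(elem, "SAMPLE_REF", accession=sample_acc)
            for analysis_acc in study.analyses:
                ET.SubElement(elem, "ANALYSIS_REF", accession=analysis_acc)

    _write_xml(sra_dir / "submission.xml", submission_set)
    _write_xml(sra_dir / "study.xml", study_set)
    _write_xml(sra_dir / "experiment.xml", experiment_set)
    _write_xml(sra_dir / "run.xml", run_set)
    _write_xml(sra_dir / "sample.xml", sample_set)
    _write_xml(sra_dir / "analysis.xml", analysis_set)


def _write_articles(articles_dir: Path, articles: list[dict]) -> None:
    fulltext_dir = articles_dir / "fulltext"
    fulltext_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for art in articles:
        lines = [f"PMID- {art['pmid']}", "TI  - A high-throughput sequencing study."]
        lines += [f"MH  - {heading}" for heading in art["headings"]]
        records.append("\n".join(lines))
        fulltext_dir.joinpath(f"{art['pmid']}.txt").write_text(
            _render_fulltext(art), encoding="utf-8"
        )
    (articles_dir / "medline.txt").write_text(
        "\n\n".join(records) + "\n", encoding="utf-8"
    )


def _render_fulltext(art: dict) -> str:
    paragraphs = [
        "We sequenced samples on a massively parallel platform and analysed "
        "the resulting reads with the SRAdb package and custom scripts.",
    ]
    for citation in art["citations"]:
        paragraphs.append(
            f"The data generated in this study are available under accession "
            f"{citation}."
        )
    paragraphs.append(
        "Processed matrices are described in the supplementary material."
    )
    return "\n\n".join(paragraphs) + "\n"


def _write_soft(
    geo_dir: Path, studies: list[_Study], geo_record_pmids: dict[str, list[int]]
) -> None:
    geo_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    for study in studies:
        if not study.geo_accession:
            continue
        gse = study.geo_accession
        lines.append(f"^SERIES = {gse}")
        lines.append(f"!Series_geo_accession = {gse}")
        lines.append(f"!Series_title = {study.title}")
        for pmid in geo_record_pmids.get(gse, []):
            lines.append(f"!Series_pubmed_id = {pmid}")
        if study.geo_has_relation:
            lines.append(
                "!Series_relation = SRA: "
                f"https://www.ncbi.nlm.nih.gov/sra?term={study.accession}"
            )
    (geo_dir / "series.soft").write_text(
        ("\n".join(lines) + "\n") if lines else "", encoding="utf-8"
    )


def _write_vocab(vocab_dir: Path, config: CorpusConfig) -> None:
    vocab_dir.mkdir(parents=True, exist_ok=True)
    specs = [_HTS_SPEC, *config.disease_pool, *config.nondisease_pool]
    records = []
    for spec in specs:
        lines = ["*NEWRECORD", f"MH = {spec.name}"]
        lines += [f"MN = {tn}" for tn in spec.tree_numbers]
        lines.append(f"UI = {spec.ui}")
        records.append("\n".join(lines))
    (vocab_dir / "mesh.bin").write_text(
        "\n\n".join(records) + "\n", encoding="utf-8"
    )

    stanzas = [
        "format-version: 1.2",
        "ontology: synthetic-disease-ontology",
    ]
    doid = 0
    for spec in config.disease_pool:
        doid += 1
        stanza = [
            "[Term]",
            f"id: DOID:{9000 + doid}",
            f"name: {spec.name.lower()}",
            f"xref: MSH:{spec.ui}",
        ]
        if spec.omim is not None:
            stanza.append(f"xref: OMIM:{spec.omim}")
        stanzas.append("\n".join(stanza))
    # an obsolete term whose mapping must NOT leak into the output
    stanzas.append(
        "\n".join(
            [
                "[Term]",
                "id: DOID:9999",
                "name: retired synthetic entry",
                "xref: MSH:D999999",
                "xref: OMIM:999999",
                "is_obsolete: true",
            ]
        )
    )
    (vocab_dir / "do.obo").write_text("\n\n".join(stanzas) + "\n", encoding="utf-8")
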