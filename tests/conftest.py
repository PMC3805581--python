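import pytest

from sramine.accessions import AccessionKind
from sramine.corpus import CorpusConfig, generate_corpus
from sramine.metadata import MetadataObject, build_accession_graph


@pytest.fixture(scope="session")
def clean_corpus(tmp_path_factory):
    """Clean fixture corpus: no decoys, everything hosted in SRA."""
    corpus_dir = tmp_path_factory.mktemp("clean_corpus")
    truth = generate_corpus(
        CorpusConfig(n_studies=20, n_articles=30, decoy_rate=0.0,
                     geo_fraction=0.0, seed=7),
        corpus_dir,
    )
    return corpus_dir, truth


@pytest.fixture(scope="session")
def decoy_corpus(tmp_path_factory):
    """Corpus whose articles also cite decoy accessions absent from SRA."""
    corpus_dir = tmp_path_factory.mktemp("decoy_corpus")
    truth = generate_corpus(
        CorpusConfig(n_studies=20, n_articles=30, decoy_rate=2.0,
                     geo_fraction=0.0, seed=7),
        corpus_dir,
    )
    return corpus_dir, truth


@pytest.fixture(scope="session")
def geo_corpus(tmp_path_factory):
    """Corpus where 30% of studies are reachable only via the GEO bridge."""
    corpus_dir = tmp_path_factory.mktemp("geo_corpus")
    truth = generate_corpus(
        CorpusConfig(n_studies=20, n_articles=30, decoy_rate=0.0,
                     geo_fraction=0.3, seed=11),
        corpus_dir,
    )
    return corpus_dir, truth


def chain_objects():
    """A minimal run -> experiment -> study chain plus satellites."""
    return [
        MetadataObject(kind=AccessionKind.STUDY, accession="SRP000010",
                       title="Whole genome of a test organism",
                       study_type="Whole Genome Sequencing"),
        MetadataObject(kind=AccessionKind.EXPERIMENT, accession="SRX000050",
                       instrument_model="Illumina HiSeq 2000",
                       references=[(AccessionKind.STUDY, "SRP000010"),
                                   (AccessionKind.SAMPLE, "SRS000007")]),
        MetadataObject(kind=AccessionKind.RUN, accession="SRR000101",
                       references=[(AccessionKind.EXPERIMENT, "SRX000050")]),
        MetadataObject(kind=AccessionKind.SAMPLE, accession="SRS000007",
                       taxon_id=9606, scientific_name="Homo sapiens"),
        MetadataObject(kind=AccessionKind.SUBMISSION, accession="SRA000001",
                       references=[(AccessionKind.STUDY, "SRP000010"),
                                   (AccessionKind.EXPERIMENT, "SRX000050"),
                                   (AccessionKind.RUN, "SRR000101"),
                                   (AccessionKind.SAMPLE, "SRS000007")]),
    ]


@pytest.fixture
def chain_graph():
    return build_accession_graph(chain_objects())
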