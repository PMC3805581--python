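"""XML parsing, accession graph construction, resolution, summaries."""

import random

import pytest

from _oracles import (
    index_objects,
    oracle_completeness,
    oracle_resolve,
    random_graph_objects,
)
from sramine.accessions import AccessionKind
from sramine.metadata import (
    MetadataObject,
    MetadataParseError,
    MetadataRecordError,
    build_accession_graph,
    completeness_profiles,
    parse_metadata,
    resolve_to_study,
    summarize_projects,
    tabulate_by,
)

STUDY_DOC = """
<STUDY_SET>
  <STUDY accession="SRP000001">
    <DESCRIPTOR>
      <STUDY_TITLE>Test genome</STUDY_TITLE>
      <STUDY_TYPE existing_study_type="Whole Genome Sequencing"/>
    </DESCRIPTOR>
    <STUDY_LINKS>
      <STUDY_LINK><XREF_LINK><DB>pubmed</DB><ID>19015660</ID></XREF_LINK></STUDY_LINK>
    </STUDY_LINKS>
    <UNKNOWN_ELEMENT><DEEPLY/></UNKNOWN_ELEMENT>
  </STUDY>
</STUDY_SET>
"""

EXPERIMENT_DOC = """
<EXPERIMENT_SET>
  <EXPERIMENT accession="SRX000001">
    <STUDY_REF accession="SRP000001"/>
    <DESIGN><SAMPLE_DESCRIPTOR accession="SRS000007"/></DESIGN>
    <PLATFORM><ILLUMINA><INSTRUMENT_MODEL>Illumina HiSeq 2000</INSTRUMENT_MODEL></ILLUMINA></PLATFORM>
  </EXPERIMENT>
</EXPERIMENT_SET>
"""


class TestParsing:
    def test_study_record(self):
        (obj,) = parse_metadata(STUDY_DOC, AccessionKind.STUDY)
        assert obj.kind is AccessionKind.STUDY
        assert obj.accession == "SRP000001"
        assert obj.title == "Test genome"
        assert obj.study_type == "Whole Genome Sequencing"
        assert obj.pubmed_refs == [19015660]

    def test_experiment_references_and_platform(self):
        (obj,) = parse_metadata(EXPERIMENT_DOC, "experiment")
        assert set(obj.references) == {
            (AccessionKind.STUDY, "SRP000001"),
            (AccessionKind.SAMPLE, "SRS000007"),
        }
        assert obj.instrument_model == "Illumina HiSeq 2000"

    def test_sample_taxon(self):
        doc = (
            '<SAMPLE_SET><SAMPLE accession="SRS000007"><SAMPLE_NAME>'
            "<TAXON_ID>9606</TAXON_ID><SCIENTIFIC_NAME>Homo sapiens"
            "</SCIENTIFIC_NAME></SAMPLE_NAME></SAMPLE></SAMPLE_SET>"
        )
        (obj,) = parse_metadata(doc, "sample")
        assert (obj.taxon_id, obj.scientific_name) == (9606, "Homo sapiens")

    def test_xref_link_attribute_form_also_accepted(self):
        doc = (
            '<STUDY_SET><STUDY accession="SRP1"><STUDY_LINKS>'
            '<XREF_LINK DB="pubmed" ID="123"/>'
            "</STUDY_LINKS></STUDY></STUDY_SET>"
        )
        (obj,) = parse_metadata(doc, "study")
        assert obj.pubmed_refs == [123]

    def test_duplicate_pubmed_refs_collapsed(self):
        doc = (
            '<STUDY_SET><STUDY accession="SRP1">'
            '<XREF_LINK DB="pubmed" ID="123"/><XREF_LINK DB="pubmed" ID="123"/>'
            "</STUDY></STUDY_SET>"
        )
        (obj,) = parse_metadata(doc, "study")
        assert obj.pubmed_refs == [123]

    def test_malformed_xml_names_byte_offset(self):
        with pytest.raises(MetadataParseError, match="byte offset"):
            parse_metadata("<STUDY_SET><STUDY></STUDY_SET>", "study")

    def test_missing_accession_names_element_path(self):
        doc = "<RUN_SET><RUN accession='SRR1'/><RUN/></RUN_SET>"
        with pytest.raises(MetadataRecordError, match=r"RUN_SET/RUN\[2\]"):
            parse_metadata(doc, "run")

    def test_empty_set_yields_no_records(self):
        assert parse_metadata("<RUN_SET/>", "run") == []


class TestGraph:
    def test_direct_construction(self):
        objects = [
            MetadataObject(kind=AccessionKind.STUDY, accession="SRP100001"),
            MetadataObject(
                kind=AccessionKind.EXPERIMENT,
                accession="SRX100001",
                references=[(AccessionKind.STUDY, "SRP100001")],
            ),
            MetadataObject(
                kind=AccessionKind.RUN,
                accession="SRR100001",
                references=[(AccessionKind.EXPERIMENT, "SRX100001")],
            ),
        ]
        g = build_accession_graph(objects)
        assert len(g.nodes) == 3
        assert g.graph.number_of_edges() == 2
        assert g.dangling == set()

    def test_dangling_reference_recorded(self):
        objects = [
            MetadataObject(
                kind=AccessionKind.EXPERIMENT,
                accession="SRX100001",
                references=[(AccessionKind.STUDY, "SRP999999")],
            )
        ]
        g = build_accession_graph(objects)
        assert g.dangling == {("SRX100001", "SRP999999")}

    def test_empty_input(self):
        g = build_accession_graph([])
        assert g.nodes == {} and g.dangling == set()

    def test_duplicate_accession_last_wins_with_warning(self, caplog):
        objects = [
            MetadataObject(kind=AccessionKind.STUDY, accession="SRP100001",
                           title="first"),
            MetadataObject(kind=AccessionKind.STUDY, accession="SRP100001",
                           title="second"),
        ]
        with caplog.at_level("WARNING"):
            g = build_accession_graph(objects)
        assert g.nodes["SRP100001"].title == "second"
        assert any("duplicate" in record.message for record in caplog.records)


class TestResolution:
    def test_chain_resolves_to_study(self, chain_graph):
        assert resolve_to_study(chain_graph, "SRR000101") == {"SRP000010"}
        assert resolve_to_study(chain_graph, "SRX000050") == {"SRP000010"}
        assert resolve_to_study(chain_graph, "SRS000007") == {"SRP000010"}
        assert resolve_to_study(chain_graph, "SRA000001") == {"SRP000010"}

    def test_study_resolves_to_itself(self, chain_graph):
        assert resolve_to_study(chain_graph, "SRP000010") == {"SRP000010"}

    def test_unknown_but_valid_accession_gives_empty_set(self, chain_graph):
        assert resolve_to_study(chain_graph, "SRR999999") == set()

    def test_invalid_accession_raises(self, chain_graph):
        with pytest.raises(ValueError):
            resolve_to_study(chain_graph, "not-an-accession")
        with pytest.raises(ValueError):
            resolve_to_study(chain_graph, "GSE1234")  # GEO ids are not SRA ids

    def test_versioned_accession_normalized(self, chain_graph):
        assert resolve_to_study(chain_graph, "SRR000101.1") == {"SRP000010"}

    def test_idempotence(self, chain_graph):
        for study in resolve_to_study(chain_graph, "SRR000101"):
            assert resolve_to_study(chain_graph, study) == {study}

    def test_agrees_with_bruteforce_oracle_on_random_graphs(self):
        rng = random.Random(20121001)
        for _ in range(30):
            objects = random_graph_objects(rng)
            g = build_accession_graph(objects)
            by_acc = index_objects(objects)
            for accession in g.nodes:
                assert resolve_to_study(g, accession) == oracle_resolve(
                    by_acc, accession
                ), accession


class TestSummaries:
    def test_completeness_single_pattern(self):
        objects = []
        for i in range(3):
            study = f"SRP10000{i}"
            exp, run, sample = f"SRX10000{i}", f"SRR10000{i}", f"SRS10000{i}"
            objects += [
                MetadataObject(kind=AccessionKind.STUDY, accession=study),
                MetadataObject(kind=AccessionKind.EXPERIMENT, accession=exp,
                               references=[(AccessionKind.STUDY, study),
                                           (AccessionKind.SAMPLE, sample)]),
                MetadataObject(kind=AccessionKind.RUN, accession=run,
                               references=[(AccessionKind.EXPERIMENT, exp)]),
                MetadataObject(kind=AccessionKind.SAMPLE, accession=sample),
                MetadataObject(kind=AccessionKind.SUBMISSION,
                               accession=f"SRA10000{i}",
                               references=[(AccessionKind.STUDY, study),
                                           (AccessionKind.EXPERIMENT, exp),
                                           (AccessionKind.RUN, run),
                                           (AccessionKind.SAMPLE, sample)]),
            ]
        profiles = completeness_profiles(build_accession_graph(objects))
        assert len(profiles) == 1
        assert profiles[0].pattern == (True, True, True, True, True, False)
        assert profiles[0].count == 3

    def test_completeness_partitions_submissions_on_random_graphs(self):
        rng = random.Random(42)
        for _ in range(20):
            objects = random_graph_objects(rng)
            g = build_accession_graph(objects)
            profiles = completeness_profiles(g)
            n_submissions = sum(
                1 for o in g.nodes.values()
                if o.kind is AccessionKind.SUBMISSION
            )
            assert sum(p.count for p in profiles) == n_submissions
            expected = oracle_completeness(index_objects(objects))
            from collections import Counter
            assert Counter(expected.values()) == Counter(
                {p.pattern: p.count for p in profiles}
            )

    def test_empty_graph_has_no_profiles(self):
        assert completeness_profiles(build_accession_graph([])) == []

    def test_project_summary_counts_match_bruteforce(self):
        rng = random.Random(7)
        for _ in range(10):
            objects = random_graph_objects(rng)
            g = build_accession_graph(objects)
            by_acc = index_objects(objects)
            for summary in summarize_projects(g):
                study = summary.study_accession
                n_exp = sum(
                    1
                    for acc, o in g.nodes.items()
                    if o.kind is AccessionKind.EXPERIMENT
                    and study in oracle_resolve(by_acc, acc)
                )
                n_run = sum(
                    1
                    for acc, o in g.nodes.items()
                    if o.kind is AccessionKind.RUN
                    and study in oracle_resolve(by_acc, acc)
                )
                assert summary.n_experiments == n_exp
                assert summary.n_runs == n_run

    def test_project_platforms_aggregate(self, chain_graph):
        (summary,) = summarize_projects(chain_graph)
        assert summary.platforms == {"Illumina HiSeq 2000"}
        assert summary.taxa == {(9606, "Homo sapiens")}
        assert summary.submissions == {"SRA000001"}

    def test_study_without_experiments(self):
        g = build_accession_graph(
            [MetadataObject(kind=AccessionKind.STUDY, accession="SRP100001")]
        )
        (summary,) = summarize_projects(g)
        assert summary.n_experiments == 0 and summary.platforms == set()


class TestFacets:
    def _projects(self):
        from sramine.metadata import ProjectSummary

        return [
            ProjectSummary("SRP1", None, "Whole Genome Sequencing",
                           {"Illumina HiSeq 2000"}, {(9606, "Homo sapiens")},
                           1, 1, set()),
            ProjectSummary("SRP2", None, "Transcriptome Analysis",
                           {"Illumina HiSeq 2000", "454 GS FLX Titanium"},
                           {(9606, "Homo sapiens"), (10090, "Mus musculus")},
                           2, 2, set()),
        ]

    def test_multi_species_study_counts_in_each_category(self):
        table = tabulate_by(self._projects(), "taxon")
        assert table == [("Homo sapiens", 2), ("Mus musculus", 1)]
        assert sum(count for _, count in table) == 3  # exceeds the 2 studies

    def test_platform_and_study_type_facets(self):
        assert tabulate_by(self._projects(), "platform")[0] == (
            "Illumina HiSeq 2000",
            2,
        )
        assert dict(tabulate_by(self._projects(), "study_type")) == {
            "Whole Genome Sequencing": 1,
            "Transcriptome Analysis": 1,
        }

    def test_unknown_facet_rejected(self):
        with pytest.raises(ValueError):
            tabulate_by([], "color")

    def test_empty_projects(self):
        assert tabulate_by([], "taxon") == []
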