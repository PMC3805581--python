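# sramine

Mining and characterization of Sequence Read Archive (SRA) metadata:
accession-mapping graphs, study–publication linking, and MeSH-based
disease indexing.

## The problem

The SRA is the INSDC's primary archive for high-throughput sequencing
data. Finding *usable* data in it is hard: each deposition is spread
over up to six cross-referencing XML metadata objects (submission,
study, experiment, run, sample, analysis), most submissions carry only
a partial object set, experimental context lives in free text, and
there is no quality control at submission time. A practical quality
proxy is citation: a study that a peer-reviewed article refers to is
worth finding.

`sramine` is a toolkit for curators and archive miners that

1. **parses the six metadata object types** and builds a directed
   accession graph, so any accession (a run `SRR…`, an experiment
   `SRX…`, a sample `SRS…`, a submission `SRA…`, across the NCBI/EBI/DDBJ
   prefix families) resolves to the study/project (`SRP…/ERP…/DRP…`)
   it belongs to — relationships are one-to-many, so resolution returns
   a *set* of studies;
2. **links studies to publications** through three provenance routes:
   PubMed IDs cited inside the metadata itself, SRA accessions extracted
   from article full text by pattern matching, and GEO series/dataset
   identifiers bridging articles to studies whose raw data lives in GEO
   (the post-2011 deposition route for RNA-Seq/ChIP-Seq/epigenomics).
   Full-text mentions that resolve to no known study are treated as
   false positives and dropped into a machine-readable log — the
   resolution-time omission filter that keeps the merged publication
   list precise;
3. **indexes studies by disease** by joining linked articles' MeSH
   headings against the vocabulary, keeping descriptors in the
   Diseases \[C\] branch or Mental Disorders \[F03\] sub-branch,
   and deriving a frequency list, a browsable MeSH tree view with
   distinct-study roll-up counts, and MeSH→OMIM mappings mediated by
   Disease Ontology xrefs (rendered as Gendoo hyperlinks).

Because the real inputs are bulk archive snapshots, the package ships a
**synthetic corpus generator** that writes all input dialects (SRA XML,
MEDLINE flat file, plain-text full texts, GEO SOFT, MeSH ASCII, DO OBO)
together with the ground truth of every planted link — the whole
pipeline is developed and verified offline.

## Worked example

```sh
sramine fixtures --out corpus --seed 7 --n-studies 20 --n-articles 30 --decoy-rate 2.0
sramine index   --sra-dir corpus/sra --out out
sramine litlink --corpus-dir corpus --out out
sramine disease --corpus-dir corpus --out out
sramine evaluate --predicted out/publications.tsv --gold corpus/truth/pairs.tsv
```

The `litlink` step reports

```
30 links, 62 dropped mentions
```

meaning all 30 planted study–article pairs were recovered and all 62
decoy accession mentions (syntactically valid, but absent from the
metadata) were rejected by the resolution filter — and `evaluate`
prints

```
tp=30   fp=0    fn=0    precision=1.0000        recall=1.0000
```

`out/publications.tsv` then holds rows like

```
study_accession  study_title                          pmid      provenance       raw_accession
ERP100003        Metagenomics of Homo sapiens         20000026  fulltext_direct  ERX100003
```

(the article cited an experiment-level accession; the graph resolved it
to its study), and `out/disease_frequency.tsv` starts

```
name                       ui       n_projects  omim_ids
Malaria                    D008288  7
Staphylococcal Infections  D013203  5
Prostatic Neoplasms        D011471  4           176807
```

where `n_projects` counts distinct studies per disease descriptor and
`omim_ids` carries the Disease-Ontology-mediated OMIM link when one
exists (descriptors without a DO→OMIM path, such as Lung Neoplasms,
stay blank).

## Layout

- `src/sramine/accessions.py` — accession grammar, classification, text extraction
- `src/sramine/metadata.py` — XML object model, accession graph, resolution, summaries
- `src/sramine/litlink.py` — the three literature routes, merge, evaluation
- `src/sramine/disease.py`, `disease_vocab.py` — MeSH/DO parsing, disease index
- `src/sramine/corpus.py` — synthetic corpus generator with ground truth
- `src/sramine/pipeline.py` — end-to-end driver and report writers
- `src/sramine/cli.py` — `sramine` command-line interface
- `docs/methods.md` — models, conventions, and design notes
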