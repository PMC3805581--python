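# Methods

## Data model and accession resolution

SRA metadata arrives as six XML files — submission, study, experiment,
run, sample, analysis — whose records cross-reference each other by
accession. We parse a minimal dialect of the public schema: record
elements carry an `accession` attribute; studies carry
`DESCRIPTOR/STUDY_TITLE` and `STUDY_TYPE@existing_study_type`;
experiments carry `STUDY_REF`, `DESIGN/SAMPLE_DESCRIPTOR`, and
`PLATFORM/*/INSTRUMENT_MODEL`; runs carry `EXPERIMENT_REF`; samples
carry `SAMPLE_NAME/TAXON_ID` and `SCIENTIFIC_NAME`; any record may
carry `XREF_LINK` entries with `DB`=pubmed (child-element or attribute
form). Everything else is ignored, so richer real-archive dumps still
parse. Accessions are uppercased and version suffixes (`SRR000001.1`)
stripped; duplicate accessions are merged last-wins with a warning
(deterministic for incremental dumps); references to absent accessions
are kept as *dangling* data rather than dropped, because unresolvable
references are exactly what the downstream false-positive filter acts
on.

Resolution of an accession to its study follows the typed topology
only: run → experiment → study, sample ← experiment → study (samples
are pointed *at* by experiments, so the edge is walked backwards,
without continuing through other samples), analysis → study,
submission → each owned object, study → itself. The result is a set:
object relationships are one-to-many and we never pick a
representative. A syntactically invalid token raises; a valid but
unknown accession resolves to the empty set — two deliberately
distinct outcomes. Correctness is checked against a brute-force
transitive-closure oracle written independently of the graph code
(plain dicts, exhaustive walking) on hundreds of randomized graphs
with dangling links, shared samples, and one-to-many links in both
directions.

Per-submission completeness patterns count a kind as present when any
record of that kind is reachable from the submission through reference
links. Project summaries define experiment/run membership by
resolution, so an experiment referencing two studies counts in both.
Facet tables (study type, platform, species) count a study once per
category it carries; totals may therefore exceed the number of
studies, which is the intended reading of multi-species studies.

## Accession grammar

SRA accessions are `[SED]R[APXRSZ]` + digits (first letter = archive
NCBI/EBI/DDBJ; third letter = object kind, with `Z` = analysis
included for completeness); GEO accessions are `GSE`/`GDS` + digits.
We require ≥5 digits for SRA tokens — real accessions carry ≥6, the
margin tolerates compact synthetic corpora, and the floor is what
keeps prose tokens like "SRAdb" from matching. GEO requires ≥1 digit.
Matches must be bounded by non-alphanumeric characters on both sides;
hyphens and dots delimit, so `(SRR123456).` matches and version
suffixes are left outside the match. Matching is uppercase-only by
default with a case-insensitive opt-in, because mixed-case tokens in
prose are rarely identifiers.

## Literature linking

Three routes produce (study, PMID) pairs, each tagged with provenance:

1. **metadata_ref** — PubMed cross-links inside any metadata object,
   resolved to the object's studies; objects that resolve nowhere are
   reported separately, never silently emitted.
2. **fulltext_direct** — accessions extracted from article full text
   (restricted by default to articles carrying the
   "High-Throughput Nucleotide Sequencing" MeSH heading, the route
   where that restriction is meaningful), resolved to studies.
   Mentions resolving to the empty set are dropped and logged, one
   drop-log entry per mention: an accession with no project behind it
   has no study title, platform, or links to offer, so it is treated
   as a false positive. This filter operates at resolution time, not
   at regex time — decoys in the test corpora are deliberately
   pattern-valid.
3. **geo_bridge** — GEO–SRA identifier pairs assembled from both sides
   (SRA accessions in GEO `relation` fields, GEO accessions in SRA
   study titles, deduplicated with the GEO-record side preferred),
   crossed with article–GEO attachments from GEO `pubmed_id` fields
   and GEO accessions cited in article full text.

Routes merge by set union on the (study, PMID) key; on collision the
highest-priority provenance is kept (metadata_ref > fulltext_direct >
geo_bridge > manual — an ordering chosen purely for deterministic
output). Manually curated pairs enter from a TSV side file and bypass
extraction but must still resolve. Precision/recall against a gold
pair set use the standard set formulas, with undefined (not zero)
values on empty denominators.

## Disease indexing

Article MeSH headings (matched by exact preferred name or UI;
MEDLINE major-topic stars and qualifiers are stripped; lexical
variants are *not* resolved — the tree view is the structural answer
to variation) are joined to linked studies. A descriptor counts as
disease when **any** of its tree numbers lies in the C branch
(`C` + digit) or under F03 at a code boundary (`F03` or `F03.…`);
any-match is the permissive reading consistent with symptom terms
appearing in disease lists. The frequency list counts distinct
studies per descriptor. The tree view materializes every annotated
tree number and all ancestors; a multi-position descriptor appears at
each position; `rolled_count` is the number of distinct studies in
the subtree, verified against a brute-force subtree union.

MeSH→OMIM mapping goes through Disease Ontology terms: a term whose
xrefs name both a MeSH descriptor and OMIM entries contributes those
entries (union across terms); a descriptor present in DO without an
OMIM co-mention maps to the empty set, which is reported as "no
link" rather than omitted. Obsolete DO terms are excluded. Gendoo
hyperlinks are produced from a configurable URL template.

## Synthetic corpus generator

The generator emulates the features of the real ecosystem that the
pipeline logic depends on, with defaults fixed once:

- **20 studies, 30 articles** (the canonical clean-corpus size used
  throughout testing), 1–3 experiments per study, 1–2 runs per
  experiment; archive prefixes drawn S/E/D at 60/25/15%.
- **Completeness mix**: 60% full-minus-analysis, 10% with analysis,
  10% missing samples, 10% missing runs, 10% study-only — submissions
  with partial object sets are the archive's normal state, not an
  edge case.
- **Citation levels**: articles cite study/experiment/run accessions
  at 40/30/30%, so study resolution is always on the critical path;
  pairs are additionally recorded as metadata PubMed references at
  rate 0.3. Articles lacking the HTS MeSH heading (rate configurable,
  default 1.0) have their pair forced through the metadata route, so
  the full-text HTS restriction never silently loses ground truth.
- **GEO-hosted fraction** (default 0 — metagenome-style corpora; 0.3
  in bridge tests): these studies are citable *only* via their GEO
  series — through the record's `pubmed_id`, a full-text GSE mention,
  an explicit SRA relation line, and/or a GSE mention in the SRA study
  title — so ablating the bridge route loses exactly these pairs.
- **Decoys**: per-article Poisson counts of globally unique,
  pattern-valid, graph-absent run accessions, recorded mention by
  mention so the drop log can be compared exactly.
- **Vocabulary**: six disease descriptors (including an F03 term, a
  descriptor with two tree positions, and one whose DO term lacks an
  OMIM xref) and four non-disease descriptors including an F02
  boundary probe; the DO file also plants an obsolete term whose
  mapping must not leak through.
- Platform, study-type, and taxon pools echo the archive's dominant
  categories (Illumina/454/SOLiD instruments; genome, transcriptome,
  metagenome, epigenetics study types; human, mouse, fly, marine
  metagenome, yeast).

All randomness flows from one `random.Random(seed)`; files are written
with fixed ordering and formatting, so a config+seed pair is
byte-reproducible — asserted by hashing every generated file and every
pipeline output across repeated runs.

What the generator does **not** emulate: natural-language noise around
accessions beyond simple templates, OCR/PDF artifacts, journal-site
markup, citation-context ambiguity, MEDLINE fields beyond PMID/TI/MH,
and real vocabulary scale (tens of descriptors, not 23 000+). Passing
tests therefore demonstrate the correctness of the graph, routing,
filtering, and indexing *mechanisms* under known ground truth — not
extraction accuracy on real journal prose, which depends on corpus
properties no desk-scale fixture can represent.

## Numerical and formatting conventions

- All outputs are UTF-8 TSV (or JSON for the tree) with header rows,
  stable sort orders (counts descending, then name/accession), and
  comma-joined multi-values; identical inputs give byte-identical
  outputs.
- Frequency rows tie-break by name ascending; completeness profiles
  by count descending then pattern; publication lists by study then
  PMID.
- Expected ablation recall is computed with the same integer division
  as the evaluator (`(n_true − n_geo_only) / n_true`) so the
  comparison is exact rather than tolerance-based.
- Degenerate inputs are defined, not exceptional: empty XML sets parse
  to empty graphs, empty corpora produce header-only outputs with exit
  status 0, and empty predicted/gold sets yield undefined (not zero)
  precision/recall.

## Design choices made where the design was open

- A study spanning several submissions is keyed by its study
  accession; submissions are an attribute of the project summary.
- The dedup key for the publication list is (study, PMID); provenance
  is metadata, not identity, and the priority order exists only to
  make the kept tag deterministic.
- The OBO and MeSH-ASCII readers are small purpose-built parsers so
  that record-level faults (a stanza without an id, a heading without
  a UI) skip one record with a warning instead of aborting a
  vocabulary load; the OBO reader is cross-checked against `obonet`
  in the test suite.
- Problem sizes in tests and the acceptance script (20 studies /
  30 articles; ~120 random graphs; 1000 evaluator trials) were chosen
  as the smallest corpora that exercise every route, pattern, and
  boundary simultaneously.

## Known limitations

- Extraction precision on real articles is untested here by design;
  the historical pipeline this reproduces reported imperfect
  precision against manually curated gold pairs, and our fixtures
  cannot (and do not try to) reproduce corpus-level figures.
- The C/F03 branch rule is applied literally; real disease lists also
  surface check-tag-like headings ("Disease Models, Animal") whose
  tree positions fall outside those branches. We implement the stated
  rule and leave such headings out rather than guess at an expanded
  filter.
- GEO dataset (`GDS`) records are parsed and classified but the
  generator plants only series (`GSE`), mirroring where sequencing
  data actually lands.
- No network access anywhere: Entrez/FTP retrieval of real snapshots
  is out of scope.
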