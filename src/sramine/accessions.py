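"""Recognition and classification of INSDC/GEO accession numbers in text.

Sequence Read Archive accessions are three-letter prefixes followed by a
run of digits.  The first letter names the archive of record (S = NCBI,
E = EBI/ENA, D = DDBJ), the middle letter is always ``R``, and the third
letter selects the object kind: ``A`` submission, ``P`` study, ``X``
experiment, ``R`` run, ``S`` sample, ``Z`` analysis.  Gene Expression
Omnibus identifiers use ``GSE`` (series) and ``GDS`` (dataset) prefixes.

Real archive accessions carry at least six digits; the patterns here
require five so that compact synthetic corpora still match, while prose
tokens such as "SRAdb" (no digits) never do.  A match must be delimited
by non-alphanumeric characters on both sides, so punctuation like
"(SRR000001)." is handled and embedded substrings are not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "AccessionKind",
    "Archive",
    "AccessionMatch",
    "classify_accession",
    "extract_accessions",
    "normalize_accession",
]


class AccessionKind(str, Enum):
    """The six SRA metadata object kinds plus the two GEO record kinds."""

    SUBMISSION = "submission"
    STUDY = "study"
    EXPERIMENT = "experiment"
    RUN = "run"
    SAMPLE = "sample"
    ANALYSIS = "analysis"
    GEO_SERIES = "geo_series"
    GEO_DATASET = "geo_dataset"


class Archive(str, Enum):
    NCBI = "NCBI"
    EBI = "EBI"
    DDBJ = "DDBJ"
    GEO = "GEO"


#: SRA object kind selected by the third prefix letter.
_KIND_BY_LETTER = {
    "A": AccessionKind.SUBMISSION,
    "P": AccessionKind.STUDY,
    "X": AccessionKind.EXPERIMENT,
    "R": AccessionKind.RUN,
    "S": AccessionKind.SAMPLE,
    "Z": AccessionKind.ANALYSIS,
}

#: Archive of record selected by the first prefix letter.
_ARCHIVE_BY_LETTER = {
    "S": Archive.NCBI,
    "E": Archive.EBI,
    "D": Archive.DDBJ,
}

# SRA: >=5 digits after the prefix; GEO: >=1 digit.
_SRA_PATTERN = r"[SED]R[APXRSZ][0-9]{5,}"
_GEO_PATTERN = r"G(?:SE|DS)[0-9]+"
_TOKEN_RE = re.compile(rf"(?:{_SRA_PATTERN}|{_GEO_PATTERN})\Z")
_TOKEN_RE_CI = re.compile(rf"(?:{_SRA_PATTERN}|{_GEO_PATTERN})\Z", re.IGNORECASE)

# Word boundary: not preceded/followed by a letter or digit (hyphen, dot,
# parentheses etc. all delimit).
_SCAN_RE = re.compile(
    rf"(?<![A-Za-z0-9])(?:{_SRA_PATTERN}|{_GEO_PATTERN})(?![A-Za-z0-9])"
)
_SCAN_RE_CI = re.compile(
    rf"(?<![A-Za-z0-9])(?:{_SRA_PATTERN}|{_GEO_PATTERN})(?![A-Za-z0-9])",
    re.IGNORECASE,
)

_VERSION_SUFFIX_RE = re.compile(r"\.[0-9]+\Z")


@dataclass(frozen=True)
class AccessionMatch:
    """One recognized accession, optionally with its offsets in a document.

    ``text`` is the exact source substring; when offsets are present it
    equals ``document[start:end]``.
    """

    text: str
    kind: AccessionKind
    archive: Archive
    start: Optional[int] = None
    end: Optional[int] = None


def normalize_accession(accession: str) -> str:
    """Canonicalize an accession: uppercase, version suffix stripped.

    ``"srr000001.1"`` -> ``"SRR000001"``.  Performs no validation.
    """
    return _VERSION_SUFFIX_RE.sub("", accession.strip().upper())


def classify_accession(
    token: str, *, case_insensitive: bool = False
) -> Optional[AccessionMatch]:
    """Classify a whole token as an accession, or return ``None``.

    Parameters
    ----------
    token:
        Candidate string; must consist of the accession alone.
    case_insensitive:
        Accept lowercase/mixed-case prefixes.  Off by default because
        mixed-case tokens in prose are usually not accessions.
    """
    pattern = _TOKEN_RE_CI if case_insensitive else _TOKEN_RE
    if not pattern.fullmatch(token):
        return None
    upper = token.upper()
    if upper.startswith("GSE"):
        return AccessionMatch(token, AccessionKind.GEO_SERIES, Archive.GEO)
    if upper.startswith("GDS"):
        return AccessionMatch(token, AccessionKind.GEO_DATASET, Archive.GEO)
    return AccessionMatch(
        token, _KIND_BY_LETTER[upper[2]], _ARCHIVE_BY_LETTER[upper[0]]
    )


def extract_accessions(
    text: str, *, case_insensitive: bool = False
) -> list[AccessionMatch]:
    """Find every accession mention in ``text``, in document order.

    Matches never overlap; the same accession cited at several positions
    is reported once per position with its own offsets.
    """
    scan = _SCAN_RE_CI if case_insensitive else _SCAN_RE
    out: list[AccessionMatch] = []
    for m in scan.finditer(text):
        cls = classify_accession(m.group(0), case_insensitive=case_insensitive)
        # The scanner and classifier share one grammar, so cls is never None.
        assert cls is not None
        out.append(
            AccessionMatch(m.group(0), cls.kind, cls.archive, m.start(), m.end())
        )
    return out
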