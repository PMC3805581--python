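"""Parsers for the two vocabulary files the disease index consumes.

MeSH descriptors arrive in the NLM ASCII descriptor format (``*NEWRECORD``
records with ``MH =`` / ``UI =`` / ``MN =`` fields); Disease Ontology
terms arrive as OBO ``[Term]`` stanzas whose ``xref:`` lines carry the
MSH/OMIM/ICD9CM cross-references that mediate identifier mapping.
Both parsers are tolerant: broken records are skipped with a warning so
one bad entry never aborts a vocabulary load, and obsolete DO terms are
excluded from the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = ["MeshDescriptor", "DoTerm", "parse_mesh_ascii", "parse_do_obo"]


@dataclass(frozen=True)
class MeshDescriptor:
    """A MeSH heading: unique identifier, preferred name, tree positions."""

    ui: str
    name: str
    tree_numbers: tuple[str, ...] = ()


@dataclass
class DoTerm:
    """A Disease Ontology term with its cross-reference identifiers."""

    doid: str
    name: str = ""
    xrefs: list[tuple[str, str]] = field(default_factory=list)


def parse_mesh_ascii(text: str) -> list[MeshDescriptor]:
    """Parse an NLM ASCII descriptor file (d2012.bin style).

    Multiple ``MN =`` lines accumulate into one descriptor.  A record
    carrying a heading but no UI is reported and skipped; parsing
    continues with the next record.
    """
    descriptors: list[MeshDescriptor] = []

    def finish(fields: dict) -> None:
        if not fields:
            return
        name, ui = fields.get("MH"), fields.get("UI")
        if name and not ui:
            logger.warning("MeSH record %r has no UI; skipped", name)
            return
        if not name or not ui:
            return
        descriptors.append(
            MeshDescriptor(ui=ui, name=name, tree_numbers=tuple(fields.get("MN", ())))
        )

    fields: dict = {}
    for line in text.splitlines():
        line = line.rstrip()
        if line == "*NEWRECORD":
            finish(fields)
            fields = {}
        elif " = " in line:
            key, _, value = line.partition(" = ")
            key = key.strip()
            if key == "MN":
                fields.setdefault("MN", []).append(value.strip())
            elif key in ("MH", "UI"):
                fields[key] = value.strip()
    finish(fields)
    return descriptors


def parse_do_obo(text: str) -> list[DoTerm]:
    """Parse Disease Ontology ``[Term]`` stanzas from OBO text.

    Each xref value is split on its first colon into (namespace, id),
    e.g. ``MSH:D001943`` -> ``("MSH", "D001943")``.  Stanzas without an
    ``id:`` line are skipped with a warning; stanzas flagged
    ``is_obsolete: true`` are excluded.
    """
    terms: list[DoTerm] = []
    in_term = False
    current: DoTerm | None = None
    obsolete = False

    def finish() -> None:
        nonlocal current, obsolete
        if in_term:
            if current is None:
                logger.warning("OBO [Term] stanza without id skipped")
            elif not obsolete:
                terms.append(current)
        current, obsolete = None, False

    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            finish()
            in_term = line == "[Term]"
            continue
        if not in_term or not line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "id":
            current = DoTerm(doid=value)
        elif current is None:
            continue
        elif key == "name":
            current.name = value
        elif key == "xref":
            ns, sep, xid = value.partition(":")
            if sep:
                current.xrefs.append((ns.strip(), xid.strip().split()[0]))
        elif key == "is_obsolete" and value.lower().startswith("true"):
            obsolete = True
    finish()
    return terms
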