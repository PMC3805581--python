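"""Independent brute-force oracles used to check the implementation.

Everything here is written directly against the domain rules with
plain dicts and exhaustive walking — no networkx, no shared code with
the package internals — so agreement between an oracle and the
implementation is a meaningful check, not a tautology.
"""

from __future__ import annotations

import random

from sramine.accessions import AccessionKind, normalize_accession
from sramine.metadata import MetadataObject


def index_objects(objects) -> dict[str, MetadataObject]:
    """Accession -> object, last-wins, accessions normalized."""
    return {normalize_accession(o.accession): o for o in objects}


def oracle_resolve(by_acc: dict[str, MetadataObject], accession: str) -> set[str]:
    """Transitive-closure resolution by exhaustive edge walking.

    Typed rules: study -> itself; experiment/analysis -> referenced
    studies; run -> through its experiments; sample -> backwards
    through every experiment that references it; submission -> through
    every owned object.
    """

    def present_targets(obj: MetadataObject, want: AccessionKind) -> list[str]:
        out = []
        self_acc = normalize_accession(obj.accession)
        for _, target in obj.references:
            target = normalize_accession(target)
            if target == self_acc:
                continue
            node = by_acc.get(target)
            if node is not None and node.kind is want:
                out.append(target)
        return out

    def rec(acc: str, stack: frozenset[str]) -> set[str]:
        if acc in stack:
            return set()
        obj = by_acc.get(acc)
        if obj is None:
            return set()
        stack = stack | {acc}
        kind = obj.kind
        if kind is AccessionKind.STUDY:
            return {acc}
        if kind in (AccessionKind.EXPERIMENT, AccessionKind.ANALYSIS):
            return set(present_targets(obj, AccessionKind.STUDY))
        if kind is AccessionKind.RUN:
            result: set[str] = set()
            for exp in present_targets(obj, AccessionKind.EXPERIMENT):
                result |= rec(exp, stack)
            return result
        if kind is AccessionKind.SAMPLE:
            result = set()
            for other_acc, other in by_acc.items():
                if other.kind is not AccessionKind.EXPERIMENT:
                    continue
                if acc in {
                    normalize_accession(t)
                    for k, t in other.references
                    if k is AccessionKind.SAMPLE
                }:
                    result |= rec(other_acc, stack)
            return result
        if kind is AccessionKind.SUBMISSION:
            result = set()
            self_acc = normalize_accession(obj.accession)
            for _, target in obj.references:
                target = normalize_accession(target)
                if target != self_acc and target in by_acc:
                    result |= rec(target, stack)
            return result
        return set()

    return rec(normalize_accession(accession), frozenset())


def oracle_completeness(by_acc: dict[str, MetadataObject]) -> dict[str, tuple]:
    """Submission -> six-boolean presence pattern, by exhaustive BFS."""
    order = (
        AccessionKind.SUBMISSION,
        AccessionKind.STUDY,
        AccessionKind.EXPERIMENT,
        AccessionKind.RUN,
        AccessionKind.SAMPLE,
        AccessionKind.ANALYSIS,
    )
    patterns: dict[str, tuple] = {}
    for acc, obj in by_acc.items():
        if obj.kind is not AccessionKind.SUBMISSION:
            continue
        seen = {acc}
        frontier = [acc]
        while frontier:
            current = frontier.pop()
            for _, target in by_acc[current].references:
                target = normalize_accession(target)
                if target in by_acc and target not in seen \
                        and target != current:
                    seen.add(target)
                    frontier.append(target)
        kinds = {by_acc[a].kind for a in seen}
        patterns[acc] = tuple(k in kinds for k in order)
    return patterns


def random_graph_objects(rng: random.Random) -> list[MetadataObject]:
    """A random, possibly messy metadata object set.

    Includes one-to-many links in both directions, shared samples,
    dangling references, and objects across all three archives.
    """
    letter = rng.choice("SED")
    n_studies = rng.randint(1, 4)
    studies = [f"{letter}RP{100001 + i:06d}" for i in range(n_studies)]
    objects = [
        MetadataObject(kind=AccessionKind.STUDY, accession=acc) for acc in studies
    ]

    n_samples = rng.randint(0, 4)
    samples = [f"{letter}RS{100001 + i:06d}" for i in range(n_samples)]
    objects += [
        MetadataObject(kind=AccessionKind.SAMPLE, accession=acc) for acc in samples
    ]

    n_exp = rng.randint(0, 6)
    experiments = []
    for i in range(n_exp):
        acc = f"{letter}RX{100001 + i:06d}"
        experiments.append(acc)
        refs = []
        # one-to-many: an experiment may reference several studies
        for study in rng.sample(studies, rng.randint(0, min(2, n_studies))):
            refs.append((AccessionKind.STUDY, study))
        if rng.random() < 0.3:  # dangling study reference
            refs.append((AccessionKind.STUDY, f"{letter}RP999999"))
        if samples and rng.random() < 0.7:
            refs.append((AccessionKind.SAMPLE, rng.choice(samples)))
        objects.append(
            MetadataObject(
                kind=AccessionKind.EXPERIMENT, accession=acc, references=refs
            )
        )

    n_runs = rng.randint(0, 8)
    for i in range(n_runs):
        refs = []
        if experiments:
            for exp in rng.sample(
                experiments, rng.randint(0, min(2, len(experiments)))
            ):
                refs.append((AccessionKind.EXPERIMENT, exp))
        if rng.random() < 0.2:
            refs.append((AccessionKind.EXPERIMENT, f"{letter}RX888888"))
        objects.append(
            MetadataObject(
                kind=AccessionKind.RUN,
                accession=f"{letter}RR{100001 + i:06d}",
                references=refs,
            )
        )

    for i in range(rng.randint(0, 2)):
        refs = [
            (AccessionKind.STUDY, rng.choice(studies))
        ] if rng.random() < 0.8 else []
        objects.append(
            MetadataObject(
                kind=AccessionKind.ANALYSIS,
                accession=f"{letter}RZ{100001 + i:06d}",
                references=refs,
            )
        )

    for i in range(rng.randint(0, 3)):
        refs = [
            (o.kind, o.accession)
            for o in rng.sample(objects, rng.randint(0, min(6, len(objects))))
        ]
        objects.append(
            MetadataObject(
                kind=AccessionKind.SUBMISSION,
                accession=f"{letter}RA{100001 + i:06d}",
                references=refs,
            )
        )
    return objects


def oracle_tree_rollup(annotations, vocab) -> dict[str, int]:
    """Tree number -> distinct-study count over its whole subtree."""
    tn_by_ui = {d.ui: list(d.tree_numbers) for d in vocab}
    own: dict[str, set[str]] = {}
    numbers: set[str] = set()
    for annotation in annotations:
        for tn in tn_by_ui.get(annotation.ui, ()):
            own.setdefault(tn, set()).add(annotation.study_accession)
            parts = tn.split(".")
            for i in range(len(parts)):
                numbers.add(".".join(parts[: i + 1]))
    rolled = {}
    for tn in numbers:
        studies: set[str] = set()
        for other, members in own.items():
            if other == tn or other.startswith(tn + "."):
                studies |= members
        rolled[tn] = len(studies)
    return rolled
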