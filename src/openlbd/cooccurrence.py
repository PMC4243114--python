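"""Document-level concept occurrence and co-occurrence counting.

Four scopes are supported:

- ``mesh_field``: both concepts appear in the record's MH list;
- ``tiab``: both are mentioned anywhere in the title+abstract text;
- ``sentence``: some single sentence mentions both;
- ``window``: some pair of sentences at index distance <= 1 covers both
  (a single sentence qualifies as a degenerate window).

All counts are per document: a pair co-occurring in three sentences of
one record still contributes one to the count for that scope.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Mapping, Sequence

from .medline_io import MedlineRecord, find_mentions, normalize_concept
from .lexicon import SemanticTypeMap, has_type

__all__ = [
    "SCOPES",
    "CooccurrenceIndex",
    "build_index",
    "build_all_indices",
    "record_sentence_concepts",
    "candidate_linking_concepts",
    "filter_by_year",
    "save_index",
    "load_index",
]

SCOPES = ("mesh_field", "tiab", "sentence", "window")


def pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CooccurrenceIndex:
    scope: str
    n_docs: int
    occ: Counter = field(default_factory=Counter)
    cooc: Counter = field(default_factory=Counter)

    def occ_of(self, concept: str) -> int:
        return self.occ.get(normalize_concept(concept), 0)

    def cooc_of(self, a: str, b: str) -> int:
        return self.cooc.get(
            pair_key(normalize_concept(a), normalize_concept(b)), 0
        )

    def validate(self) -> None:
        for c, n in self.occ.items():
            if not 0 <= n <= self.n_docs:
                raise ValueError(f"occ({c!r})={n} outside [0, {self.n_docs}]")
        for (a, b), n in self.cooc.items():
            if a > b:
                raise ValueError(f"unordered pair key {(a, b)!r}")
            if n > min(self.occ.get(a, 0), self.occ.get(b, 0)):
                raise ValueError(
                    f"cooc({a!r},{b!r})={n} exceeds min marginal count"
                )
            if n < 0:
                raise ValueError(f"negative cooc for {(a, b)!r}")


def record_sentence_concepts(
    record: MedlineRecord, concepts: Iterable[str]
) -> list[set[str]]:
    """Per-sentence sets of concepts mentioned in the record (title is
    sentence 0 when present)."""
    mentions = find_mentions(record, concepts)
    n = 1 + max((m.sentence_index for m in mentions), default=0)
    per_sentence: list[set[str]] = [set() for _ in range(n)]
    for m in mentions:
        per_sentence[m.sentence_index].add(m.concept)
    return per_sentence


def _present_and_pairs(
    per_sentence: Sequence[set[str]], scope: str
) -> tuple[set[str], set[tuple[str, str]]]:
    present = set().union(*per_sentence) if per_sentence else set()
    pairs: set[tuple[str, str]] = set()
    if scope == "tiab":
        pairs = {pair_key(a, b) for a, b in combinations(sorted(present), 2)}
    elif scope == "sentence":
        for sent in per_sentence:
            pairs |= {pair_key(a, b) for a, b in combinations(sorted(sent), 2)}
    elif scope == "window":
        for i in range(len(per_sentence)):
            window = per_sentence[i] | (
                per_sentence[i + 1] if i + 1 < len(per_sentence) else set()
            )
            pairs |= {pair_key(a, b) for a, b in combinations(sorted(window), 2)}
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown scope {scope!r}")
    return present, pairs


def build_index(
    records: Sequence[MedlineRecord],
    scope: str,
    concepts: Iterable[str] | None = None,
) -> CooccurrenceIndex:
    """Build the occurrence/co-occurrence index for one scope.

    ``concepts`` restricts the text search set for the textual scopes and
    is required there; for ``mesh_field`` it defaults to every MH term in
    the corpus. For the textual scopes, occurrence means "mentioned
    anywhere in title+abstract" while co-occurrence is scope-specific.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    index = CooccurrenceIndex(scope=scope, n_docs=len(records))
    if scope == "mesh_field":
        allowed = (
            {normalize_concept(c) for c in concepts} if concepts is not None else None
        )
        for rec in records:
            present = set(rec.mesh_terms)
            if allowed is not None:
                present &= allowed
            index.occ.update(present)
            index.cooc.update(
                pair_key(a, b) for a, b in combinations(sorted(present), 2)
            )
        return index
    if concepts is None:
        raise ValueError("textual scopes require an explicit concept set")
    concept_set = {normalize_concept(c) for c in concepts}
    for rec in records:
        per_sentence = record_sentence_concepts(rec, concept_set)
        present, pairs = _present_and_pairs(per_sentence, scope)
        index.occ.update(present)
        index.cooc.update(pairs)
    return index


def build_all_indices(
    records: Sequence[MedlineRecord], concepts: Iterable[str]
) -> dict[str, CooccurrenceIndex]:
    """Build all four indices, sharing one mention pass for the textual
    scopes."""
    concept_set = {normalize_concept(c) for c in concepts}
    indices = {
        "mesh_field": build_index(records, "mesh_field"),
        "tiab": CooccurrenceIndex("tiab", len(records)),
        "sentence": CooccurrenceIndex("sentence", len(records)),
        "window": CooccurrenceIndex("window", len(records)),
    }
    for rec in records:
        per_sentence = record_sentence_concepts(rec, concept_set)
        for scope in ("tiab", "sentence", "window"):
            present, pairs = _present_and_pairs(per_sentence, scope)
            indices[scope].occ.update(present)
            indices[scope].cooc.update(pairs)
    return indices


def candidate_linking_concepts(
    index: CooccurrenceIndex,
    start: str,
    type_map: SemanticTypeMap | None = None,
    linking_types: Iterable[str] | None = None,
) -> set[str]:
    """Concepts co-occurring with the starting concept in the MeSH field,
    optionally restricted to the admitted linking semantic types."""
    if index.scope != "mesh_field":
        raise ValueError("candidate linking concepts come from the mesh_field index")
    c = normalize_concept(start)
    if index.occ.get(c, 0) == 0:
        warnings.warn(f"starting concept {start!r} absent from corpus", stacklevel=2)
        return set()
    candidates = {
        (b if a == c else a)
        for (a, b), n in index.cooc.items()
        if n >= 1 and c in (a, b)
    }
    candidates.discard(c)
    if linking_types is not None and type_map is not None:
        candidates = {
            b for b in candidates if has_type(type_map, b, linking_types)
        }
    return candidates


def filter_by_year(
    records: Iterable[MedlineRecord], max_year: int | None
) -> list[MedlineRecord]:
    """Keep records published strictly before ``max_year`` (``None`` keeps
    everything). Records without a year are dropped when a bound is set."""
    if max_year is None:
        return list(records)
    return [r for r in records if r.year is not None and r.year < max_year]


def save_index(index: CooccurrenceIndex, stream: IO[str]) -> None:
    """Write the 3-section TSV serialization (header, occ, cooc)."""
    stream.write(f"#scope\t{index.scope}\t{index.n_docs}\n")
    stream.write("#occ\n")
    for concept in sorted(index.occ):
        stream.write(f"{concept}\t{index.occ[concept]}\n")
    stream.write("#cooc\n")
    for a, b in sorted(index.cooc):
        stream.write(f"{a}\t{b}\t{index.cooc[(a, b)]}\n")


def load_index(stream: IO[str]) -> CooccurrenceIndex:
    lines = [ln.rstrip("\n") for ln in stream]
    if not lines or not lines[0].startswith("#scope\t"):
        raise ValueError("missing #scope header")
    _, scope, n_docs = lines[0].split("\t")
    index = CooccurrenceIndex(scope=scope, n_docs=int(n_docs))
    section = None
    for ln in lines[1:]:
        if ln == "#occ":
            section = "occ"
        elif ln == "#cooc":
            section = "cooc"
        elif ln.strip():
            parts = ln.split("\t")
            if section == "occ":
                index.occ[parts[0]] = int(parts[1])
            elif section == "cooc":
                index.cooc[(parts[0], parts[1])] = int(parts[2])
            else:
                raise ValueError(f"data line outside a section: {ln!r}")
    return index
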