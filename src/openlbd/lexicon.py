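"""Semantic-type mapping, type-filter configuration and interaction lexicon."""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .medline_io import normalize_concept

__all__ = [
    "SemanticTypeMap",
    "TypeFilterConfig",
    "InteractionLexicon",
    "DEFAULT_LINKING_TYPES",
    "DEFAULT_TARGET_TYPES",
    "DEFAULT_INTERACTION_WORDS",
    "load_semantic_types",
    "load_interaction_lexicon",
    "load_stop_concepts",
    "has_type",
    "contains_interaction_word",
    "too_general_concepts",
]

# The nine functional semantic types admitted for linking concepts and the
# five dietary-factor types admitted for target concepts.
DEFAULT_LINKING_TYPES = frozenset(
    {
        "Biological function",
        "Cell function",
        "Finding",
        "Molecular function",
        "Organism function",
        "Organ or Tissue function",
        "Pathological function",
        "Phenomenon or process",
        "Physiological function",
    }
)

DEFAULT_TARGET_TYPES = frozenset(
    {"Element", "Ion", "Isotope", "Vitamin", "Lipid"}
)

# Partial universe of recognized semantic-type names. The full 135-name
# inventory is an external resource; names outside this set are accepted
# with a warning so user-supplied maps remain usable.
KNOWN_SEMANTIC_TYPES = frozenset(
    DEFAULT_LINKING_TYPES
    | DEFAULT_TARGET_TYPES
    | {
        "Disease or Syndrome",
        "Sign or Symptom",
        "Pharmacologic Substance",
        "Chemical",
        "Body Part, Organ, or Organ Component",
        "Cell",
        "Tissue",
        "Organism",
        "Plant",
        "Animal",
        "Gene or Genome",
        "Amino Acid, Peptide, or Protein",
        "Carbohydrate",
        "Hormone",
        "Enzyme",
        "Geographic Area",
        "Laboratory Procedure",
        "Therapeutic or Preventive Procedure",
        "Diagnostic Procedure",
        "Mental or Behavioral Dysfunction",
        "Neoplastic Process",
        "Injury or Poisoning",
        "Organic Chemical",
        "Inorganic Chemical",
        "Food",
        "Research Activity",
        "Population Group",
        "Age Group",
        "Temporal Concept",
        "Quantitative Concept",
        "Qualitative Concept",
        "Spatial Concept",
        "Idea or Concept",
        "Functional Concept",
    }
)

# Seed interaction lexicon: influence verbs plus inflectional variants,
# enumerated explicitly (no runtime stemming). Replication work should
# supply the full domain lexicon as a file.
DEFAULT_INTERACTION_WORDS = frozenset(
    {
        "increase", "increases", "increased", "increasing",
        "decrease", "decreases", "decreased", "decreasing",
        "inhibit", "inhibits", "inhibited", "inhibiting",
        "induce", "induces", "induced", "inducing",
        "aggravate", "aggravates", "aggravated", "aggravating",
        "reduce", "reduces", "reduced", "reducing",
        "promote", "promotes", "promoted", "promoting",
        "block", "blocks", "blocked", "blocking",
        "stimulate", "stimulates", "stimulated", "stimulating",
        "suppress", "suppresses", "suppressed", "suppressing",
    }
)


@dataclass(frozen=True)
class SemanticTypeMap:
    """Mapping from normalized concept string to its semantic types."""

    entries: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def types_of(self, concept: str) -> frozenset[str]:
        return self.entries.get(normalize_concept(concept), frozenset())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, concept: str) -> bool:
        return normalize_concept(concept) in self.entries


@dataclass(frozen=True)
class TypeFilterConfig:
    linking_types: frozenset[str] = DEFAULT_LINKING_TYPES
    target_types: frozenset[str] = DEFAULT_TARGET_TYPES
    enabled: bool = True


@dataclass(frozen=True)
class InteractionLexicon:
    words: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.words)

    def __bool__(self) -> bool:
        return bool(self.words)


def default_interaction_lexicon() -> InteractionLexicon:
    return InteractionLexicon(words=DEFAULT_INTERACTION_WORDS)


def _lines(stream: IO[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return stream


def load_semantic_types(stream: IO[str] | str) -> SemanticTypeMap:
    """Load a 2-column TSV (concept<TAB>semantic type) into a map.

    Repeated concept lines union their types. A malformed line raises
    ``ValueError`` with its line number; an unrecognized type name emits a
    warning but the line is kept.
    """
    entries: dict[str, set[str]] = {}
    for line_no, line in enumerate(_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"malformed semantic-type line {line_no}: {line!r}")
        concept = normalize_concept(parts[0])
        for type_name in (p.strip() for p in parts[1:]):
            if not type_name:
                continue
            if type_name not in KNOWN_SEMANTIC_TYPES:
                warnings.warn(
                    f"line {line_no}: unrecognized semantic type {type_name!r}",
                    stacklevel=2,
                )
            entries.setdefault(concept, set()).add(type_name)
    return SemanticTypeMap(
        entries={c: frozenset(ts) for c, ts in entries.items()}
    )


def write_semantic_types(type_map: SemanticTypeMap) -> str:
    lines = []
    for concept in sorted(type_map.entries):
        for type_name in sorted(type_map.entries[concept]):
            lines.append(f"{concept}\t{type_name}")
    return "\n".join(lines) + ("\n" if lines else "")


def load_interaction_lexicon(stream: IO[str] | str) -> InteractionLexicon:
    """Load a one-entry-per-line lexicon; ``#`` starts a comment line."""
    words: set[str] = set()
    for line in _lines(stream):
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        words.add(entry.lower())
    return InteractionLexicon(words=frozenset(words))


def load_stop_concepts(stream: IO[str] | str) -> frozenset[str]:
    concepts: set[str] = set()
    for line in _lines(stream):
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        concepts.add(normalize_concept(entry))
    return frozenset(concepts)


def has_type(
    type_map: SemanticTypeMap, concept: str, types: Iterable[str]
) -> bool:
    """True iff the concept is mapped and its types intersect ``types``.
    Unmapped concepts are false."""
    return bool(type_map.types_of(concept) & set(types))


_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z'-]*")


def contains_interaction_word(lexicon: InteractionLexicon, text: str) -> bool:
    """True iff any lexicon entry equals a whole token of ``text``
    (case-insensitive)."""
    if not lexicon.words:
        return False
    return any(
        tok.group(0).lower() in lexicon.words for tok in _TOKEN_RE.finditer(text)
    )


def too_general_concepts(
    document_frequency: Mapping[str, int],
    quantile: float = 0.99,
    stop_concepts: Iterable[str] = (),
) -> frozenset[str]:
    """Concepts considered "too general": document frequency at or above
    the given quantile of the supplied DF distribution, or listed in an
    explicit stop-concept file."""
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    stop = {normalize_concept(c) for c in stop_concepts}
    result = {c for c in document_frequency if normalize_concept(c) in stop}
    if document_frequency:
        values = sorted(document_frequency.values())
        # smallest DF value at or above the quantile position
        pos = min(len(values) - 1, int(quantile * len(values)))
        threshold = values[pos]
        result |= {
            c for c, df in document_frequency.items() if df >= threshold
        }
    return frozenset(result)
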