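"""Seeded MEDLINE-like corpus generator with full ground-truth bookkeeping.

Generated corpora contain three kinds of record:

- C-literature: the start concept with relevant/decoy linking concepts.
  Relevant links get same-sentence interaction evidence at
  ``interaction_rate``; decoys co-occur in MeSH only, in non-adjacent
  sentences, or in one sentence without an interaction word.
- A-literature: linking-target records carrying rule1/rule2 evidence.
- Background noise records.

Planted target concepts never co-occur with the start concept in any
field of any record. Sentences are template text: the features depend
only on mention and lexicon geometry, not fluency.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .cooccurrence import CooccurrenceIndex, pair_key
from .lexicon import (
    DEFAULT_INTERACTION_WORDS,
    DEFAULT_LINKING_TYPES,
    DEFAULT_TARGET_TYPES,
    SemanticTypeMap,
)
from .medline_io import MedlineRecord, normalize_concept

__all__ = ["CorpusSpec", "GroundTruth", "generate_corpus", "generate_semantic_types"]

# verbs drawn from the default interaction lexicon / guaranteed outside it
_INTERACTION_VERBS = ("increase", "inhibit", "reduce", "aggravate")
_NEUTRAL_VERBS = ("accompany", "parallel", "match")

_NOISE_TYPES = ("Plant", "Geographic Area", "Temporal Concept")


@dataclass(frozen=True)
class CorpusSpec:
    n_records: int = 60
    start_concept: str = "startconcept"
    relevant_b: tuple[str, ...] = ("linkrel0", "linkrel1", "linkrel2")
    decoy_b: tuple[str, ...] = tuple(f"linkdecoy{i}" for i in range(6))
    targets: tuple[str, ...] = ("targetcand0",)
    interaction_rate: float = 1.0
    abbrev_rate: float = 0.0
    noise_mesh_rate: float = 0.0
    seed: int = 0
    records_per_link: int = 2
    n_noise_concepts: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant_b", tuple(map(normalize_concept, self.relevant_b)))
        object.__setattr__(self, "decoy_b", tuple(map(normalize_concept, self.decoy_b)))
        object.__setattr__(self, "targets", tuple(map(normalize_concept, self.targets)))
        for name in ("interaction_rate", "abbrev_rate", "noise_mesh_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if set(self.relevant_b) & set(self.decoy_b):
            raise ValueError("relevant_b and decoy_b must be disjoint")
        c = normalize_concept(self.start_concept)
        overlapping = ({c} | set(self.relevant_b) | set(self.decoy_b)) & set(self.targets)
        if overlapping:
            raise ValueError(f"targets overlap other roles: {sorted(overlapping)}")
        if self.n_records < 1 or self.records_per_link < 1:
            raise ValueError("n_records and records_per_link must be positive")

    @property
    def start(self) -> str:
        return normalize_concept(self.start_concept)

    @property
    def noise_concepts(self) -> tuple[str, ...]:
        return tuple(f"noiseterm{i}" for i in range(self.n_noise_concepts))

    @property
    def decoy_targets(self) -> tuple[str, ...]:
        return tuple(f"offtarget{i}" for i in range(min(len(self.decoy_b), 4)))


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything planted, recorded independently
    of the parsing/mention pipeline."""

    spec: CorpusSpec
    # pmid -> {"mesh": [...], "sentences": [[concepts...], ...], "interaction": [bool,...]}
    records: dict[str, dict] = field(default_factory=dict)
    # (b, a) normalized pair -> strongest planted evidence level
    pair_evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def add_record(
        self,
        pmid: str,
        mesh: Sequence[str],
        sentence_concepts: Sequence[set[str]],
        interaction_flags: Sequence[bool],
    ) -> None:
        self.records[pmid] = {
            "mesh": list(mesh),
            "sentences": [sorted(s) for s in sentence_concepts],
            "interaction": list(interaction_flags),
        }

    def note_pair(self, a: str, b: str, level: str) -> None:
        order = {"mesh_only": 0, "tiab": 1, "window": 2, "sentence": 3, "interaction_sentence": 4}
        key = pair_key(normalize_concept(a), normalize_concept(b))
        if order[level] > order.get(self.pair_evidence.get(key, "mesh_only"), -1):
            self.pair_evidence[key] = level

    def expected_index(self, scope: str) -> CooccurrenceIndex:
        """Recompute the per-scope counts from the planted bookkeeping."""
        index = CooccurrenceIndex(scope=scope, n_docs=len(self.records))
        for info in self.records.values():
            sentence_sets = [set(s) for s in info["sentences"]]
            if scope == "mesh_field":
                present = set(info["mesh"])
                pairs = {pair_key(a, b) for a, b in combinations(sorted(present), 2)}
            elif scope == "tiab":
                present = set().union(*sentence_sets) if sentence_sets else set()
                pairs = {pair_key(a, b) for a, b in combinations(sorted(present), 2)}
            elif scope == "sentence":
                present = set().union(*sentence_sets) if sentence_sets else set()
                pairs = set()
                for s in sentence_sets:
                    pairs |= {pair_key(a, b) for a, b in combinations(sorted(s), 2)}
            elif scope == "window":
                present = set().union(*sentence_sets) if sentence_sets else set()
                pairs = set()
                for i in range(len(sentence_sets)):
                    window = sentence_sets[i] | (
                        sentence_sets[i + 1] if i + 1 < len(sentence_sets) else set()
                    )
                    pairs |= {pair_key(a, b) for a, b in combinations(sorted(window), 2)}
            else:
                raise ValueError(f"unknown scope {scope!r}")
            index.occ.update(present)
            index.cooc.update(pairs)
        return index

    def mention_count(self, concept: str) -> int:
        concept = normalize_concept(concept)
        return sum(
            sum(1 for s in info["sentences"] if concept in s)
            for info in self.records.values()
        )

    def to_json(self) -> str:
        payload = {
            "start": self.spec.start,
            "relevant_b": list(self.spec.relevant_b),
            "decoy_b": list(self.spec.decoy_b),
            "targets": list(self.spec.targets),
            "decoy_targets": list(self.spec.decoy_targets),
            "seed": self.spec.seed,
            "records": self.records,
            "pair_evidence": {
                f"{a}|{b}": level for (a, b), level in sorted(self.pair_evidence.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _cap(sentence: str) -> str:
    return sentence[0].upper() + sentence[1:] if sentence else sentence


class _Builder:
    def __init__(self, spec: CorpusSpec, rng: random.Random, truth: GroundTruth):
        self.spec, self.rng, self.truth = spec, rng, truth
        self.records: list[MedlineRecord] = []
        self._next_pmid = 1000

    def add(
        self,
        title: str,
        title_concepts: set[str],
        abstract_parts: Sequence[tuple[str, set[str], bool]],
        mesh: Sequence[str],
    ) -> MedlineRecord:
        pmid = str(self._next_pmid)
        self._next_pmid += 1
        mesh = list(dict.fromkeys(normalize_concept(m) for m in mesh))
        if self.spec.noise_mesh_rate and self.rng.random() < self.spec.noise_mesh_rate:
            extra = self.rng.choice(self.spec.noise_concepts)
            if extra not in mesh:
                mesh.append(extra)
        record = MedlineRecord(
            pmid=pmid,
            title=_cap(title),
            abstract=" ".join(_cap(text) for text, _, _ in abstract_parts),
            mesh_terms=tuple(mesh),
            year=self.rng.randint(1975, 1984),
        )
        self.records.append(record)
        sentence_sets = [set(title_concepts)] + [set(c) for _, c, _ in abstract_parts]
        flags = [False] + [flag for _, _, flag in abstract_parts]
        self.truth.add_record(pmid, mesh, sentence_sets, flags)
        return record


def generate_corpus(spec: CorpusSpec) -> tuple[list[MedlineRecord], GroundTruth]:
    """Generate a corpus and its ground truth. Deterministic per seed."""
    rng = random.Random(spec.seed)
    truth = GroundTruth(spec=spec)
    b = _Builder(spec, rng, truth)
    c = spec.start
    filler = ("further studies are required.", set(), False)

    # --- C-literature: relevant linking concepts -------------------------
    for i, rel in enumerate(spec.relevant_b):
        for k in range(spec.records_per_link):
            interactive = rng.random() < spec.interaction_rate
            verb = rng.choice(_INTERACTION_VERBS if interactive else _NEUTRAL_VERBS)
            abbrev = k == 0 and rng.random() < spec.abbrev_rate
            parts: list[tuple[str, set[str], bool]] = []
            if abbrev:
                token = f"QX{i}Z"
                if interactive:
                    lead = f"{rel} ({token}) may {verb} vascular factors in {c}."
                else:
                    lead = f"{rel} ({token}) may {verb} vascular factors seen in {c}."
                parts.append((lead, {rel, c}, interactive))
                parts.append((f"elevated {token} was seen in several patients.", {rel}, False))
            else:
                if interactive:
                    parts.append((f"{rel} may {verb} vascular factors in {c}.", {rel, c}, True))
                else:
                    parts.append((f"{rel} occurs together with {c} in patients.", {rel, c}, False))
            parts.append(filler)
            b.add(f"clinical aspects of {c}.", {c}, parts, [c, rel])
            truth.note_pair(c, rel, "interaction_sentence" if interactive else "sentence")

    # --- C-literature: decoy linking concepts ----------------------------
    for i, decoy in enumerate(spec.decoy_b):
        for k in range(spec.records_per_link):
            style = i % 3
            if style == 0:  # MeSH-only co-occurrence, decoy absent from text
                b.add(
                    f"observations in {c}.",
                    {c},
                    [("patients were monitored daily.", set(), False), filler],
                    [c, decoy],
                )
                truth.note_pair(c, decoy, "mesh_only")
            elif style == 1:  # non-adjacent sentences (distance 2)
                b.add(
                    "report of clinical findings.",
                    set(),
                    [
                        (f"symptoms of {c} were assessed.", {c}, False),
                        ("samples were collected weekly.", set(), False),
                        (f"levels of {decoy} were measured.", {decoy}, False),
                    ],
                    [c, decoy],
                )
                truth.note_pair(c, decoy, "tiab")
            else:  # same sentence, no interaction word
                b.add(
                    f"observations in {c}.",
                    {c},
                    [(f"{decoy} occurs together with {c} in patients.", {decoy, c}, False), filler],
                    [c, decoy],
                )
                truth.note_pair(c, decoy, "sentence")

    # --- A-literature: relevant B -> target records ----------------------
    for target in spec.targets:
        for rel in spec.relevant_b:
            for _ in range(spec.records_per_link):
                interactive = rng.random() < spec.interaction_rate
                verb = rng.choice(_INTERACTION_VERBS if interactive else _NEUTRAL_VERBS)
                if interactive:
                    body = (f"{rel} may {verb} the concentration of {target}.", {rel, target}, True)
                    truth.note_pair(rel, target, "interaction_sentence")
                else:
                    body = (f"{rel} appears alongside {target} in several assays.", {rel, target}, False)
                    truth.note_pair(rel, target, "sentence")
                b.add(f"biochemical role of {target}.", {target}, [body, filler], [rel, target])

    # --- decoy-target records (MeSH-only reachability via decoys) --------
    decoy_targets = spec.decoy_targets
    for i, decoy in enumerate(spec.decoy_b):
        if not decoy_targets:
            break
        off = decoy_targets[i % len(decoy_targets)]
        b.add(
            "supplementary laboratory report.",
            set(),
            [(f"additional data on {decoy} were collected.", {decoy}, False), filler],
            [decoy, off],
        )
        truth.note_pair(decoy, off, "mesh_only")

    # --- background noise, padding up to n_records -----------------------
    noise = spec.noise_concepts
    general = spec.decoy_b[0] if spec.decoy_b else None
    j = 0
    while len(b.records) < spec.n_records:
        n1 = noise[j % len(noise)]
        n2 = noise[(j + 1) % len(noise)]
        mesh = [n1, n2]
        # inflate the document frequency of the first decoy so the
        # "too general" rule has a non-trivial hit
        if general is not None and j % 2 == 0:
            mesh.append(general)
        b.add(
            "methodological notes.",
            set(),
            [(f"use of {n1} was reviewed.", {n1}, False), filler],
            mesh,
        )
        j += 1

    _validate_no_ca_cooccurrence(b.records, truth, spec)
    return b.records, truth


def _validate_no_ca_cooccurrence(
    records: Sequence[MedlineRecord], truth: GroundTruth, spec: CorpusSpec
) -> None:
    c = spec.start
    forbidden = set(spec.targets) | set(spec.decoy_targets)
    for rec in records:
        info = truth.records[rec.pmid]
        everywhere = set(info["mesh"]).union(*[set(s) for s in info["sentences"]])
        if c in everywhere and forbidden & everywhere:
            raise AssertionError(
                f"generator violated the C/A separation constraint in {rec.pmid}"
            )


def generate_semantic_types(spec: CorpusSpec) -> SemanticTypeMap:
    """Assign linking types to planted B concepts, target types to planted
    (and decoy) targets, and unrelated types to noise concepts."""
    linking_types = sorted(DEFAULT_LINKING_TYPES)
    target_types = sorted(DEFAULT_TARGET_TYPES)
    entries: dict[str, frozenset[str]] = {
        spec.start: frozenset({"Disease or Syndrome"})
    }
    for i, concept in enumerate(spec.relevant_b + spec.decoy_b):
        entries[concept] = frozenset({linking_types[i % len(linking_types)]})
    for i, concept in enumerate(spec.targets + spec.decoy_targets):
        entries[concept] = frozenset({target_types[i % len(target_types)]})
    for i, concept in enumerate(spec.noise_concepts):
        entries[concept] = frozenset({_NOISE_TYPES[i % len(_NOISE_TYPES)]})
    return SemanticTypeMap(entries=entries)
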