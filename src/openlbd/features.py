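"""Mutual-information scores and the 7-dimensional pair feature vector.

Feature layout for a (starting concept C, linking concept B) pair:

- f1: MIM over the MeSH-field scope (bits);
- f2: MIM over the title+abstract scope (bits);
- f3: 1 iff some sentence mentions both;
- f4: 1 iff some sentence mentions both and contains an interaction word;
- f5: 1 iff some window of two neighboring sentences (or one sentence)
  covers mentions of both;
- f6: 1 iff such a window also contains an interaction word anywhere in it;
- f7: 1 iff both are mentioned in the abstract text of some record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import CooccurrenceIndex, pair_key
from .lexicon import InteractionLexicon, contains_interaction_word
from .medline_io import MedlineRecord, find_mentions, normalize_concept, segment_sentences

__all__ = [
    "MIM_FLOOR",
    "FeatureVector",
    "TextEvidence",
    "mim",
    "extract_features",
    "feature_frame",
    "write_feature_matrix",
]

MIM_FLOOR = -20.0

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7")


def mim(
    n_ab: int, n_a: int, n_b: int, n_docs: int, floor: float = MIM_FLOOR
) -> float:
    """Mutual information measure in bits:
    ``log2((n_ab/n_docs) / ((n_a/n_docs) * (n_b/n_docs)))``.

    When any count is zero the score is undefined and the configured
    floor is returned so feature vectors stay finite.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    if not 0 <= n_ab <= min(n_a, n_b) <= n_docs:
        raise ValueError(
            f"count ordering violated: n_ab={n_ab}, n_a={n_a}, n_b={n_b}, "
            f"n_docs={n_docs}"
        )
    if n_ab == 0 or n_a == 0 or n_b == 0:
        return floor
    return math.log2((n_ab * n_docs) / (n_a * n_b))


@dataclass(frozen=True)
class FeatureVector:
    starting: str
    concept: str
    f1: float
    f2: float
    f3: int
    f4: int
    f5: int
    f6: int
    f7: int

    def __post_init__(self) -> None:
        for name in ("f3", "f4", "f5", "f6", "f7"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if self.f4 > self.f3 or self.f3 > self.f5 or self.f6 > self.f5:
            raise ValueError(
                f"implication chain violated for pair "
                f"({self.starting!r}, {self.concept!r})"
            )
        if not (math.isfinite(self.f1) and math.isfinite(self.f2)):
            raise ValueError("f1/f2 must be finite")

    def values(self) -> np.ndarray:
        return np.array(
            [self.f1, self.f2, self.f3, self.f4, self.f5, self.f6, self.f7],
            dtype=float,
        )


class TextEvidence:
    """Precomputed per-sentence mention sets and interaction flags for a
    corpus, shared by feature extraction and the ranking rules."""

    def __init__(
        self,
        records: Sequence[MedlineRecord],
        concepts: Iterable[str],
        lexicon: InteractionLexicon | None = None,
    ) -> None:
        self.concepts = {normalize_concept(c) for c in concepts if c.strip()}
        self.lexicon = lexicon
        # per record: list of (concept set, interaction flag, source)
        self._records: list[list[tuple[set[str], bool, str]]] = []
        for rec in records:
            sentences = segment_sentences(rec)
            sets: list[set[str]] = [set() for _ in sentences]
            for m in find_mentions(rec, self.concepts):
                sets[m.sentence_index].add(m.concept)
            self._records.append(
                [
                    (
                        sets[s.index],
                        bool(lexicon) and contains_interaction_word(lexicon, s.text),
                        s.source,
                    )
                    for s in sentences
                ]
            )

    def _pairs(self, a: str, b: str):
        a, b = normalize_concept(a), normalize_concept(b)
        return a, b

    def sentence_pair(self, a: str, b: str, require_interaction: bool = False) -> bool:
        a, b = self._pairs(a, b)
        for sents in self._records:
            for concepts, flag, _ in sents:
                if a in concepts and b in concepts and (flag or not require_interaction):
                    return True
        return False

    def window_pair(self, a: str, b: str, require_interaction: bool = False) -> bool:
        a, b = self._pairs(a, b)
        for sents in self._records:
            for i in range(len(sents)):
                hi = min(i + 1, len(sents) - 1)
                concepts = sents[i][0] | sents[hi][0]
                flag = sents[i][1] or sents[hi][1]
                if a in concepts and b in concepts and (flag or not require_interaction):
                    return True
        return False

    def _field_pair(self, a: str, b: str, source: str) -> bool:
        a, b = self._pairs(a, b)
        for sents in self._records:
            present: set[str] = set()
            for concepts, _, src in sents:
                if src == source:
                    present |= concepts
            if a in present and b in present:
                return True
        return False

    def abstract_pair(self, a: str, b: str) -> bool:
        return self._field_pair(a, b, "abstract")

    def title_pair(self, a: str, b: str) -> bool:
        return self._field_pair(a, b, "title")

    def tiab_pair(self, a: str, b: str) -> bool:
        a, b = self._pairs(a, b)
        for sents in self._records:
            present = set().union(*(c for c, _, _ in sents)) if sents else set()
            if a in present and b in present:
                return True
        return False


def extract_features(
    c: str,
    b: str,
    mesh_index: CooccurrenceIndex,
    tiab_index: CooccurrenceIndex,
    evidence: TextEvidence,
    floor: float = MIM_FLOOR,
    strict_f7: bool = False,
) -> FeatureVector:
    """Assemble the 7-feature vector for pair (c, b).

    ``strict_f7`` switches feature VII to the strict reading: both
    concepts co-occur in some abstract but never jointly in any title.
    """
    c_n, b_n = normalize_concept(c), normalize_concept(b)
    f1 = mim(
        mesh_index.cooc_of(c_n, b_n),
        mesh_index.occ_of(c_n),
        mesh_index.occ_of(b_n),
        mesh_index.n_docs,
        floor=floor,
    )
    f2 = mim(
        tiab_index.cooc_of(c_n, b_n),
        tiab_index.occ_of(c_n),
        tiab_index.occ_of(b_n),
        tiab_index.n_docs,
        floor=floor,
    )
    f3 = int(evidence.sentence_pair(c_n, b_n))
    f4 = int(evidence.sentence_pair(c_n, b_n, require_interaction=True))
    f5 = int(evidence.window_pair(c_n, b_n))
    f6 = int(evidence.window_pair(c_n, b_n, require_interaction=True))
    f7 = int(evidence.abstract_pair(c_n, b_n))
    if strict_f7 and f7:
        f7 = int(not evidence.title_pair(c_n, b_n))
    return FeatureVector(
        starting=c_n, concept=b_n, f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, f6=f6, f7=f7
    )


def feature_frame(
    vectors: Sequence[FeatureVector], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Feature matrix as a DataFrame (one row per linking concept)."""
    rows = [
        {"concept": v.concept, **dict(zip(FEATURE_NAMES, v.values()))}
        for v in vectors
    ]
    frame = pd.DataFrame(rows, columns=["concept", *FEATURE_NAMES])
    if labels is not None:
        if len(labels) != len(vectors):
            raise ValueError("labels and vectors length mismatch")
        frame["label"] = list(labels)
    return frame


def write_feature_matrix(
    vectors: Sequence[FeatureVector],
    stream: IO[str],
    labels: Sequence[str] | None = None,
) -> None:
    feature_frame(vectors, labels).to_csv(stream, sep="\t", index=False)
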