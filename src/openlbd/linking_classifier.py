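"""Training-set construction rules and the linking-concept classifier.

Positive examples are candidate linking concepts with interaction
evidence against the starting concept (f4 or f6 set), plus optional
manually supplied labels. Negatives fall in three categories: too-general
concepts (document-frequency rule or stop list), concepts never
co-occurring with the start within a two-sentence window (f5=0), and
concepts co-occurring without any interaction word (f5=1, f4=f6=0). The
two classes are balanced by seeded down-sampling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cooccurrence import build_all_indices, candidate_linking_concepts
from .features import MIM_FLOOR, FeatureVector, TextEvidence, extract_features
from .lexicon import InteractionLexicon, too_general_concepts
from .medline_io import MedlineRecord, normalize_concept

__all__ = [
    "LabeledExample",
    "ClassifierModel",
    "TrainingSetError",
    "build_training_set",
    "train",
    "classify",
]

POSITIVE = "positive"
NEGATIVE = "negative"

PROVENANCES = (
    "interaction_with_start",
    "swanson_verified",
    "too_general",
    "no_window_cooccurrence",
    "cooccur_no_interaction",
    "manual",
)


class TrainingSetError(ValueError):
    """Raised when a required example category is empty."""


@dataclass(frozen=True)
class LabeledExample:
    vector: FeatureVector
    label: str
    provenance: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"bad provenance {self.provenance!r}")


@dataclass
class ClassifierModel:
    pipeline: Pipeline
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.metadata.get("n_features", 7))


def build_training_set(
    records: Sequence[MedlineRecord],
    start: str,
    lexicon: InteractionLexicon,
    df_quantile: float = 0.99,
    stop_concepts: Iterable[str] = (),
    manual_labels: Mapping[str, str] | None = None,
    seed: int = 0,
    floor: float = MIM_FLOOR,
) -> list[LabeledExample]:
    """Apply the labeling rules to a corpus and return a balanced set.

    Negatives are drawn round-robin across the non-empty negative
    categories so no single rule dominates. Raises
    :class:`TrainingSetError` when either class ends up empty.
    """
    start_n = normalize_concept(start)
    mesh_index = build_all_indices(records, [])["mesh_field"]
    candidates = sorted(candidate_linking_concepts(mesh_index, start_n))
    if not candidates:
        raise TrainingSetError("no candidate linking concepts for the start concept")
    indices = build_all_indices(records, {start_n, *candidates})
    evidence = TextEvidence(records, {start_n, *candidates}, lexicon)
    vectors = {
        b: extract_features(
            start_n, b, indices["mesh_field"], indices["tiab"], evidence, floor=floor
        )
        for b in candidates
    }

    manual = {
        normalize_concept(c): lab for c, lab in (manual_labels or {}).items()
    }
    df = {b: mesh_index.occ_of(b) for b in candidates}
    general = too_general_concepts(df, quantile=df_quantile, stop_concepts=stop_concepts)

    positives: list[LabeledExample] = []
    by_category: dict[str, list[LabeledExample]] = {
        "too_general": [],
        "no_window_cooccurrence": [],
        "cooccur_no_interaction": [],
        "manual": [],
    }
    for b in candidates:
        v = vectors[b]
        override = manual.get(b)
        if override == POSITIVE or (
            override is None and (v.f4 == 1 or v.f6 == 1)
        ):
            positives.append(
                LabeledExample(
                    v,
                    POSITIVE,
                    "manual" if override == POSITIVE else "interaction_with_start",
                )
            )
            continue
        if override == NEGATIVE:
            by_category["manual"].append(LabeledExample(v, NEGATIVE, "manual"))
            continue
        if b in general:
            by_category["too_general"].append(LabeledExample(v, NEGATIVE, "too_general"))
        elif v.f5 == 0:
            by_category["no_window_cooccurrence"].append(
                LabeledExample(v, NEGATIVE, "no_window_cooccurrence")
            )
        elif v.f4 == 0 and v.f6 == 0:
            by_category["cooccur_no_interaction"].append(
                LabeledExample(v, NEGATIVE, "cooccur_no_interaction")
            )
        # else: interaction evidence but manually labeled negative, or
        # no category applies; such concepts are left out of training.

    if not positives:
        raise TrainingSetError("positive class is empty: no interaction evidence")
    nonempty = [cat for cat in by_category if by_category[cat]]
    if not nonempty:
        raise TrainingSetError("negative class is empty: no rule produced negatives")

    rng = random.Random(seed)
    for cat in nonempty:
        rng.shuffle(by_category[cat])
    # round-robin across categories for even coverage
    negatives: list[LabeledExample] = []
    depth = 0
    while True:
        added = False
        for cat in nonempty:
            if depth < len(by_category[cat]):
                negatives.append(by_category[cat][depth])
                added = True
        if not added:
            break
        depth += 1

    size = min(len(positives), len(negatives))
    rng.shuffle(positives)
    examples = positives[:size] + negatives[:size]
    examples.sort(key=lambda e: (e.label, e.vector.concept))
    return examples


def train(
    examples: Sequence[LabeledExample],
    c: float = 1.0,
    kernel: str = "linear",
    seed: int = 0,
) -> ClassifierModel:
    """Fit the margin classifier (standardized features, linear kernel by
    default). Deterministic for a fixed seed."""
    labels = {e.label for e in examples}
    if labels != {POSITIVE, NEGATIVE}:
        raise TrainingSetError(f"need both classes to train, got {sorted(labels)}")
    for label in (POSITIVE, NEGATIVE):
        if sum(1 for e in examples if e.label == label) < 2:
            raise TrainingSetError(f"need >= 2 examples of class {label!r}")
    x = np.vstack([e.vector.values() for e in examples])
    y = np.array([1 if e.label == POSITIVE else 0 for e in examples])
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=c, random_state=seed)),
        ]
    )
    pipeline.fit(x, y)
    return ClassifierModel(
        pipeline=pipeline,
        metadata={
            "kernel": kernel,
            "C": c,
            "seed": seed,
            "n_features": x.shape[1],
            "n_examples": len(examples),
        },
    )


def classify(
    model: ClassifierModel, vectors: Sequence[FeatureVector]
) -> list[str]:
    """Label feature vectors, preserving input order."""
    if not vectors:
        return []
    x = np.vstack([v.values() for v in vectors])
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature schema mismatch: model expects {model.n_features}, "
            f"got {x.shape[1]}"
        )
    pred = model.pipeline.predict(x)
    return [POSITIVE if p == 1 else NEGATIVE for p in pred]
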