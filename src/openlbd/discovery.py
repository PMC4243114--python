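"""Open discovery C -> B -> A: target discovery, useful-linking rules,
tie-aware ranking and the percentage-of-useful-LTC evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .cooccurrence import (
    CooccurrenceIndex,
    build_all_indices,
    candidate_linking_concepts,
    filter_by_year,
)
from .features import MIM_FLOOR, TextEvidence, extract_features
from .lexicon import (
    InteractionLexicon,
    SemanticTypeMap,
    TypeFilterConfig,
    has_type,
)
from .linking_classifier import (
    POSITIVE,
    ClassifierModel,
    build_training_set,
    classify,
    train,
)
from .medline_io import MedlineRecord, normalize_concept

__all__ = [
    "RULES",
    "RankedTarget",
    "EvaluationResult",
    "DiscoveryConfig",
    "DiscoveryReport",
    "discover_targets",
    "useful_linking_set",
    "rank_targets",
    "percent_useful_ltc",
    "run_open_discovery",
]

RULES = ("plain_ltc", "rule1", "rule2")
EVALUATION_MODES = ("rule1", "rule2", "mesh_vs_designated")


@dataclass(frozen=True)
class RankedTarget:
    concept: str
    ltc: int
    useful_linking: frozenset[str]
    useful_ltc: int
    rank: int
    type_rank: int | None = None

    def __post_init__(self) -> None:
        if self.useful_ltc != len(self.useful_linking):
            raise ValueError("useful_ltc must equal |useful_linking|")
        if self.useful_ltc > self.ltc:
            raise ValueError("useful_ltc cannot exceed ltc")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class EvaluationResult:
    n_useful: int
    n_all: int
    percentage: float
    designated_rank: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_useful <= self.n_all:
            raise ValueError("need 0 <= n_useful <= n_all")
        if not 0.0 <= self.percentage <= 100.0:
            raise ValueError("percentage outside [0, 100]")


@dataclass(frozen=True)
class DiscoveryConfig:
    start: str
    max_year: int | None = None
    rule: str = "rule1"
    type_filter: TypeFilterConfig = field(default_factory=TypeFilterConfig)
    use_classifier: bool = True
    seed: int = 0
    mim_floor: float = MIM_FLOOR
    df_quantile: float = 0.99
    designated_target: str | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")


@dataclass
class DiscoveryReport:
    """Machine-readable run summary."""

    config: DiscoveryConfig
    n_records: int
    preliminary_linking: frozenset[str]
    active_linking: frozenset[str]
    labels: dict[str, str]
    targets: list[RankedTarget]
    evaluation: EvaluationResult


def discover_targets(
    positive_b: Iterable[str],
    mesh_index: CooccurrenceIndex,
    preliminary_b: Iterable[str],
    c: str,
    type_filter: TypeFilterConfig | None = None,
    type_map: SemanticTypeMap | None = None,
) -> dict[str, set[str]]:
    """Map each surviving target concept A to the linking concepts that
    reach it.

    A-candidates co-occur (MeSH field) with at least one positive linking
    concept; excluded are the starting concept itself, any concept
    co-occurring with it, members of the preliminary linking set, and —
    when the type filter is enabled — concepts outside the target types.
    """
    c_n = normalize_concept(c)
    positives = {normalize_concept(b) for b in positive_b}
    preliminary = {normalize_concept(b) for b in preliminary_b}
    if not positives:
        warnings.warn("empty positive linking set: no targets", stacklevel=2)
        return {}
    links: dict[str, set[str]] = {}
    for (x, y), n in mesh_index.cooc.items():
        if n < 1:
            continue
        for a, b in ((x, y), (y, x)):
            if b in positives and a != c_n:
                links.setdefault(a, set()).add(b)
    result: dict[str, set[str]] = {}
    for a, linked in links.items():
        if a in preliminary:
            continue
        if mesh_index.cooc_of(a, c_n) >= 1:
            continue
        if (
            type_filter is not None
            and type_filter.enabled
            and not (
                type_map is not None
                and has_type(type_map, a, type_filter.target_types)
            )
        ):
            continue
        result[a] = linked
    return result


def useful_linking_set(
    a: str,
    linking: Iterable[str],
    rule: str,
    evidence: TextEvidence,
    lexicon: InteractionLexicon | None = None,
) -> set[str]:
    """Linking concepts whose connection to target ``a`` satisfies the
    active rule: title/abstract co-occurrence (rule1) or same-sentence
    co-occurrence with an interaction word (rule2)."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    a_n = normalize_concept(a)
    linking_n = {normalize_concept(b) for b in linking}
    if rule == "plain_ltc":
        return linking_n
    if rule == "rule1":
        return {b for b in linking_n if evidence.tiab_pair(b, a_n)}
    if lexicon is None or not lexicon:
        raise ValueError("rule2 requires a non-empty interaction lexicon")
    return {
        b
        for b in linking_n
        if evidence.sentence_pair(b, a_n, require_interaction=True)
    }


def _dense_ranks(counts: Sequence[int]) -> list[int]:
    distinct = sorted(set(counts), reverse=True)
    position = {v: i + 1 for i, v in enumerate(distinct)}
    return [position[v] for v in counts]


def rank_targets(
    targets: Mapping[str, tuple[int, Iterable[str]]],
    type_map: SemanticTypeMap | None = None,
    target_types: Iterable[str] | None = None,
) -> list[RankedTarget]:
    """Rank targets by descending useful-LTC with dense (tie-sharing)
    ranks; within a rank, listing order is alphabetical.

    ``targets`` maps each concept to ``(ltc, useful_linking_set)``. When a
    type map is given, ``type_rank`` is the best dense rank the target
    attains within any one of its admitted semantic types.
    """
    items = sorted(
        targets.items(), key=lambda kv: (-len(set(kv[1][1])), kv[0])
    )
    counts = [len(set(useful)) for _, (_, useful) in items]
    ranks = _dense_ranks(counts)

    type_ranks: dict[str, int] = {}
    if type_map is not None:
        admitted = set(target_types) if target_types is not None else None
        per_type: dict[str, list[tuple[str, int]]] = {}
        for concept, (_, useful) in items:
            for t in type_map.types_of(concept):
                if admitted is None or t in admitted:
                    per_type.setdefault(t, []).append((concept, len(set(useful))))
        for t, members in per_type.items():
            members.sort(key=lambda kv: (-kv[1], kv[0]))
            for concept, r in zip(
                (m[0] for m in members), _dense_ranks([m[1] for m in members])
            ):
                if concept not in type_ranks or r < type_ranks[concept]:
                    type_ranks[concept] = r

    return [
        RankedTarget(
            concept=concept,
            ltc=ltc,
            useful_linking=frozenset(set(useful)),
            useful_ltc=len(set(useful)),
            rank=rank,
            type_rank=type_ranks.get(concept),
        )
        for (concept, (ltc, useful)), rank in zip(items, ranks)
    ]


def percent_useful_ltc(n_useful: int, n_all: int) -> float:
    """``100 * n_useful / n_all`` — the percentage-of-useful-LTC metric."""
    if n_all < 1:
        raise ValueError("n_all must be >= 1")
    if not 0 <= n_useful <= n_all:
        raise ValueError("need 0 <= n_useful <= n_all")
    return 100.0 * n_useful / n_all


def run_open_discovery(
    config: DiscoveryConfig,
    records: Sequence[MedlineRecord],
    lexicon: InteractionLexicon,
    type_map: SemanticTypeMap | None = None,
    model: ClassifierModel | None = None,
) -> DiscoveryReport:
    """Execute the full open-discovery pipeline.

    Stages: year filter -> candidate linking concepts -> feature
    extraction -> classifier pruning (optional) -> target discovery ->
    useful-linking rules -> ranking -> evaluation.
    """
    c = normalize_concept(config.start)
    recs = filter_by_year(records, config.max_year)
    all_concepts = {t for r in recs for t in r.mesh_terms} | {c}
    indices = build_all_indices(recs, all_concepts)
    mesh_index, tiab_index = indices["mesh_field"], indices["tiab"]

    preliminary = candidate_linking_concepts(mesh_index, c)
    if config.type_filter.enabled and type_map is not None:
        candidates = {
            b for b in preliminary
            if has_type(type_map, b, config.type_filter.linking_types)
        }
    else:
        candidates = set(preliminary)

    evidence = TextEvidence(recs, all_concepts, lexicon)
    ordered = sorted(candidates)
    vectors = [
        extract_features(
            c, b, mesh_index, tiab_index, evidence, floor=config.mim_floor
        )
        for b in ordered
    ]

    labels: dict[str, str] = {}
    if config.use_classifier and ordered:
        if model is None:
            examples = build_training_set(
                recs,
                c,
                lexicon,
                df_quantile=config.df_quantile,
                seed=config.seed,
            )
            model = train(examples, seed=config.seed)
        labels = dict(zip(ordered, classify(model, vectors)))
        active = {b for b in ordered if labels[b] == POSITIVE}
    else:
        labels = {b: POSITIVE for b in ordered}
        active = set(ordered)

    target_links = discover_targets(
        active, mesh_index, preliminary, c,
        type_filter=config.type_filter, type_map=type_map,
    )
    per_target: dict[str, tuple[int, set[str]]] = {}
    for a, linked in target_links.items():
        useful = useful_linking_set(a, linked, config.rule, evidence, lexicon)
        per_target[a] = (len(linked), useful)
    ranked = rank_targets(
        per_target,
        type_map=type_map,
        target_types=config.type_filter.target_types
        if config.type_filter.enabled
        else None,
    )

    evaluation = _evaluate(
        config, active, per_target, ranked, mesh_index, evidence, lexicon
    )
    return DiscoveryReport(
        config=config,
        n_records=len(recs),
        preliminary_linking=frozenset(preliminary),
        active_linking=frozenset(active),
        labels=labels,
        targets=ranked,
        evaluation=evaluation,
    )


def _evaluate(
    config: DiscoveryConfig,
    active: set[str],
    per_target: Mapping[str, tuple[int, set[str]]],
    ranked: Sequence[RankedTarget],
    mesh_index: CooccurrenceIndex,
    evidence: TextEvidence,
    lexicon: InteractionLexicon,
) -> EvaluationResult:
    n_all = len(active)
    designated = (
        normalize_concept(config.designated_target)
        if config.designated_target
        else None
    )
    if designated is not None:
        _, useful = per_target.get(designated, (0, set()))
        n_useful = len(useful)
        designated_rank = next(
            (t.rank for t in ranked if t.concept == designated), None
        )
    else:
        union: set[str] = set()
        for _, useful in per_target.values():
            union |= useful
        n_useful = len(union)
        designated_rank = None
    percentage = percent_useful_ltc(n_useful, n_all) if n_all else 0.0
    return EvaluationResult(
        n_useful=n_useful,
        n_all=n_all,
        percentage=percentage,
        designated_rank=designated_rank,
    )


def evaluate_designated(
    designated: str,
    active_linking: Iterable[str],
    mode: str,
    mesh_index: CooccurrenceIndex,
    evidence: TextEvidence,
    lexicon: InteractionLexicon | None = None,
) -> EvaluationResult:
    """Score one designated known target under an evaluation mode.

    ``mesh_vs_designated`` counts linking concepts co-occurring with the
    designated target in the MeSH field as useful (the feature-ablation
    protocol); ``rule1``/``rule2`` apply the textual rules.
    """
    if mode not in EVALUATION_MODES:
        raise ValueError(f"mode must be one of {EVALUATION_MODES}")
    a = normalize_concept(designated)
    active = {normalize_concept(b) for b in active_linking}
    if not active:
        raise ValueError("active linking set is empty")
    if mode == "mesh_vs_designated":
        useful = {b for b in active if mesh_index.cooc_of(b, a) >= 1}
    else:
        useful = useful_linking_set(a, active, mode, evidence, lexicon)
    return EvaluationResult(
        n_useful=len(useful),
        n_all=len(active),
        percentage=percent_useful_ltc(len(useful), len(active)),
    )
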