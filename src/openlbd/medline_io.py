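"""MEDLINE-style flat-file I/O, sentence segmentation and mention resolution.

The dialect handled here is the classic tag-prefixed layout::

    PMID- 8655342
    DP  - 1985 Jun
    TI  - Some title.
    AB  - First sentence of the abstract. Second sentence.
    MH  - Blood Viscosity
    MH  - *Raynaud Disease/therapy

Tags occupy four characters (padded with spaces), followed by ``"- "``.
Continuation lines begin with whitespace and are joined with a single
space. Records are separated by blank lines.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "MedlineRecord",
    "Sentence",
    "Mention",
    "MedlineParseError",
    "normalize_concept",
    "parse_medline",
    "write_medline",
    "segment_sentences",
    "find_mentions",
]


class MedlineParseError(ValueError):
    """Raised for malformed flat-file input; carries a line number when known."""


_WS_RE = re.compile(r"\s+")


def normalize_concept(raw: str) -> str:
    """Normalize a concept string: lowercase, collapse whitespace, strip
    MeSH qualifier suffixes (text after ``/``) and emphasis ``*`` markers."""
    text = raw.split("/", 1)[0]
    text = text.lstrip("*").strip()
    return _WS_RE.sub(" ", text).lower()


@dataclass(frozen=True)
class MedlineRecord:
    """One bibliographic record."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.year is not None and self.year < 1800:
            raise ValueError(f"implausible year {self.year!r} for pmid {self.pmid}")
        object.__setattr__(self, "mesh_terms", tuple(self.mesh_terms))


@dataclass(frozen=True)
class Sentence:
    record_id: str
    index: int
    text: str
    source: str  # "title" | "abstract"


@dataclass(frozen=True)
class Mention:
    concept: str
    sentence_index: int
    via_abbreviation: bool = False


_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s{0,3}- ?(.*)$")
_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _coerce_stream(stream: IO[str] | str) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(io.StringIO(stream))
    return iter(stream)


def parse_medline(stream: IO[str] | str) -> list[MedlineRecord]:
    """Parse a tag-prefixed MEDLINE flat file into records.

    Raises :class:`MedlineParseError` on a block lacking a PMID (with the
    line number of the block start) or on a duplicate PMID.
    """
    records: list[MedlineRecord] = []
    seen: set[str] = set()
    fields: list[tuple[str, str]] = []  # (tag, value) in order of appearance
    block_start = 1

    def flush(line_no: int) -> None:
        nonlocal fields
        if not fields:
            return
        tags = dict()
        mesh: list[str] = []
        for tag, value in fields:
            if tag == "MH":
                mesh.append(value)
            elif tag not in tags:  # first occurrence wins for scalar tags
                tags[tag] = value
        pmid = tags.get("PMID", "").strip()
        if not pmid:
            raise MedlineParseError(
                f"record block starting at line {block_start} has no PMID"
            )
        if pmid in seen:
            raise MedlineParseError(f"duplicate PMID {pmid!r}")
        seen.add(pmid)
        year = None
        if "DP" in tags:
            m = _YEAR_RE.search(tags["DP"])
            if m:
                year = int(m.group(1))
        mesh_norm: list[str] = []
        for raw in mesh:
            term = normalize_concept(raw)
            if term and term not in mesh_norm:
                mesh_norm.append(term)
        records.append(
            MedlineRecord(
                pmid=pmid,
                title=tags.get("TI", ""),
                abstract=tags.get("AB", ""),
                mesh_terms=tuple(mesh_norm),
                year=year,
            )
        )
        fields = []

    line_no = 0
    for line_no, line in enumerate(_coerce_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(line_no)
            block_start = line_no + 1
            continue
        if line[:1].isspace():
            if not fields:
                raise MedlineParseError(
                    f"continuation line {line_no} without a preceding tag"
                )
            tag, value = fields[-1]
            fields[-1] = (tag, f"{value} {line.strip()}" if value else line.strip())
            continue
        m = _TAG_RE.match(line)
        if m is None:
            raise MedlineParseError(f"unparseable line {line_no}: {line!r}")
        if not fields:
            block_start = line_no
        fields.append((m.group(1), m.group(2).strip()))
    flush(line_no + 1)
    return records


def write_medline(records: Iterable[MedlineRecord]) -> str:
    """Serialize records in the dialect :func:`parse_medline` accepts.

    Field order is PMID, DP, TI, AB, then MH lines.
    """
    blocks: list[str] = []
    for rec in records:
        lines = [f"PMID- {rec.pmid}"]
        if rec.year is not None:
            lines.append(f"DP  - {rec.year}")
        if rec.title:
            lines.append(f"TI  - {rec.title}")
        if rec.abstract:
            lines.append(f"AB  - {rec.abstract}")
        for term in rec.mesh_terms:
            lines.append(f"MH  - {term}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# Tokens (lowercased, including the trailing period) that do not end a
# sentence even when followed by whitespace and an uppercase letter.
ABBREVIATION_EXCEPTIONS = frozenset(
    {
        "e.g.",
        "i.e.",
        "etc.",
        "vs.",
        "cf.",
        "al.",
        "fig.",
        "figs.",
        "no.",
        "approx.",
        "dr.",
        "st.",
        "spp.",
        "sp.",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?](?=\s+[A-Z0-9])")


def _split_text(text: str) -> list[str]:
    """Split on terminal punctuation followed by whitespace and an
    uppercase letter or digit, skipping known abbreviations."""
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        token = text[start:end].rsplit(None, 1)[-1].lower()
        if token in ABBREVIATION_EXCEPTIONS:
            continue
        piece = text[start:end].strip()
        if piece:
            pieces.append(piece)
        start = end
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


def segment_sentences(record: MedlineRecord) -> list[Sentence]:
    """Return the record's sentences: the title as a single sentence at
    index 0, then the abstract split on sentence boundaries."""
    sentences: list[Sentence] = []
    idx = 0
    title = record.title.strip()
    if title:
        sentences.append(Sentence(record.pmid, idx, title, "title"))
        idx += 1
    for piece in _split_text(record.abstract):
        sentences.append(Sentence(record.pmid, idx, piece, "abstract"))
        idx += 1
    return sentences


def _concept_pattern(concept: str) -> re.Pattern[str]:
    tokens = concept.split()
    body = r"\s+".join(re.escape(t) for t in tokens)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


_ABBREV_DEF_RE = re.compile(r"\s*\(([^\s()]{1,10})\)")


def find_mentions(
    record: MedlineRecord, concepts: Iterable[str]
) -> list[Mention]:
    """Locate concept mentions in a record's sentences.

    Matching is case-insensitive on word boundaries; each concept is
    matched independently, so overlapping concepts may both be reported
    (mention sets are therefore monotone in the concept set). When a
    matched concept is immediately followed by a parenthesized single
    token of 1-10 characters, that token is registered as a record-local
    abbreviation; subsequent whole-token matches of it yield mentions
    with ``via_abbreviation=True``.
    """
    concept_list = sorted({normalize_concept(c) for c in concepts if c.strip()})
    patterns = {c: _concept_pattern(c) for c in concept_list}
    sentences = segment_sentences(record)
    # abbreviation token -> (concept, defining sentence index, char offset past ")")
    abbrevs: dict[str, tuple[str, int, int]] = {}
    found: dict[tuple[str, int], bool] = {}  # (concept, sentence idx) -> direct?

    for sent in sentences:
        for concept in concept_list:
            for m in patterns[concept].finditer(sent.text):
                found[(concept, sent.index)] = True
                d = _ABBREV_DEF_RE.match(sent.text, m.end())
                if d is not None:
                    token = d.group(1).lower()
                    if token not in abbrevs and token not in patterns:
                        abbrevs[token] = (concept, sent.index, d.end())
        for token, (concept, def_idx, def_end) in abbrevs.items():
            pat = re.compile(rf"(?<!\w){re.escape(token)}(?!\w)", re.IGNORECASE)
            for m in pat.finditer(sent.text):
                if sent.index < def_idx:
                    continue
                if sent.index == def_idx and m.start() < def_end:
                    continue  # the defining "(ABBR)" itself is not a mention
                found.setdefault((concept, sent.index), False)

    return [
        Mention(concept=c, sentence_index=i, via_abbreviation=not direct)
        for (c, i), direct in sorted(found.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]
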