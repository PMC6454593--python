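"""Windowed pattern learning from an inline-annotated corpus.

Transgender mentions that carry no transgender-specific keyword ("who now
identify as male") defeat a pure lexicon. This module learns literal token
contexts around annotated mention spans: every combination of left/right
windows up to ``beta`` tokens becomes a candidate, candidates are matched
back against the corpus, and only those with enough correct matches
(support) and a high enough correct-match rate (confidence) survive.

Two inline annotation dialects are accepted::

    ... criteria text [who now identify as male|TGM] more text ...
    ... criteria text <TG_Start>who now identify as male<TG_End> more text ...
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .preprocessing import (
    PreprocessingConfig,
    Sentence,
    Section,
    default_config,
    sentences_from_section,
)

TG_START = "<TG_Start>"
TG_END = "<TG_End>"

_BRACKET_SPAN = re.compile(r"\[([^\[\]|]+)\|[^\[\]|]*\]")
_TAG = re.compile(r"<\s*TG_(Start|End)\s*>", re.IGNORECASE)

#: default cap on slot length during match-back and detection
DEFAULT_SLOT_MAX = 10


class CorpusFormatError(ValueError):
    """Unbalanced or nested annotation tags."""


@dataclass
class AnnotatedSentence:
    """A sentence plus gold mention spans as half-open token ranges."""

    sentence: Sentence
    spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class PatternLearningConfig:
    beta: int = 7
    support_threshold: int = 4
    confidence_threshold: float = 0.7
    slot_max: int = DEFAULT_SLOT_MAX

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.support_threshold < 1:
            raise ValueError("support_threshold must be >= 1")
        if not (0 < self.confidence_threshold <= 1):
            raise ValueError("confidence_threshold must be in (0, 1]")


@dataclass(frozen=True)
class Pattern:
    """A literal token context around a single transgender slot."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    support: int = 0
    confidence: float = 0.0

    @property
    def context_size(self) -> int:
        return len(self.left) + len(self.right)

    def render(self) -> str:
        return " ".join([*self.left, "<TG>", *self.right])

    def to_json(self) -> str:
        return json.dumps(
            {
                "left": list(self.left),
                "right": list(self.right),
                "support": self.support,
                "confidence": self.confidence,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "Pattern":
        d = json.loads(line)
        return cls(
            tuple(d["left"]), tuple(d["right"]), int(d["support"]), float(d["confidence"])
        )


PatternSet = list[Pattern]


def save_patterns(patterns: PatternSet, path: str) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(p.to_json() + "\n")


def load_patterns(path: str) -> PatternSet:
    with open(path) as fh:
        return [Pattern.from_json(line) for line in fh if line.strip()]


def _strip_tags(text: str) -> tuple[str, list[tuple[int, int]]]:
    """Remove TG tags from raw text, returning clean text and char spans."""
    text = _BRACKET_SPAN.sub(lambda m: f"{TG_START}{m.group(1)}{TG_END}", text)
    clean: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    open_at: int | None = None
    for m in _TAG.finditer(text):
        clean.append(text[pos : m.start()])
        pos = m.end()
        here = sum(len(c) for c in clean)
        if m.group(1).lower() == "start":
            if open_at is not None:
                raise CorpusFormatError(f"nested {TG_START} at char {m.start()}")
            open_at = here
        else:
            if open_at is None:
                raise CorpusFormatError(f"unmatched {TG_END} at char {m.start()}")
            spans.append((open_at, here))
            open_at = None
    if open_at is not None:
        raise CorpusFormatError(f"unclosed {TG_START} (span opened at char {open_at})")
    clean.append(text[pos:])
    return "".join(clean), spans


def normalize_annotations(
    corpus: str,
    trial_id: str = "corpus",
    section: Section = Section.OTHER,
    cfg: PreprocessingConfig | None = None,
) -> list[AnnotatedSentence]:
    """Parse inline annotations, split sentences, and map spans to tokens."""
    cfg = cfg or default_config()
    clean, char_spans = _strip_tags(corpus)
    sentences = sentences_from_section(trial_id, section, clean, cfg)

    # recover each sentence's absolute start in the clean text
    out: list[AnnotatedSentence] = []
    cursor = 0
    for sent in sentences:
        abs_start = clean.index(sent.text, cursor)
        cursor = abs_start + len(sent.text)
        spans_here: list[tuple[int, int]] = []
        for cs, ce in char_spans:
            if ce <= abs_start or cs >= abs_start + len(sent.text):
                continue
            if cs < abs_start or ce > abs_start + len(sent.text):
                raise CorpusFormatError(
                    f"annotated span crosses a sentence boundary near char {cs}"
                )
            rel_s, rel_e = cs - abs_start, ce - abs_start
            toks = [
                i
                for i, t in enumerate(sent.tokens)
                if t.start < rel_e and t.end > rel_s
            ]
            if toks:
                spans_here.append((toks[0], toks[-1] + 1))
        out.append(AnnotatedSentence(sent, sorted(spans_here)))
    return out


def extract_candidates(
    sentences: Iterable[AnnotatedSentence], cfg: PatternLearningConfig
) -> Counter:
    """All (left, right) window pairs around gold spans, with multiplicity.

    For a span, left/right windows of lengths ``0..beta`` (truncated at the
    sentence edges) are combined; the vacuous empty-empty pair is skipped.
    """
    counts: Counter = Counter()
    for ann in sentences:
        surfaces = ann.sentence.surfaces
        for s, e in ann.spans:
            max_l = min(cfg.beta, s)
            max_r = min(cfg.beta, len(surfaces) - e)
            for l in range(max_l + 1):
                for r in range(max_r + 1):
                    if l == 0 and r == 0:
                        continue
                    counts[(tuple(surfaces[s - l : s]), tuple(surfaces[e : e + r]))] += 1
    return counts


def _find_matches(
    surfaces: Sequence[str],
    left: tuple[str, ...],
    right: tuple[str, ...],
    slot_max: int,
) -> list[tuple[int, int, bool, bool]]:
    """Slot matches of a context pair: (start, end, left_anchored, right_anchored).

    Both-sided patterns pair each left-context occurrence with the nearest
    right-context occurrence within ``slot_max`` tokens. One-sided patterns
    anchor only one slot edge; the free edge extends up to ``slot_max``
    tokens (clipped at the sentence) and is marked unanchored.
    """
    n = len(surfaces)
    lefts = (
        [i + len(left) for i in range(n - len(left) + 1)
         if tuple(surfaces[i : i + len(left)]) == left]
        if left
        else None
    )
    rights = (
        [i for i in range(n - len(right) + 1)
         if tuple(surfaces[i : i + len(right)]) == right]
        if right
        else None
    )
    matches: list[tuple[int, int, bool, bool]] = []
    if lefts is not None and rights is not None:
        for p in lefts:
            gaps = [q for q in rights if 1 <= q - p <= slot_max]
            if gaps:
                matches.append((p, min(gaps), True, True))
    elif lefts is not None:
        for p in lefts:
            if p < n:
                matches.append((p, min(p + slot_max, n), True, False))
    elif rights is not None:
        for q in rights:
            if q > 0:
                matches.append((max(q - slot_max, 0), q, False, True))
    return matches


def _is_correct(
    match: tuple[int, int, bool, bool], gold: list[tuple[int, int]]
) -> bool:
    s, e, la, ra = match
    if la and ra:
        return (s, e) in gold
    if la:
        return any(gs == s for gs, _ in gold)
    return any(ge == e for _, ge in gold)


def score_patterns(
    candidates: Counter | Iterable[tuple[tuple[str, ...], tuple[str, ...]]],
    corpus: Sequence[AnnotatedSentence],
    cfg: PatternLearningConfig,
) -> PatternSet:
    """Match every candidate back against the corpus and score it.

    Support is the number of matches whose slot aligns with a gold span;
    confidence is that count over all matches. Never-matching candidates
    are dropped (their confidence is undefined).
    """
    keys = candidates.keys() if isinstance(candidates, Counter) else candidates
    scored: PatternSet = []
    tokenized = [(ann.sentence.surfaces, ann.spans) for ann in corpus]
    for left, right in keys:
        total = correct = 0
        for surfaces, gold in tokenized:
            for m in _find_matches(surfaces, left, right, cfg.slot_max):
                total += 1
                if _is_correct(m, gold):
                    correct += 1
        if total:
            scored.append(Pattern(left, right, correct, correct / total))
    return scored


def filter_patterns(scored: PatternSet, cfg: PatternLearningConfig) -> PatternSet:
    """Keep patterns at or above both thresholds, deduplicated and sorted."""
    seen: dict[tuple, Pattern] = {}
    for p in scored:
        if p.support >= cfg.support_threshold and p.confidence >= cfg.confidence_threshold:
            seen[(p.left, p.right)] = p
    return sorted(
        seen.values(), key=lambda p: (-p.support, -p.confidence, p.render())
    )


def learn_patterns(
    corpus: str,
    cfg: PatternLearningConfig | None = None,
    pre_cfg: PreprocessingConfig | None = None,
) -> PatternSet:
    """End-to-end: normalize, extract, score and filter."""
    cfg = cfg or PatternLearningConfig()
    annotated = normalize_annotations(corpus, cfg=pre_cfg)
    candidates = extract_candidates(annotated, cfg)
    return filter_patterns(score_patterns(candidates, annotated, cfg), cfg)


@dataclass(frozen=True)
class PatternHit:
    """A detected slot span with the pattern(s) that produced it."""

    start: int
    end: int
    patterns: tuple[Pattern, ...]


def match_patterns(
    sentence: Sentence, patterns: PatternSet, slot_max: int = DEFAULT_SLOT_MAX
) -> list[PatternHit]:
    """Detect transgender slot spans in a plain sentence.

    Identical slots found by several patterns are pooled; overlapping,
    non-identical slots are resolved in favor of the pattern with the
    larger context (then higher support).
    """
    surfaces = sentence.surfaces
    raw: list[tuple[int, int, Pattern]] = []
    for p in patterns:
        for s, e, _la, _ra in _find_matches(surfaces, p.left, p.right, slot_max):
            raw.append((s, e, p))

    by_slot: dict[tuple[int, int], list[Pattern]] = {}
    for s, e, p in raw:
        by_slot.setdefault((s, e), []).append(p)

    ranked = sorted(
        by_slot.items(),
        key=lambda kv: (
            -max(p.context_size for p in kv[1]),
            -max(p.support for p in kv[1]),
            kv[0],
        ),
    )
    accepted: list[PatternHit] = []
    for (s, e), ps in ranked:
        if any(not (e <= a.start or s >= a.end) for a in accepted):
            continue
        accepted.append(
            PatternHit(s, e, tuple(sorted(ps, key=lambda p: p.render())))
        )
    return sorted(accepted, key=lambda h: (h.start, h.end))
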