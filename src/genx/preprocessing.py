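"""Sentence splitting and tokenization for criteria-style clinical text.

Criteria text is messy: bulleted lists without full stops, headers ending
in colons, abbreviations with internal periods. Splitting is rule based —
a boundary after sentence-final punctuation (with abbreviation and decimal
protection), before bullet markers, and at newlines — so that every input
character lands in exactly one sentence. Tokenization lowercases, keeps
punctuation marks as separate tokens (learned patterns include them) and
protects slash-joined abbreviations such as ``m/f`` as single tokens.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml


class Section(enum.Enum):
    DESCRIPTION = "description"
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"
    OTHER = "other"


@dataclass(frozen=True)
class Token:
    """A lowercased surface form and its character offset in the sentence."""

    surface: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.surface)


@dataclass
class Sentence:
    """One sentence of a trial section, with token-level structure."""

    trial_id: str
    section: Section
    index: int
    text: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class PreprocessingConfig:
    abbreviations: frozenset[str]
    protected_tokens: tuple[str, ...]
    bullet_markers: tuple[str, ...]

    @classmethod
    def from_mapping(cls, data: dict) -> "PreprocessingConfig":
        return cls(
            abbreviations=frozenset(a.lower() for a in data.get("abbreviations", [])),
            protected_tokens=tuple(
                sorted((t.lower() for t in data.get("protected_tokens", [])), key=len, reverse=True)
            ),
            bullet_markers=tuple(data.get("bullet_markers", [])),
        )

    @classmethod
    def load(cls, path: str | None = None) -> "PreprocessingConfig":
        if path is None:
            text = resources.files("genx.data").joinpath("preprocessing.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(yaml.safe_load(text) or {})


_DEFAULT_CONFIG: PreprocessingConfig | None = None


def default_config() -> PreprocessingConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = PreprocessingConfig.load()
    return _DEFAULT_CONFIG


_TERMINAL = ".!?;"
# word (possibly with internal periods, as in "e.g.") ending just before a "."
_ABBREV_BEFORE = re.compile(r"(\S+)$")


def _is_protected_stop(text: str, i: int, cfg: PreprocessingConfig) -> bool:
    """True when the '.' at position i must not close a sentence."""
    if text[i] != ".":
        return False
    if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return True  # decimal number
    if re.search(r"(?:^|\n)\s*\d{1,2}$", text[:i]):
        return True  # numbered list marker, handled as a bullet
    m = _ABBREV_BEFORE.search(text[:i])
    if m:
        word = m.group(1).lstrip("([{'\"") + "."
        if word.lower() in cfg.abbreviations:
            return True
    return False


def split_sentences(
    text: str, cfg: PreprocessingConfig | None = None
) -> list[tuple[str, int]]:
    """Split a section string into (sentence, start-offset) pairs.

    The returned slices are contiguous and cover the whole input; callers
    may strip whitespace when building :class:`Sentence` objects.
    """
    cfg = cfg or default_config()
    if not text:
        return []
    boundaries: set[int] = set()

    for m in re.finditer(rf"[{re.escape(_TERMINAL)}]", text):
        i = m.start()
        if _is_protected_stop(text, i, cfg):
            continue
        j = i + 1
        # trailing close-quotes/brackets stay with the sentence
        while j < len(text) and text[j] in ")]'\"":
            j += 1
        if j >= len(text) or text[j].isspace():
            boundaries.add(j)

    for m in re.finditer(r"\n", text):
        boundaries.add(m.end())

    bullet_re = re.compile("|".join(f"(?:{p})" for p in cfg.bullet_markers))
    for m in bullet_re.finditer(text):
        i = m.start()
        if text[i].isdigit():
            # numbered items only open sentences at line starts
            if i == 0 or text[i - 1] == "\n":
                boundaries.add(i)
        elif i == 0 or text[i - 1].isspace():
            boundaries.add(i)

    # headers ending with ':' open a new sentence as well
    for m in re.finditer(r":\s", text):
        boundaries.add(m.start() + 1)

    cuts = sorted(b for b in boundaries if 0 < b < len(text))
    pieces: list[tuple[str, int]] = []
    prev = 0
    for cut in cuts:
        pieces.append((text[prev:cut], prev))
        prev = cut
    pieces.append((text[prev:], prev))
    return [(p, off) for p, off in pieces if p.strip()]


def _token_pattern(cfg: PreprocessingConfig) -> re.Pattern:
    protected = "|".join(re.escape(t) for t in cfg.protected_tokens)
    parts = []
    if protected:
        parts.append(f"(?:{protected})(?![\\w/&])")
    parts.append(r"\w+(?:'\w+)?")
    parts.append(r"[^\w\s]")
    return re.compile("|".join(parts), re.IGNORECASE)


def tokenize(text: str, cfg: PreprocessingConfig | None = None) -> list[Token]:
    """Lowercased word/punctuation tokens with character offsets."""
    cfg = cfg or default_config()
    pattern = _token_pattern(cfg)
    return [Token(m.group(0).lower(), m.start()) for m in pattern.finditer(text)]


def sentences_from_section(
    trial_id: str,
    section: Section,
    text: str,
    cfg: PreprocessingConfig | None = None,
) -> list[Sentence]:
    """Split and tokenize one trial section into :class:`Sentence` objects."""
    cfg = cfg or default_config()
    out: list[Sentence] = []
    for idx, (raw, _off) in enumerate(split_sentences(text, cfg)):
        stripped = raw.strip()
        out.append(
            Sentence(
                trial_id=trial_id,
                section=section,
                index=idx,
                text=stripped,
                tokens=tokenize(stripped, cfg),
            )
        )
    return out


def ngram_at(surfaces: list[str], i: int, n: int) -> tuple[str, ...]:
    """The n-gram of token surfaces starting at position i."""
    return tuple(surfaces[i : i + n])


def find_token_runs(surfaces: Iterable[str], target: tuple[str, ...]) -> list[int]:
    """Start positions where ``target`` occurs as a contiguous token run."""
    surfaces = list(surfaces)
    n = len(target)
    if n == 0:
        return []
    return [i for i in range(len(surfaces) - n + 1) if tuple(surfaces[i : i + n]) == target]
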