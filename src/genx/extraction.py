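"""Gender mention detection, verification and per-trial extraction.

Per sentence the extractor runs, in order: learned pattern matching,
heuristic-rule composition over lexicon hits, context verification
(partner and negation rules) and section logic (a requirement asserted in
the exclusion criteria means that population is *not* recruited). The
lexicon, composition gaps, verification windows and section header
patterns are all data, shipped in ``genx/data/rules.yaml``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .gender_model import CompositeLabel
from .pattern_learning import PatternHit, PatternSet, match_patterns
from .preprocessing import (
    PreprocessingConfig,
    Section,
    Sentence,
    default_config,
    sentences_from_section,
    tokenize,
)

SEX_TYPES = ("Male", "Female")
QUALIFIER_TYPES = ("Transgender", "Biological")


class LexiconError(ValueError):
    pass


class MentionLexicon:
    """Mention-type name -> tokenized feature list, with validation."""

    def __init__(
        self, features: dict[str, list[str]], pre_cfg: PreprocessingConfig | None = None
    ):
        pre_cfg = pre_cfg or default_config()
        self.features: dict[str, list[tuple[str, ...]]] = {}
        for mtype, feats in features.items():
            if not feats:
                raise LexiconError(f"feature list for {mtype!r} is empty")
            toks = []
            for f in feats:
                if f != f.lower():
                    raise LexiconError(f"feature {f!r} must be lowercase")
                toks.append(tuple(t.surface for t in tokenize(f, pre_cfg)))
            self.features[mtype] = toks
        male = set(self.features.get("Male", ()))
        female = set(self.features.get("Female", ()))
        if male & female:
            raise LexiconError(f"features in both sex lists: {male & female}")
        # (n-gram, type) pairs ordered longest-first for greedy matching
        self._entries = sorted(
            ((toks, mtype) for mtype, feats in self.features.items() for toks in feats),
            key=lambda e: -len(e[0]),
        )
        self._max_len = max((len(e[0]) for e in self._entries), default=0)

    def entries(self):
        return self._entries


@dataclass(frozen=True)
class LexiconHit:
    """A token-level lexicon match."""

    mention_type: str
    start: int
    end: int
    surface: str


class Polarity(enum.Enum):
    ASSERTED = "asserted"
    NEGATED = "negated"
    IRRELEVANT = "irrelevant"


class Provenance(enum.Enum):
    RULE = "rule"
    PATTERN = "pattern"
    BOTH = "both"


@dataclass
class GenderMention:
    """A detected gender mention span within one sentence."""

    trial_id: str
    section: Section
    sentence_index: int
    start: int
    end: int
    surface: str
    composite: CompositeLabel
    polarity: Polarity = Polarity.ASSERTED
    provenance: Provenance = Provenance.RULE
    patterns: tuple = ()
    negation_trigger: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "nct_id": self.trial_id,
            "section": self.section.value,
            "sentence": self.sentence_index,
            "span": [self.start, self.end],
            "surface": self.surface,
            "composite": self.composite.name,
            "polarity": self.polarity.value,
            "provenance": self.provenance.value,
        }


@dataclass
class RulesConfig:
    lexicon: MentionLexicon
    qualifier_gap: int = 2
    partner_gap: int = 2
    negation_window: int = 4
    slot_max: int = 10
    birth_cues: tuple[tuple[str, ...], ...] = (("at", "birth"), ("assigned",))
    inclusion_header: str = r"(?i)inclusion\s+criteria\s*:?"
    exclusion_header: str = r"(?i)exclusion\s+criteria\s*:?"

    @classmethod
    def from_mapping(
        cls, data: dict, pre_cfg: PreprocessingConfig | None = None
    ) -> "RulesConfig":
        pre_cfg = pre_cfg or default_config()
        lex = MentionLexicon(data["lexicon"], pre_cfg)
        comp = data.get("composition", {})
        ver = data.get("verification", {})
        pat = data.get("patterns", {})
        sec = data.get("sections", {})
        cues = tuple(
            tuple(t.surface for t in tokenize(c, pre_cfg))
            for c in pat.get("birth_cues", ["at birth", "assigned"])
        )
        return cls(
            lexicon=lex,
            qualifier_gap=comp.get("qualifier_gap", 2),
            partner_gap=ver.get("partner_gap", 2),
            negation_window=ver.get("negation_window", 4),
            slot_max=pat.get("slot_max", 10),
            birth_cues=cues,
            inclusion_header=sec.get("inclusion_header", cls.inclusion_header),
            exclusion_header=sec.get("exclusion_header", cls.exclusion_header),
        )

    @classmethod
    def load(cls, path: str | None = None, pre_cfg: PreprocessingConfig | None = None):
        if path is None:
            text = resources.files("genx.data").joinpath("rules.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls.from_mapping(yaml.safe_load(text), pre_cfg)


_DEFAULT_RULES: RulesConfig | None = None


def default_rules() -> RulesConfig:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = RulesConfig.load()
    return _DEFAULT_RULES


def match_lexicon(sentence: Sentence, lex: MentionLexicon) -> list[LexiconHit]:
    """Longest-match-first, non-overlapping token-level lexicon hits."""
    surfaces = sentence.surfaces
    hits: list[LexiconHit] = []
    i = 0
    while i < len(surfaces):
        matched = False
        for toks, mtype in lex.entries():
            n = len(toks)
            if tuple(surfaces[i : i + n]) == toks:
                hits.append(LexiconHit(mtype, i, i + n, " ".join(toks)))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return hits


def _gap(a_end: int, b_start: int) -> int:
    return b_start - a_end


def compose_mentions(
    hits: list[LexiconHit], sentence: Sentence, rules: RulesConfig | None = None
) -> list[GenderMention]:
    """Apply adjacency composition rules over typed lexicon hits.

    Qualifier+sex pairs compose first ([Transgender][Female] or
    [Female][Transgender] within a small gap), then bare hits map to their
    default composites. Consumed hits are not reused.
    """
    rules = rules or default_rules()
    consumed: set[int] = set()
    mentions: list[GenderMention] = []

    def emit(start: int, end: int, composite: CompositeLabel) -> None:
        toks = sentence.tokens[start:end]
        mentions.append(
            GenderMention(
                trial_id=sentence.trial_id,
                section=sentence.section,
                sentence_index=sentence.index,
                start=start,
                end=end,
                surface=sentence.text[toks[0].start : toks[-1].end] if toks else "",
                composite=composite,
            )
        )

    # candidate qualifier+sex pairs, closest first (ties: sex word after
    # its qualifier wins, then left-to-right); greedy consumption
    pairs: list[tuple[int, int, int, int, int]] = []
    for i, hit in enumerate(hits):
        if hit.mention_type not in QUALIFIER_TYPES:
            continue
        for j, other in enumerate(hits):
            if other.mention_type not in SEX_TYPES:
                continue
            if other.start >= hit.end:
                d, direction = _gap(hit.end, other.start), 0
            elif hit.start >= other.end:
                d, direction = _gap(other.end, hit.start), 1
            else:
                continue
            if d <= rules.qualifier_gap:
                pairs.append((d, direction, hit.start, i, j))
    for _d, _dir, _pos, i, j in sorted(pairs):
        if i in consumed or j in consumed:
            continue
        consumed.update({i, j})
        emit(
            min(hits[i].start, hits[j].start),
            max(hits[i].end, hits[j].end),
            CompositeLabel[f"{hits[i].mention_type.upper()}_{hits[j].mention_type.upper()}"],
        )

    bare = {
        "Transgender": CompositeLabel.TRANSGENDER_ALL,
        "Biological": CompositeLabel.BIOLOGICAL_ALL,
        "Male": CompositeLabel.BIOLOGICAL_MALE,
        "Male_Abbreviation": CompositeLabel.BIOLOGICAL_MALE,
        "Female": CompositeLabel.BIOLOGICAL_FEMALE,
        "Two_Gender": CompositeLabel.BIOLOGICAL_ALL,
    }
    for i, hit in enumerate(hits):
        if i in consumed or hit.mention_type not in bare:
            continue
        emit(hit.start, hit.end, bare[hit.mention_type])

    return sorted(mentions, key=lambda m: (m.start, m.end))


def verify_mentions(
    mentions: list[GenderMention],
    hits: list[LexiconHit],
    sentence: Sentence,
    rules: RulesConfig | None = None,
) -> list[GenderMention]:
    """Partner rule first, then negation rule.

    A mention followed within ``partner_gap`` tokens by a [Partner] feature
    does not describe the recruited population and becomes IRRELEVANT.
    Each [Negation_Word] trigger then negates the nearest remaining mention
    within ``negation_window`` tokens, preferring a following mention over
    a preceding one; triggers do not stack or toggle.
    """
    rules = rules or default_rules()
    partner_hits = [h for h in hits if h.mention_type == "Partner"]
    neg_hits = [h for h in hits if h.mention_type == "Negation_Word"]

    for m in mentions:
        for p in partner_hits:
            d = _gap(m.end, p.start)
            if 0 <= d <= rules.partner_gap and not any(
                o is not m and o.start >= m.end and o.end <= p.start for o in mentions
            ):
                m.polarity = Polarity.IRRELEVANT
                break

    for t in neg_hits:
        best: tuple[int, int, GenderMention] | None = None
        for m in mentions:
            if m.polarity is Polarity.IRRELEVANT:
                continue
            if m.start >= t.end:
                key = (0, _gap(t.end, m.start))
            elif t.start >= m.end:
                key = (1, _gap(m.end, t.start))
            else:
                continue
            if key[1] <= rules.negation_window and (best is None or key < best[:2]):
                best = (*key, m)
        if best is not None:
            m = best[2]
            m.polarity = Polarity.NEGATED
            m.negation_trigger = (t.start, t.end)

    return mentions


def apply_section_logic(mentions: list[GenderMention]) -> list[GenderMention]:
    """In exclusion criteria an asserted requirement excludes, so polarity flips
    (and a negated one — "will not be excluded" — flips back to asserted)."""
    for m in mentions:
        if m.section is Section.EXCLUSION:
            if m.polarity is Polarity.ASSERTED:
                m.polarity = Polarity.NEGATED
            elif m.polarity is Polarity.NEGATED:
                m.polarity = Polarity.ASSERTED
    return mentions


_IDENTITY = {
    CompositeLabel.BIOLOGICAL_MALE: CompositeLabel.TRANSGENDER_MALE,
    CompositeLabel.BIOLOGICAL_FEMALE: CompositeLabel.TRANSGENDER_FEMALE,
}


def _has_birth_cue(hit: PatternHit, rules: RulesConfig) -> bool:
    for p in hit.patterns:
        for side in (p.left, p.right):
            for cue in rules.birth_cues:
                n = len(cue)
                if any(side[i : i + n] == cue for i in range(len(side) - n + 1)):
                    return True
    return False


def _type_slot(
    hit: PatternHit, sentence: Sentence, rules: RulesConfig
) -> CompositeLabel:
    """Type a pattern-detected slot by running the lexicon inside it.

    A transgender-axis composite inside the slot wins outright. A bare
    sexed word names a gender *identity* when the pattern context carries
    assigned-sex-at-birth cues, so it maps to the transgender type of that
    sex; without such cues the slot is typed TRANSGENDER_ALL, as is a slot
    with no sexed feature at all.
    """
    slot_tokens = sentence.tokens[hit.start : hit.end]
    sub = Sentence(
        trial_id=sentence.trial_id,
        section=sentence.section,
        index=sentence.index,
        text=sentence.text,
        tokens=slot_tokens,
    )
    inner = compose_mentions(match_lexicon(sub, rules.lexicon), sub, rules)
    for m in inner:
        if m.composite.name.startswith("TRANSGENDER"):
            return m.composite
    if _has_birth_cue(hit, rules):
        for m in inner:
            if m.composite in _IDENTITY:
                return _IDENTITY[m.composite]
    return CompositeLabel.TRANSGENDER_ALL


def _merge_pattern_and_rule(
    pattern_mentions: list[GenderMention], rule_mentions: list[GenderMention]
) -> list[GenderMention]:
    """Dedup pattern and rule hits; pattern wins span conflicts."""
    merged: list[GenderMention] = list(pattern_mentions)
    for rm in rule_mentions:
        clash = False
        for pm in merged:
            if rm.end <= pm.start or rm.start >= pm.end:
                continue
            clash = True
            if (rm.start, rm.end, rm.composite) == (pm.start, pm.end, pm.composite):
                pm.provenance = Provenance.BOTH
            break
        if not clash:
            merged.append(rm)
    return sorted(merged, key=lambda m: (m.start, m.end))


def extract_sentence(
    sentence: Sentence,
    patterns: PatternSet | None = None,
    rules: RulesConfig | None = None,
) -> list[GenderMention]:
    """Run the full per-sentence stack: patterns, rules, verification."""
    rules = rules or default_rules()
    hits = match_lexicon(sentence, rules.lexicon)

    pattern_mentions: list[GenderMention] = []
    if patterns:
        for ph in match_patterns(sentence, patterns, rules.slot_max):
            toks = sentence.tokens[ph.start : ph.end]
            pattern_mentions.append(
                GenderMention(
                    trial_id=sentence.trial_id,
                    section=sentence.section,
                    sentence_index=sentence.index,
                    start=ph.start,
                    end=ph.end,
                    surface=sentence.text[toks[0].start : toks[-1].end] if toks else "",
                    composite=_type_slot(ph, sentence, rules),
                    provenance=Provenance.PATTERN,
                    patterns=ph.patterns,
                )
            )

    rule_mentions = compose_mentions(hits, sentence, rules)
    mentions = _merge_pattern_and_rule(pattern_mentions, rule_mentions)
    return verify_mentions(mentions, hits, sentence, rules)


def segment_criteria(
    text: str, rules: RulesConfig | None = None
) -> dict[Section, str]:
    """Partition a combined criteria block on inclusion/exclusion headers.

    Text before any header is OTHER.
    """
    rules = rules or default_rules()
    markers = []
    for section, pat in (
        (Section.INCLUSION, rules.inclusion_header),
        (Section.EXCLUSION, rules.exclusion_header),
    ):
        for m in re.finditer(pat, text):
            markers.append((m.start(), m.end(), section))
    markers.sort()
    out = {Section.OTHER: "", Section.INCLUSION: "", Section.EXCLUSION: ""}
    if not markers:
        out[Section.OTHER] = text
        return out
    out[Section.OTHER] = text[: markers[0][0]]
    for k, (_s, e, section) in enumerate(markers):
        nxt = markers[k + 1][0] if k + 1 < len(markers) else len(text)
        out[section] = (out[section] + "\n" + text[e:nxt]).strip()
    return out


def extract_trial(
    trial,
    patterns: PatternSet | None = None,
    rules: RulesConfig | None = None,
    pre_cfg: PreprocessingConfig | None = None,
) -> list[GenderMention]:
    """Extract verified, section-adjusted gender mentions from one trial.

    Scans the study description and the split eligibility criteria; an
    empty trial yields an empty list.
    """
    rules = rules or default_rules()
    pre_cfg = pre_cfg or default_config()
    mentions: list[GenderMention] = []
    section_order = {
        Section.DESCRIPTION: 0,
        Section.OTHER: 1,
        Section.INCLUSION: 2,
        Section.EXCLUSION: 3,
    }
    for section, text in (
        (Section.DESCRIPTION, trial.description),
        (Section.INCLUSION, trial.inclusion),
        (Section.EXCLUSION, trial.exclusion),
    ):
        if not text:
            continue
        for sentence in sentences_from_section(trial.nct_id, section, text, pre_cfg):
            mentions.extend(extract_sentence(sentence, patterns, rules))
    apply_section_logic(mentions)
    return sorted(
        mentions, key=lambda m: (section_order[m.section], m.sentence_index, m.start)
    )
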