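"""Trial record readers/writers, annotation round-trip, fixture generation.

The canonical internal format is a trial JSONL schema (one object per
line: ``nct_id``, ``description``, ``inclusion``, ``exclusion``,
``registered_sex``, optional ``gold_label``). A reader for the legacy
public registry XML dialect and for a directory of plain-text files is
provided. The fixture generator builds seeded synthetic corpora — trials
with known gold labels assembled from feature-bearing sentence templates,
plus an inline-annotated corpus for the pattern learner — so every stage
is testable without any external data.
"""

from __future__ import annotations

import enum
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gender_model as gm
from .extraction import RulesConfig, default_rules, segment_criteria
from .pattern_learning import TG_END, TG_START, AnnotatedSentence, normalize_annotations
from .preprocessing import Section

logger = logging.getLogger(__name__)


@dataclass
class TrialRecord:
    """One clinical trial: sectioned free text plus registered sex."""

    nct_id: str
    description: str = ""
    inclusion: str = ""
    exclusion: str = ""
    registered_sex: str = "Unknown"
    gold_label: str | None = None

    def to_dict(self) -> dict:
        d = {
            "nct_id": self.nct_id,
            "description": self.description,
            "inclusion": self.inclusion,
            "exclusion": self.exclusion,
            "registered_sex": self.registered_sex,
        }
        if self.gold_label is not None:
            d["gold_label"] = self.gold_label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(
            nct_id=d["nct_id"],
            description=d.get("description", ""),
            inclusion=d.get("inclusion", ""),
            exclusion=d.get("exclusion", ""),
            registered_sex=d.get("registered_sex", "Unknown"),
            gold_label=d.get("gold_label"),
        )


class TrialFormat(enum.Enum):
    JSONL = "jsonl"
    REGISTRY_XML = "registry_xml"
    PLAIN_DIR = "plain_dir"


class CorpusIOError(ValueError):
    pass


def _xml_text(root, path: str) -> str:
    node = root.find(path)
    return (node.text or "").strip() if node is not None else ""


def _trial_from_xml(path: Path, rules: RulesConfig) -> TrialRecord | None:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        logger.warning("skipping malformed XML %s: %s", path, exc)
        return None
    nct_id = _xml_text(root, "./id_info/nct_id")
    if not nct_id:
        logger.warning("skipping %s: no nct_id", path)
        return None
    description = "\n".join(
        t
        for t in (
            _xml_text(root, "./brief_summary/textblock"),
            _xml_text(root, "./detailed_description/textblock"),
        )
        if t
    )
    criteria = _xml_text(root, "./eligibility/criteria/textblock")
    parts = segment_criteria(criteria, rules)
    sex = _xml_text(root, "./eligibility/gender") or "Unknown"
    if sex.lower() in ("both", "all"):
        sex = "All"
    return TrialRecord(
        nct_id=nct_id,
        description=description,
        inclusion=(parts[Section.OTHER] + "\n" + parts[Section.INCLUSION]).strip(),
        exclusion=parts[Section.EXCLUSION],
        registered_sex=sex.title() if sex.lower() in ("male", "female") else sex,
    )


def read_trials(
    path: str | Path,
    fmt: TrialFormat = TrialFormat.JSONL,
    rules: RulesConfig | None = None,
) -> list[TrialRecord]:
    """Load trial records; malformed records are skipped with a warning."""
    path = Path(path)
    rules = rules or default_rules()
    records: list[TrialRecord] = []
    if fmt is TrialFormat.JSONL:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    records.append(TrialRecord.from_dict(json.loads(line)))
                except (json.JSONDecodeError, KeyError) as exc:
                    logger.warning("skipping line %d of %s: %s", lineno, path, exc)
    elif fmt is TrialFormat.REGISTRY_XML:
        files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
        for f in files:
            rec = _trial_from_xml(f, rules)
            if rec is not None:
                records.append(rec)
    elif fmt is TrialFormat.PLAIN_DIR:
        for f in sorted(path.glob("*.txt")):
            text = f.read_text()
            parts = segment_criteria(text, rules)
            records.append(
                TrialRecord(
                    nct_id=f.stem,
                    description=parts[Section.OTHER],
                    inclusion=parts[Section.INCLUSION],
                    exclusion=parts[Section.EXCLUSION],
                )
            )
    if not records:
        raise CorpusIOError(f"no parseable trial records in {path}")
    return records


def write_trials(records: list[TrialRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def write_annotations(annotated: list[AnnotatedSentence], path: str | Path) -> None:
    """Serialize annotated sentences, one per line, with inline TG tags."""
    lines = []
    for ann in annotated:
        text = ann.sentence.text
        inserts: list[tuple[int, str]] = []
        for s, e in ann.spans:
            inserts.append((ann.sentence.tokens[s].start, TG_START))
            inserts.append((ann.sentence.tokens[e - 1].end, TG_END))
        for pos, tag in sorted(inserts, key=lambda x: -x[0]):
            text = text[:pos] + tag + text[pos:]
        lines.append(text)
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[AnnotatedSentence]:
    return normalize_annotations(Path(path).read_text())


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

#: sentence templates realizing exactly one composite mention each
MENTION_TEMPLATES: dict[gm.CompositeLabel, tuple[str, ...]] = {
    gm.CompositeLabel.TRANSGENDER_MALE: (
        "Self identify as a transgender man.",
        "The study recruits transgender men.",
        "Eligible participants are transsexual male adults.",
    ),
    gm.CompositeLabel.TRANSGENDER_FEMALE: (
        "Self identify as a transgender woman.",
        "The study recruits transgender women.",
        "Eligible participants are transsexual female adults.",
    ),
    gm.CompositeLabel.TRANSGENDER_ALL: (
        "The study is open to transgender adults.",
        "Transgender people of any identity are welcome.",
        "A history of transsexualism is acceptable for enrollment.",
    ),
    gm.CompositeLabel.BIOLOGICAL_MALE: (
        "Biologically male participants are eligible.",
        "The study recruits adult males.",
        "Cisgender men are eligible.",
    ),
    gm.CompositeLabel.BIOLOGICAL_FEMALE: (
        "Biologically female participants are eligible.",
        "The study recruits adult females.",
        "Cisgender women are eligible.",
    ),
    gm.CompositeLabel.BIOLOGICAL_ALL: (
        "Both genders are eligible.",
        "The study enrolls participants of all genders.",
        "Open to m/f adults.",
    ),
}

#: feature-free filler; several carry commas so vacuous punctuation-only
#: pattern candidates lose confidence during learning
FILLER_SENTENCES = (
    "Age 18 years or older.",
    "Able to provide informed consent.",
    "In addition, participants must complete the baseline survey.",
    "Willing to attend follow-up visits, as scheduled.",
    "A diagnosis of hypertension, diabetes, or asthma is acceptable.",
    "Participants must live within the study catchment area.",
    "Laboratory values, vital signs, and medical history are reviewed.",
    "This is a randomized, double-blind, placebo-controlled study.",
)

NEGATION_TEMPLATES = (
    "Participants must not be transsexual.",
    "Participants must not be male.",
    "Participants must not be female.",
)

PARTNER_TEMPLATES = (
    "Participants with male sexual partners are eligible.",
    "Having a female sexual partner is acceptable.",
    "Participants whose husband is enrolled elsewhere remain eligible.",
)

#: the assigned-at-birth phrasing only the pattern learner can resolve
BIRTH_SENTENCE = (
    "Participants who were female at birth, who now identify as male, "
    "will not be excluded."
)

_BIRTH_PREFIXES = (
    "Participants who were",
    "Participants who are",
    "Candidates who were",
    "Those who are",
    "Volunteers who were",
    "Individuals who are",
)

_BIRTH_SLOTS = (
    "who now identify as male",
    "who currently identify as male",
    "who now identify as men",
)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic corpus generator."""

    n_positive: int = 50
    n_negative: int = 200
    label_mix: dict[str, float] | None = None  # default: uniform over 13 labels
    mentions_per_trial: tuple[int, int] = (6, 8)
    noise_mention_rate: float = 0.0
    negation_rate: float = 0.0
    partner_rate: float = 0.0
    seed: int = 0
    # mu-tuning support: plant count profiles that make exactly this mu optimal
    planted_mu: int | None = None
    hard_noise_rate: float = 0.15
    genuine_secondary_rate: float = 0.5
    birth_sentence_rate: float = 0.5
    n_annotated: int = 8

    def __post_init__(self) -> None:
        for name in ("noise_mention_rate", "negation_rate", "partner_rate",
                     "hard_noise_rate", "genuine_secondary_rate", "birth_sentence_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class FixtureSet:
    trials: list[TrialRecord]
    annotated_corpus: str
    positives: list[TrialRecord] = field(default_factory=list)
    negatives: list[TrialRecord] = field(default_factory=list)


_LABEL_METAS: dict[str, tuple[gm.MetaGender, ...]] = {}
for _tg in gm.Component:
    for _bio in gm.Component:
        if _tg is gm.Component.NONE and _bio is gm.Component.NONE:
            continue
        _metas: list[gm.MetaGender] = []
        for _axis, _comp in (("TRANSGENDER", _tg), ("BIOLOGICAL", _bio)):
            if _comp in (gm.Component.MALE, gm.Component.ALL):
                _metas.append(gm.MetaGender[f"{_axis}_MALE"])
            if _comp in (gm.Component.FEMALE, gm.Component.ALL):
                _metas.append(gm.MetaGender[f"{_axis}_FEMALE"])
        _label = gm.GenderType(_tg, _bio).label
        if _label not in _LABEL_METAS:
            _LABEL_METAS[_label] = tuple(_metas)


def _allocate_labels(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of labels to trials, then a shuffle.

    Deterministic marginals guarantee every label with positive mass is
    present once n is large enough.
    """
    mix = spec.label_mix or {lab: 1.0 for lab in gm.ALL_LABELS}
    labels = sorted(mix)
    weights = np.array([mix[lab] for lab in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("label_mix weights must sum to a positive value")
    weights = weights / weights.sum()
    ideal = weights * spec.n_positive
    counts = np.floor(ideal).astype(int)
    remainder = spec.n_positive - counts.sum()
    order = np.argsort(-(ideal - counts))
    for j in range(remainder):
        counts[order[j % len(labels)]] += 1
    out = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def _meta_sentences(meta: gm.MetaGender, n: int, rng: np.random.Generator) -> list[str]:
    pool = MENTION_TEMPLATES[gm.CompositeLabel[meta.name]]
    return [pool[int(rng.integers(len(pool)))] for _ in range(n)]


def _plan_counts(
    metas: tuple[gm.MetaGender, ...], spec: FixtureSpec, rng: np.random.Generator
) -> dict[gm.MetaGender, int]:
    """Per-meta mention counts for one trial, including planted noise.

    Count profiles are arranged so the default mu prunes injected noise;
    with ``planted_mu`` set, genuine-secondary and noise profiles make
    exactly that mu the F1-optimal grid point.
    """
    lo, hi = spec.mentions_per_trial
    k = int(rng.integers(lo, hi + 1))
    counts = {m: k for m in metas}
    others = [m for m in gm.META_ORDER if m not in metas]

    mu = spec.planted_mu
    if mu is not None and len(metas) > 1 and rng.random() < spec.genuine_secondary_rate:
        # one genuine low-frequency type: kept only when grid mu >= planted mu
        secondary = metas[int(rng.integers(len(metas)))]
        counts = {m: mu for m in metas}
        counts[secondary] = 1
        return counts

    if others and spec.noise_mention_rate and rng.random() < spec.noise_mention_rate:
        noise = others[int(rng.integers(len(others)))]
        if mu is not None:
            if rng.random() < spec.hard_noise_rate:
                counts = {m: mu + 1 for m in metas}
                counts[noise] = 2  # survives pruning for mu >= 3: a real error
            else:
                counts = {m: mu + 1 for m in metas}
                counts[noise] = 1  # pruned iff mu <= planted mu
        else:
            counts[noise] = 1
    return counts


def _assemble_trial(
    nct_id: str,
    label: str,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> TrialRecord:
    metas = _LABEL_METAS[label]
    if label == "Biological":
        choice = int(rng.integers(3))
        metas = (
            (gm.MetaGender.BIOLOGICAL_MALE,),
            (gm.MetaGender.BIOLOGICAL_FEMALE,),
            (gm.MetaGender.BIOLOGICAL_MALE, gm.MetaGender.BIOLOGICAL_FEMALE),
        )[choice]
    counts = _plan_counts(metas, spec, rng)

    sentences: list[str] = []
    exclusion_sentences: list[str] = []
    use_birth = (
        counts.get(gm.MetaGender.TRANSGENDER_MALE, 0) >= 1
        and rng.random() < spec.birth_sentence_rate
    )
    for meta, n in counts.items():
        if use_birth and meta is gm.MetaGender.TRANSGENDER_MALE:
            exclusion_sentences.append(BIRTH_SENTENCE)
            n -= 1
        sentences.extend(_meta_sentences(meta, n, rng))

    if spec.negation_rate and rng.random() < spec.negation_rate:
        sentences.append(NEGATION_TEMPLATES[int(rng.integers(len(NEGATION_TEMPLATES)))])
    if spec.partner_rate and rng.random() < spec.partner_rate:
        sentences.append(PARTNER_TEMPLATES[int(rng.integers(len(PARTNER_TEMPLATES)))])
    sentences.extend(
        FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
        for _ in range(int(rng.integers(1, 3)))
    )
    rng.shuffle(sentences)

    half = len(sentences) // 2
    description = " ".join(sentences[:half])
    inclusion = " ".join(sentences[half:])
    exclusion = " ".join(exclusion_sentences)
    gold = gm.GenderType(*_label_components(label))
    return TrialRecord(
        nct_id=nct_id,
        description=description,
        inclusion=inclusion,
        exclusion=exclusion,
        registered_sex=gm.to_conventional(gold).value,
        gold_label=label,
    )


def _label_components(label: str) -> tuple[gm.Component, gm.Component]:
    for tg in gm.Component:
        for bio in gm.Component:
            if tg is gm.Component.NONE and bio is gm.Component.NONE:
                continue
            if gm.GenderType(tg, bio).label == label:
                return tg, bio
    raise ValueError(f"unknown label {label!r}")


def _negative_trial(nct_id: str, rng: np.random.Generator) -> TrialRecord:
    sentences = [
        FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
        for _ in range(int(rng.integers(2, 5)))
    ]
    sex = "All"
    if rng.random() < 0.5:
        # half the negatives state a plain biological requirement
        meta = (gm.MetaGender.BIOLOGICAL_MALE, gm.MetaGender.BIOLOGICAL_FEMALE)[
            int(rng.integers(2))
        ]
        sentences.extend(_meta_sentences(meta, int(rng.integers(1, 3)), rng))
        sex = "Male" if meta is gm.MetaGender.BIOLOGICAL_MALE else "Female"
    rng.shuffle(sentences)
    half = len(sentences) // 2
    return TrialRecord(
        nct_id=nct_id,
        description=" ".join(sentences[:half]),
        inclusion=" ".join(sentences[half:]),
        exclusion="",
        registered_sex=sex,
        gold_label="Biological",
    )


def _annotated_corpus(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """Birth-pattern sentences with inline tags, diluted with plain filler."""
    lines: list[str] = []
    for i in range(spec.n_annotated):
        prefix = _BIRTH_PREFIXES[i % len(_BIRTH_PREFIXES)]
        slot = _BIRTH_SLOTS[int(rng.integers(len(_BIRTH_SLOTS)))]
        lines.append(
            f"{prefix} female at birth, {TG_START}{slot}{TG_END}, "
            "will not be excluded."
        )
    # unannotated negatives: every filler template repeated enough times that
    # comma-pair matches sink vacuous punctuation-only candidates well below
    # the confidence threshold, independent of the seed
    repeats = max(1, -(-spec.n_annotated // 2))
    for filler in FILLER_SENTENCES:
        lines.extend([filler] * repeats)
    rng.shuffle(lines)
    return "\n".join(lines) + "\n"


def generate_fixtures(spec: FixtureSpec) -> FixtureSet:
    """Generate a seeded synthetic dataset with known gold labels."""
    rng = np.random.default_rng(spec.seed)
    labels = _allocate_labels(spec, rng)
    positives = [
        _assemble_trial(f"NCTP{i:07d}", lab, spec, rng)
        for i, lab in enumerate(labels)
    ]
    negatives = [
        _negative_trial(f"NCTN{i:07d}", rng) for i in range(spec.n_negative)
    ]
    corpus = _annotated_corpus(spec, rng)
    return FixtureSet(
        trials=positives + negatives,
        annotated_corpus=corpus,
        positives=positives,
        negatives=negatives,
    )
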