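"""Frequency-based inference of a trial's final gender requirement.

Asserted composite mentions are split into the four atomic meta gender
types and counted. Ranked counts are then pruned by a majority rule: at
rank i the predominance score ``Pred = MG_{i+1} / MG_i * mu`` is computed,
and the first rank where ``Pred < 1`` cuts everything below it off as
noise. The surviving meta types merge into one of the 13 final labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from . import gender_model as gm
from .extraction import GenderMention, Polarity


@dataclass(frozen=True)
class SummarizationConfig:
    mu: float = 5.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")


@dataclass
class MetaGenderCounts:
    """Frequency table over the four meta gender types."""

    frequency: dict[gm.MetaGender, int] = field(
        default_factory=lambda: {mg: 0 for mg in gm.META_ORDER}
    )

    @property
    def ranked(self) -> list[tuple[gm.MetaGender, int]]:
        """Nonzero types by count descending; ties in fixed meta order.

        The tie order is cosmetic: at a tie the Pred score equals mu >= 1,
        so tied types can never be split across a prune boundary.
        """
        nonzero = [(mg, c) for mg, c in self.frequency.items() if c > 0]
        order = {mg: i for i, mg in enumerate(gm.META_ORDER)}
        return sorted(nonzero, key=lambda mc: (-mc[1], order[mc[0]]))

    @property
    def total(self) -> int:
        return sum(self.frequency.values())


class NoEvidenceError(ValueError):
    pass


def meta_counts_from_composites(
    composites: Iterable[gm.CompositeGender | gm.CompositeLabel],
) -> MetaGenderCounts:
    """Split each composite into meta types and tally.

    ``*_ALL`` composites contribute one count to each of their members.
    """
    counts = MetaGenderCounts()
    for comp in composites:
        if gm.split_judgement(comp):
            for half in gm.split(comp):
                counts.frequency[gm.MetaGender[half.label.name]] += 1
        else:
            label = comp.label if isinstance(comp, gm.CompositeGender) else comp
            counts.frequency[gm.MetaGender[label.name]] += 1
    return counts


def to_meta_counts(mentions: Iterable[GenderMention]) -> MetaGenderCounts:
    """Meta counts over the ASSERTED mentions only."""
    return meta_counts_from_composites(
        m.composite for m in mentions if m.polarity is Polarity.ASSERTED
    )


def pred_score(
    counts: MetaGenderCounts | Mapping[gm.MetaGender, int],
    i: int,
    cfg: SummarizationConfig | None = None,
) -> float:
    """Predominance of rank ``i`` (1-based) over rank ``i+1``: MG_{i+1}/MG_i * mu."""
    cfg = cfg or SummarizationConfig()
    if not isinstance(counts, MetaGenderCounts):
        counts = MetaGenderCounts(dict(counts))
    ranked = counts.ranked
    if i < 1 or i > len(ranked):
        raise IndexError(f"rank {i} out of range")
    mg_i = ranked[i - 1][1]
    if mg_i == 0:
        raise NoEvidenceError("Pred undefined at a zero-count rank")
    mg_next = ranked[i][1] if i < len(ranked) else 0
    return mg_next / mg_i * cfg.mu


def prune_noise(
    counts: MetaGenderCounts, cfg: SummarizationConfig | None = None
) -> tuple[set[gm.MetaGender], set[gm.MetaGender]]:
    """Scan ranks top-down; the first rank with Pred < 1 cuts off the rest.

    Returns (kept, pruned) over the nonzero types; zero-count types belong
    to neither.
    """
    cfg = cfg or SummarizationConfig()
    ranked = counts.ranked
    if not ranked:
        raise NoEvidenceError("no nonzero meta gender counts")
    cut = len(ranked)
    for i in range(1, len(ranked)):
        if pred_score(counts, i, cfg) < 1:
            cut = i
            break
    return {mg for mg, _ in ranked[:cut]}, {mg for mg, _ in ranked[cut:]}


@dataclass
class GenderSummary:
    """The final summary for one trial."""

    trial_id: str
    label: gm.GenderType
    conventional: gm.Conventional
    kept: set[gm.MetaGender]
    pruned: set[gm.MetaGender]
    evidence_counts: MetaGenderCounts
    fallback: bool = False
    negated_evidence: MetaGenderCounts | None = None

    def to_dict(self) -> dict:
        return {
            "nct_id": self.trial_id,
            "label": self.label.label,
            "conventional": self.conventional.value,
            "kept": sorted(mg.name for mg in self.kept),
            "pruned": sorted(mg.name for mg in self.pruned),
            "counts": {mg.name: c for mg, c in self.evidence_counts.frequency.items()},
            "fallback": self.fallback,
        }


_SEX_TO_COMPONENT = {
    "Male": gm.Component.MALE,
    "Female": gm.Component.FEMALE,
    "All": gm.Component.ALL,
    None: gm.Component.ALL,
}


def summarize(
    mentions: Iterable[GenderMention],
    cfg: SummarizationConfig | None = None,
    trial_id: str | None = None,
    registered_sex: str | None = None,
    by_identity: bool = True,
) -> GenderSummary:
    """Count, prune and compose the final 13-type label for one trial.

    With zero asserted evidence the summary falls back to 'Biological'
    with the trial's registered sex (ALL when unknown), flagged
    ``fallback=True``. Negated evidence is never counted but is kept on
    the summary for audit.
    """
    cfg = cfg or SummarizationConfig()
    mentions = list(mentions)
    if trial_id is None:
        trial_id = mentions[0].trial_id if mentions else ""
    counts = to_meta_counts(mentions)
    negated = meta_counts_from_composites(
        m.composite for m in mentions if m.polarity is Polarity.NEGATED
    )
    if counts.total == 0:
        sex = registered_sex if registered_sex in ("Male", "Female", "All") else None
        label = gm.GenderType(gm.Component.NONE, _SEX_TO_COMPONENT[sex])
        return GenderSummary(
            trial_id=trial_id,
            label=label,
            conventional=gm.to_conventional(label, by_identity),
            kept=set(),
            pruned=set(),
            evidence_counts=counts,
            fallback=True,
            negated_evidence=negated,
        )
    kept, pruned = prune_noise(counts, cfg)
    label = gm.compose_label(kept)
    return GenderSummary(
        trial_id=trial_id,
        label=label,
        conventional=gm.to_conventional(label, by_identity),
        kept=kept,
        pruned=pruned,
        evidence_counts=counts,
        fallback=False,
        negated_evidence=negated,
    )
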