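"""End-to-end plumbing: trials -> mentions -> summaries -> labels."""

from __future__ import annotations

from typing import Sequence

from .extraction import GenderMention, RulesConfig, default_rules, extract_trial
from .pattern_learning import PatternSet
from .summarization import GenderSummary, SummarizationConfig, summarize


def extract_all(
    trials: Sequence,
    patterns: PatternSet | None = None,
    rules: RulesConfig | None = None,
) -> list[list[GenderMention]]:
    rules = rules or default_rules()
    return [extract_trial(t, patterns, rules) for t in trials]


def summarize_all(
    trials: Sequence,
    mentions: Sequence[list[GenderMention]],
    mu: float = 5.0,
    by_identity: bool = True,
) -> list[GenderSummary]:
    cfg = SummarizationConfig(mu=mu)
    return [
        summarize(
            ms,
            cfg,
            trial_id=t.nct_id,
            registered_sex=t.registered_sex,
            by_identity=by_identity,
        )
        for t, ms in zip(trials, mentions)
    ]


def predict_labels(
    trials: Sequence,
    patterns: PatternSet | None = None,
    rules: RulesConfig | None = None,
    mu: float = 5.0,
) -> list[str]:
    """Final 13-type label string per trial."""
    mentions = extract_all(trials, patterns, rules)
    return [s.label.label for s in summarize_all(trials, mentions, mu)]
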