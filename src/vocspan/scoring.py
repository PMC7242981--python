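"""Trial scoring: serial position, phoneme-level, and key-word accuracy.

Serial recall is scored positionally: slot *i* of the response is correct
only if it matches slot *i* of the target (proportional list scoring, which
retains information from partially correct trials). Word lists score each
of the three CVC phonemes separately, giving credit for partially correct
words. Sentence trials use order-free key-word scoring: each designated key
word may be matched at most once against the normalized response tokens.

Accuracy aggregates to a participant × condition summary as a pooled
proportion, Σ correct / Σ slots across trials of all list lengths (slot
weighted). A mean-of-trial-proportions alternative is available behind a
flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TrialScore",
    "ConditionSummary",
    "score_serial_positions",
    "score_word_phonemes",
    "score_keywords",
    "aggregate_condition_accuracy",
]


@dataclass(frozen=True)
class TrialScore:
    """Slots scored on one trial: ``proportion == n_correct / n_slots``."""

    n_slots: int
    n_correct: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_slots <= 0:
            raise ValueError("n_slots must be positive")
        if not 0 <= self.n_correct <= self.n_slots:
            raise ValueError("need 0 <= n_correct <= n_slots")

    @property
    def proportion(self) -> float:
        return self.n_correct / self.n_slots


@dataclass(frozen=True)
class ConditionSummary:
    """Pooled accuracy for one participant × condition × stimulus kind."""

    participant: str
    condition: str
    kind: str
    n_slots: int
    n_correct: int
    mean_proportion: float


def _item_key(item) -> object:
    # Words compare by phoneme triple; anything else by equality.
    phonemes = getattr(item, "phonemes", None)
    return phonemes if phonemes is not None else item


def score_serial_positions(target: Sequence, response: Sequence) -> TrialScore:
    """Position-wise serial scoring of a digit (or item) list.

    Slot *i* is correct iff the response has an item at *i* equal to the
    target's. Missing positions are incorrect; surplus response items are
    ignored.
    """
    if len(target) == 0:
        raise ValueError("target list must be non-empty")
    n_correct = sum(
        1 for pos in range(len(target))
        if pos < len(response) and _item_key(response[pos]) == _item_key(target[pos])
    )
    return TrialScore(n_slots=len(target), n_correct=n_correct)


def score_word_phonemes(target: Sequence, response: Sequence) -> TrialScore:
    """Phoneme-level position-wise scoring of a CVC word list.

    Each target word contributes three slots (initial consonant, vowel,
    final consonant); slot (i, j) is correct iff the response word at
    position i exists and its phoneme j matches. Response tokens without
    exactly three phonemes are scored against their aligned slots only and
    flagged.
    """
    if len(target) == 0:
        raise ValueError("target list must be non-empty")
    n_correct = 0
    flags: list[str] = []
    for pos, word in enumerate(target):
        target_phonemes = tuple(getattr(word, "phonemes", word))
        if len(target_phonemes) != 3:
            raise ValueError(f"target word at position {pos + 1} is not CVC")
        if pos >= len(response):
            continue
        response_phonemes = tuple(getattr(response[pos], "phonemes", response[pos]))
        if len(response_phonemes) != 3:
            flags.append(f"response word {pos + 1} has {len(response_phonemes)} phonemes")
        n_correct += sum(
            1 for j in range(min(len(response_phonemes), 3))
            if response_phonemes[j] == target_phonemes[j]
        )
    return TrialScore(n_slots=3 * len(target), n_correct=n_correct, flags=tuple(flags))


_PUNCT = re.compile(r"[^\w']+", flags=re.UNICODE)


def _normalize_tokens(text_or_tokens) -> list[str]:
    if isinstance(text_or_tokens, str):
        tokens = _PUNCT.split(text_or_tokens)
    else:
        tokens = list(text_or_tokens)
    return [token.casefold().strip("'") for token in tokens if token and token.strip("'")]


def score_keywords(keywords: Sequence[str], response) -> TrialScore:
    """Order-free key-word scoring of a sentence response.

    Tokens are case-folded and stripped of punctuation; each key word is
    matched one-to-one against response tokens (a duplicated key word needs
    a duplicated response token). Exact-form match only — no credit for
    morphological variants.
    """
    if len(keywords) == 0:
        raise ValueError("keyword list must be non-empty")
    normalized_keywords = _normalize_tokens(list(keywords))
    available: dict[str, int] = {}
    for token in _normalize_tokens(response):
        available[token] = available.get(token, 0) + 1
    n_correct = 0
    for keyword in normalized_keywords:
        if available.get(keyword, 0) > 0:
            available[keyword] -= 1
            n_correct += 1
    return TrialScore(n_slots=len(normalized_keywords), n_correct=n_correct)


def aggregate_condition_accuracy(
    trials: Iterable[TrialScore],
    participant: str = "",
    condition: str = "",
    kind: str = "",
    weighting: str = "pooled",
) -> ConditionSummary:
    """Aggregate trial scores to one accuracy per participant × condition.

    ``weighting="pooled"`` (default) computes Σ correct / Σ slots across
    all trials, weighting each slot equally across list lengths;
    ``weighting="mean"`` averages trial proportions instead.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to aggregate")
    total_slots = sum(t.n_slots for t in trials)
    total_correct = sum(t.n_correct for t in trials)
    if weighting == "pooled":
        mean_proportion = total_correct / total_slots
    elif weighting == "mean":
        mean_proportion = sum(t.proportion for t in trials) / len(trials)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return ConditionSummary(
        participant=participant, condition=condition, kind=kind,
        n_slots=total_slots, n_correct=total_correct,
        mean_proportion=mean_proportion,
    )
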