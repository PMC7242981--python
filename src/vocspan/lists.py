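"""Generation and validation of serial-recall stimulus lists.

Two list families are supported:

* **Digit lists** (lengths 2–9, digits 1–9) edited so that no adjacent pair
  of digits differs by one or repeats — runs like (4, 5) or (5, 5) invite
  chunking, which inflates recall for reasons unrelated to memory capacity.
* **Word lists** (lengths 1–6) drawn from a 60-item inventory of
  consonant–vowel–consonant (CVC) words over a restricted phoneme set
  chosen to minimize phonetic confusions. Within a list, no phoneme may
  repeat in the same word position (all initial consonants distinct, all
  vowels distinct, all final consonants distinct), lists of equal length are
  balanced on lexical neighborhood density and log word frequency, and each
  word is used 3 or 4 times per spectral-resolution block, 10 or 11 times
  across the whole session.

An independent :func:`validate_list` re-implements every rule so generator
bugs cannot hide behind shared code, and :func:`order_block` arranges lists
for presentation (no two consecutive lists of the same length; an easy
first trial).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "INITIAL_CONSONANTS",
    "FINAL_CONSONANTS",
    "VOWELS",
    "Word",
    "RecallList",
    "ListGenerationError",
    "generate_digit_list",
    "generate_word_lists",
    "validate_list",
    "order_block",
    "build_synthetic_inventory",
    "read_word_inventory",
    "write_word_inventory",
]

#: Allowed phonemes (IPA). /h/ occurs initial-only, /z/ final-only.
INITIAL_CONSONANTS = ("w", "d", "p", "s", "ʃ", "m", "f", "v", "tʃ", "h")
FINAL_CONSONANTS = ("w", "d", "p", "s", "ʃ", "m", "f", "v", "tʃ", "z")
VOWELS = ("æ", "ɑ", "e", "ɛ", "i", "o", "u")

DIGITS = tuple(range(1, 10))


class ListGenerationError(RuntimeError):
    """Constraint satisfaction failed after the configured search budget."""


@dataclass(frozen=True)
class Word:
    """A CVC word with the lexical attributes used for list balancing."""

    orthography: str
    phonemes: tuple[str, str, str]
    neighborhood_density: float
    log_frequency: float

    def __post_init__(self) -> None:
        c1, v, c2 = self.phonemes
        if c1 not in INITIAL_CONSONANTS:
            raise ValueError(f"{self.orthography}: initial consonant {c1!r} not allowed")
        if v not in VOWELS:
            raise ValueError(f"{self.orthography}: vowel {v!r} not allowed")
        if c2 not in FINAL_CONSONANTS:
            raise ValueError(f"{self.orthography}: final consonant {c2!r} not allowed")


@dataclass(frozen=True)
class RecallList:
    """An ordered recall list: digits 1–9 or Word items, with its condition."""

    kind: str  # "digit" | "word"
    items: tuple
    condition: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("digit", "word"):
            raise ValueError(f"unknown list kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# digit lists


def generate_digit_list(
    length: int, rng: np.random.Generator, condition: str = ""
) -> RecallList:
    """A uniform random digit list with no adjacent pair differing by <= 1.

    Rejection sampling from the uniform distribution over all sequences of
    digits 1-9 keeps the distribution uniform over the valid set.
    """
    if not 2 <= length <= 9:
        raise ValueError(f"digit list length must be in [2, 9], got {length}")
    while True:
        digits = rng.integers(1, 10, size=length)
        if np.all(np.abs(np.diff(digits)) > 1):
            return RecallList(kind="digit", items=tuple(int(d) for d in digits),
                              condition=condition)


# ---------------------------------------------------------------------------
# word lists

WORD_LENGTHS = (1, 2, 3, 4, 5, 6)


def _list_ok(words: Sequence[Word]) -> bool:
    for pos in range(3):
        seen = [w.phonemes[pos] for w in words]
        if len(set(seen)) != len(seen):
            return False
    return True


def _block_quotas(
    n_words: int, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-word, per-block usage counts in {3, 4} summing to 10 or 11.

    Half the words receive count 4 in exactly two blocks (total 11), half in
    exactly one (total 10); each block gets exactly half its words at 4, so
    block totals are equal.
    """
    if n_words % 2 or n_blocks != 3:
        raise ListGenerationError("usage quota scheme requires an even inventory and 3 blocks")
    half = n_words // 2
    pair_patterns = [(0, 1), (1, 2), (0, 2)] * (half // 3) + [(0, 1), (1, 2), (0, 2)][: half % 3]
    single_patterns = [(b,) for b in ([0, 1, 2] * (half // 3) + [0, 1, 2][: half % 3])]
    patterns = pair_patterns + single_patterns
    order = rng.permutation(n_words)
    quotas = np.full((n_words, 3), 3, dtype=int)
    for word_idx, pattern in zip(order, patterns):
        for b in pattern:
            quotas[word_idx, b] = 4
    return quotas


def _pick_singletons(
    inventory: Sequence[Word], counts: np.ndarray, n_needed: int,
    d_scale: float, f_scale: float,
) -> list[int]:
    """Word indices for the length-1 lists, chosen for tight lexical spread.

    Singleton lists are the hardest to balance (a list mean is a single
    word's value), so they are pre-selected: anchor on each word in turn,
    absorb the nearest words in normalized (density, frequency) space until
    enough usage instances are gathered, and keep the anchor minimizing the
    larger of the two spreads.
    """
    dens = np.array([w.neighborhood_density for w in inventory]) / d_scale
    freq = np.array([w.log_frequency for w in inventory]) / f_scale
    best: list[int] | None = None
    best_spread = np.inf
    for anchor in range(len(inventory)):
        dist = np.maximum(np.abs(dens - dens[anchor]), np.abs(freq - freq[anchor]))
        order = np.argsort(dist)
        chosen: list[int] = []
        for idx in order:
            chosen.extend([idx] * int(counts[idx]))
            if len(chosen) >= n_needed:
                break
        chosen = chosen[:n_needed]
        uniq = np.array(sorted(set(chosen)))
        spread = max(dens[uniq].max() - dens[uniq].min(),
                     freq[uniq].max() - freq[uniq].min())
        if spread < best_spread:
            best_spread = spread
            best = chosen
    assert best is not None
    return best


def _build_block_lists(
    inventory: Sequence[Word],
    counts: np.ndarray,
    trials_per_length: int,
    rng: np.random.Generator,
    max_restarts: int = 200,
) -> list[list[int]]:
    """Partition the block's word-instance multiset into phoneme-valid lists."""
    d_vals = np.array([w.neighborhood_density for w in inventory], dtype=float)
    f_vals = np.array([w.log_frequency for w in inventory], dtype=float)
    d_scale = float(d_vals.std(ddof=1)) or 1.0
    f_scale = float(f_vals.std(ddof=1)) or 1.0

    lengths = [length for length in WORD_LENGTHS for _ in range(trials_per_length)]
    for _ in range(max_restarts):
        remaining = counts.copy()
        lists: list[list[int]] = []
        singles = _pick_singletons(inventory, remaining, trials_per_length,
                                   d_scale, f_scale)
        feasible_singles = True
        for idx in singles:
            if remaining[idx] <= 0:
                feasible_singles = False
                break
            remaining[idx] -= 1
            lists.append([idx])
        if not feasible_singles:
            continue
        ok = True
        for length in sorted((l for l in lengths if l > 1), reverse=True):
            built = _build_one_list(inventory, remaining, length, rng)
            if built is None:
                ok = False
                break
            for idx in built:
                remaining[idx] -= 1
            lists.append(built)
        if ok and np.all(remaining == 0):
            return lists
    raise ListGenerationError(
        "could not partition word instances into phoneme-valid lists; "
        "inventory may be too concentrated on few phonemes"
    )


def _build_one_list(
    inventory: Sequence[Word], remaining: np.ndarray, length: int,
    rng: np.random.Generator, attempts: int = 80,
) -> list[int] | None:
    candidates = np.flatnonzero(remaining > 0)
    if candidates.size < length:
        return None
    for _ in range(attempts):
        chosen: list[int] = []
        used = [set(), set(), set()]
        pool = list(candidates)
        weights = remaining[candidates].astype(float)
        order = rng.permutation(len(pool))
        # prefer words with more remaining uses to avoid stranding instances
        order = sorted(order, key=lambda i: (-weights[i], rng.random()))
        for i in order:
            idx = pool[i]
            word = inventory[idx]
            if any(word.phonemes[p] in used[p] for p in range(3)):
                continue
            chosen.append(idx)
            for p in range(3):
                used[p].add(word.phonemes[p])
            if len(chosen) == length:
                return chosen
    return None


def _balance_repair(
    lists: list[list[int]],
    inventory: Sequence[Word],
    rng: np.random.Generator,
    tolerance: float,
    max_proposals: int = 200_000,
) -> None:
    """Pairwise swap repair pushing equal-length list means together.

    Swapping one word instance between two lists preserves list lengths and
    block usage counts; a swap is kept only when both lists stay
    phoneme-valid. Directed rounds move the most offending word out of the
    extreme list of the worst-balanced group; random proposals (including
    occasional sideways moves) shake the search off plateaus. The internal
    target is 90% of the tolerance so the hinge objective keeps a gradient
    up to the finish line; success is judged against the full tolerance.
    """
    d_raw = [w.neighborhood_density for w in inventory]
    f_raw = [w.log_frequency for w in inventory]
    d_sd = float(np.std(d_raw, ddof=1)) or 1.0
    f_sd = float(np.std(f_raw, ddof=1)) or 1.0
    d = [v / d_sd for v in d_raw]
    f = [v / f_sd for v in f_raw]
    phon = [w.phonemes for w in inventory]
    target = 0.9 * tolerance

    n_lists = len(lists)
    sizes = [len(lst) for lst in lists]
    d_sum = [sum(d[k] for k in lst) for lst in lists]
    f_sum = [sum(f[k] for k in lst) for lst in lists]
    groups: dict[int, list[int]] = {}
    for pos, lst in enumerate(lists):
        groups.setdefault(len(lst), []).append(pos)

    def group_excess(length: int, tol: float = target) -> float:
        members = groups[length]
        if len(members) < 2:
            return 0.0
        dm = [d_sum[m] / sizes[m] for m in members]
        fm = [f_sum[m] / sizes[m] for m in members]
        total = 0.0
        spread = max(dm) - min(dm) - tol
        if spread > 0:
            total += spread
        spread = max(fm) - min(fm) - tol
        if spread > 0:
            total += spread
        return total

    excess = {length: group_excess(length) for length in groups}
    current = sum(excess.values())

    def ok_swap(host: list[int], pos: int, new_word: int) -> bool:
        pn = phon[new_word]
        for k, idx in enumerate(host):
            if k == pos:
                continue
            q = phon[idx]
            if pn[0] == q[0] or pn[1] == q[1] or pn[2] == q[2]:
                return False
        return True

    def try_swap(a: int, i: int, b: int, j: int, sideways: bool = False) -> bool:
        nonlocal current
        wa, wb = lists[a][i], lists[b][j]
        if wa == wb:
            return False
        if not ok_swap(lists[a], i, wb) or not ok_swap(lists[b], j, wa):
            return False
        dd, df = d[wb] - d[wa], f[wb] - f[wa]
        d_sum[a] += dd
        f_sum[a] += df
        d_sum[b] -= dd
        f_sum[b] -= df
        touched = {sizes[a], sizes[b]}
        new_excess = {length: group_excess(length) for length in touched}
        new = current + sum(new_excess[t] - excess[t] for t in touched)
        if new < current - 1e-12 or (sideways and new <= current + 1e-12):
            lists[a][i], lists[b][j] = wb, wa
            excess.update(new_excess)
            current = new
            return True
        d_sum[a] -= dd
        f_sum[a] -= df
        d_sum[b] += dd
        f_sum[b] += df
        return False

    def directed_round() -> bool:
        """Move the most offending word out of the worst group\'s extreme list."""
        length = max(excess, key=lambda k: excess[k])
        if excess[length] <= 0:
            return False
        members = groups[length]
        dm = [(d_sum[m] / sizes[m], m) for m in members]
        fm = [(f_sum[m] / sizes[m], m) for m in members]
        d_spread = max(dm)[0] - min(dm)[0]
        f_spread = max(fm)[0] - min(fm)[0]
        vals, ranking = (d, dm) if d_spread >= f_spread else (f, fm)
        hi, lo = max(ranking)[1], min(ranking)[1]
        for a, want_smaller in ((hi, True), (lo, False)):
            la = lists[a]
            key = max if want_smaller else min
            i = key(range(len(la)), key=lambda k: vals[la[k]])
            wa = la[i]
            order = list(rng.permutation(n_lists))
            for b in order:
                if b == a:
                    continue
                lb = lists[b]
                for j in range(len(lb)):
                    wb = lb[j]
                    if want_smaller and vals[wb] >= vals[wa]:
                        continue
                    if not want_smaller and vals[wb] <= vals[wa]:
                        continue
                    if try_swap(a, i, b, j):
                        return True
        return False

    budget = max_proposals
    while budget > 0 and current > 1e-9:
        if directed_round():
            budget -= 1
            continue
        # directed search stuck: random shake with occasional sideways moves
        for _ in range(min(4000, budget)):
            budget -= 1
            a = int(rng.integers(0, n_lists))
            b = int(rng.integers(0, n_lists))
            if a == b:
                continue
            i = int(rng.integers(0, sizes[a]))
            j = int(rng.integers(0, sizes[b]))
            try_swap(a, i, b, j, sideways=rng.random() < 0.4)
            if current <= 1e-9:
                return
    remaining = sum(group_excess(length, tolerance) for length in groups)
    if remaining > 0.0:
        raise ListGenerationError(
            f"lexical balance not reached (excess spread {remaining:.4f} in "
            f"pooled-SD units after swap repair)"
        )


def generate_word_lists(
    inventory: Sequence[Word],
    rng: np.random.Generator,
    n_blocks: int = 3,
    trials_per_length: int = 10,
    conditions: Sequence[str] | None = None,
    balance_tolerance: float = 0.5,
) -> dict[str, list[RecallList]]:
    """Word lists for every block under usage, phoneme and balance constraints.

    Each block receives ``trials_per_length`` lists of each length 1-6
    (210 word slots for the default 10), drawn so that every inventory word
    is used 3 or 4 times per block and 10 or 11 times overall. Within a
    list no phoneme repeats in the same word position; across lists of
    equal length the means of neighborhood density and log frequency differ
    by at most ``balance_tolerance`` pooled SDs.

    Raises :class:`ListGenerationError` with a diagnostic when the search
    budget is exhausted — constraints are never silently violated.
    """
    inventory = list(inventory)
    if len(inventory) != 60:
        raise ValueError(f"inventory must hold 60 words, got {len(inventory)}")
    if conditions is None:
        conditions = [f"block{b + 1}" for b in range(n_blocks)]
    slots = trials_per_length * sum(WORD_LENGTHS)
    quota_total = slots  # per block
    if not 3 * len(inventory) <= quota_total <= 4 * len(inventory):
        raise ListGenerationError(
            f"{quota_total} word slots per block incompatible with 3-4 uses "
            f"of each of {len(inventory)} words"
        )
    quotas = _block_quotas(len(inventory), n_blocks, rng)
    out: dict[str, list[RecallList]] = {}
    for block in range(n_blocks):
        # swap repair can stall in a local minimum; rebuild from a fresh
        # random partition when it does
        last_error: ListGenerationError | None = None
        for _ in range(8):
            idx_lists = _build_block_lists(inventory, quotas[:, block],
                                           trials_per_length, rng)
            try:
                _balance_repair(idx_lists, inventory, rng, balance_tolerance)
                last_error = None
                break
            except ListGenerationError as exc:
                last_error = exc
        if last_error is not None:
            raise last_error
        block_lists = [
            RecallList(kind="word",
                       items=tuple(inventory[k] for k in lst),
                       condition=conditions[block])
            for lst in idx_lists
        ]
        out[conditions[block]] = block_lists
    return out


# ---------------------------------------------------------------------------
# independent validator


def validate_list(recall_list: RecallList) -> tuple[bool, list[str]]:
    """Independently re-check every constraint a list must satisfy.

    Deliberately shares no code with the generators: each rule is written
    out explicitly so the validator can serve as an oracle for them.
    Returns (valid, list of named violations).
    """
    violations: list[str] = []
    items = recall_list.items
    if recall_list.kind == "digit":
        if not 2 <= len(items) <= 9:
            violations.append(f"digit list length {len(items)} outside [2, 9]")
        for item in items:
            if item not in (1, 2, 3, 4, 5, 6, 7, 8, 9):
                violations.append(f"item {item!r} is not a digit 1-9")
        for pos in range(len(items) - 1):
            first, second = items[pos], items[pos + 1]
            if isinstance(first, int) and isinstance(second, int):
                if abs(first - second) == 1:
                    violations.append(
                        f"adjacent ±1 transition ({first}, {second}) at position {pos + 1}"
                    )
                elif first == second:
                    violations.append(
                        f"adjacent repeat ({first}, {second}) at position {pos + 1}"
                    )
    elif recall_list.kind == "word":
        if not 1 <= len(items) <= 6:
            violations.append(f"word list length {len(items)} outside [1, 6]")
        position_names = ("initial consonant", "vowel", "final consonant")
        allowed = (INITIAL_CONSONANTS, VOWELS, FINAL_CONSONANTS)
        for pos in range(3):
            seen: dict[str, int] = {}
            for word_idx, word in enumerate(items):
                phoneme = word.phonemes[pos]
                if phoneme not in allowed[pos]:
                    violations.append(
                        f"{position_names[pos]} {phoneme!r} not in the allowed inventory"
                    )
                if phoneme in seen:
                    violations.append(
                        f"{position_names[pos]} repeated in position {pos + 1}: "
                        f"{phoneme!r} (words {seen[phoneme] + 1} and {word_idx + 1})"
                    )
                else:
                    seen[phoneme] = word_idx
    return (len(violations) == 0, violations)


# ---------------------------------------------------------------------------
# presentation order


def order_block(
    lists: Sequence[RecallList], rng: np.random.Generator, max_attempts: int = 2000
) -> list[RecallList]:
    """Order a block's lists for presentation.

    No two consecutive lists may share a length, and the first trial must be
    easy: at most six digits or four words. Raises when the length multiset
    admits no such ordering.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("empty block")
    lengths = [len(lst) for lst in lists]
    counts: dict[int, int] = {}
    for length in lengths:
        counts[length] = counts.get(length, 0) + 1
    if max(counts.values()) > (len(lists) + 1) // 2:
        raise ListGenerationError(
            f"length multiset {sorted(lengths)} cannot avoid consecutive repeats"
        )
    first_cap = 6 if lists[0].kind == "digit" else 4
    if not any(len(lst) <= first_cap for lst in lists):
        raise ListGenerationError(f"no list short enough (≤{first_cap}) to open the block")
    for _ in range(max_attempts):
        order = list(rng.permutation(len(lists)))
        arranged = _greedy_arrange([lists[i] for i in order], first_cap)
        if arranged is not None:
            return arranged
    raise ListGenerationError("no valid presentation order found within attempt budget")


def _greedy_arrange(pool: list[RecallList], first_cap: int) -> list[RecallList] | None:
    remaining = list(pool)
    out: list[RecallList] = []
    prev_len = None
    while remaining:
        # pick the most abundant eligible length to keep the tail feasible
        eligible = [
            lst for lst in remaining
            if len(lst) != prev_len and (out or len(lst) <= first_cap)
        ]
        if not eligible:
            return None
        tallies: dict[int, int] = {}
        for lst in remaining:
            tallies[len(lst)] = tallies.get(len(lst), 0) + 1
        eligible.sort(key=lambda lst: -tallies[len(lst)])
        chosen = eligible[0]
        remaining.remove(chosen)
        out.append(chosen)
        prev_len = len(chosen)
    return out


# ---------------------------------------------------------------------------
# inventories

_ORTHO = {
    "w": "w", "d": "d", "p": "p", "s": "s", "ʃ": "sh", "m": "m", "f": "f",
    "v": "v", "tʃ": "ch", "h": "h", "z": "z",
    "æ": "a", "ɑ": "ah", "e": "ay", "ɛ": "e", "i": "ee", "o": "oh", "u": "oo",
}


def build_synthetic_inventory(seed: int = 0, n_words: int = 60) -> list[Word]:
    """A synthetic 60-word CVC inventory with balanced phoneme coverage.

    Stands in for a curated word set (which is study material, not part of
    this package): phoneme triples are drawn so each position's phonemes are
    used nearly equally, and lexical attributes (neighborhood density,
    log frequency) are sampled with a cluster of near-median words so that
    list balancing is feasible, mimicking how a curated inventory is chosen
    to permit balanced lists.
    """
    from itertools import product

    rng = np.random.default_rng(seed)
    triples: list[tuple[str, str, str]] = []
    used = [dict.fromkeys(INITIAL_CONSONANTS, 0),
            dict.fromkeys(VOWELS, 0),
            dict.fromkeys(FINAL_CONSONANTS, 0)]
    caps = [int(np.ceil(n_words / len(s)))
            for s in (INITIAL_CONSONANTS, VOWELS, FINAL_CONSONANTS)]
    pool = list(product(INITIAL_CONSONANTS, VOWELS, FINAL_CONSONANTS))
    order = rng.permutation(len(pool))
    # greedy pass under near-uniform phoneme-usage caps; if exact caps leave
    # the selection short (a dead end), relax them by one and sweep again
    while len(triples) < n_words:
        for k in order:
            c1, v, c2 = pool[k]
            if (c1, v, c2) in triples:
                continue
            if (used[0][c1] >= caps[0] or used[1][v] >= caps[1]
                    or used[2][c2] >= caps[2]):
                continue
            used[0][c1] += 1
            used[1][v] += 1
            used[2][c2] += 1
            triples.append((c1, v, c2))
            if len(triples) == n_words:
                break
        else:
            caps = [c + 1 for c in caps]
    # attributes: half the words scattered, half clustered near the median so
    # that equal-length lists can be balanced (as a curated set would allow)
    density = np.where(rng.random(n_words) < 0.5,
                       np.round(20 + 1.5 * rng.standard_normal(n_words)),
                       np.round(20 + 6.0 * rng.standard_normal(n_words)))
    density = np.clip(density, 1, None)
    log_freq = np.where(rng.random(n_words) < 0.5,
                        2.5 + 0.15 * rng.standard_normal(n_words),
                        2.5 + 0.7 * rng.standard_normal(n_words))
    words = []
    for k, (c1, v, c2) in enumerate(triples):
        ortho = _ORTHO[c1] + _ORTHO[v] + _ORTHO[c2]
        words.append(Word(orthography=ortho, phonemes=(c1, v, c2),
                          neighborhood_density=float(density[k]),
                          log_frequency=float(np.round(log_freq[k], 3))))
    return words


def read_word_inventory(path: str | Path) -> list[Word]:
    """Read a word inventory from CSV.

    Expected columns: orthography, initial, vowel, final,
    neighborhood_density, log_frequency. Homophones (identical phoneme
    triples) all receive the highest log frequency within their group, the
    convention used when balancing lists.
    """
    words: list[Word] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            words.append(Word(
                orthography=row["orthography"],
                phonemes=(row["initial"], row["vowel"], row["final"]),
                neighborhood_density=float(row["neighborhood_density"]),
                log_frequency=float(row["log_frequency"]),
            ))
    by_triple: dict[tuple[str, str, str], float] = {}
    for word in words:
        prev = by_triple.get(word.phonemes, -np.inf)
        by_triple[word.phonemes] = max(prev, word.log_frequency)
    return [
        Word(w.orthography, w.phonemes, w.neighborhood_density, by_triple[w.phonemes])
        for w in words
    ]


def write_word_inventory(path: str | Path, words: Iterable[Word]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["orthography", "initial", "vowel", "final",
                         "neighborhood_density", "log_frequency"])
        for word in words:
            writer.writerow([word.orthography, *word.phonemes,
                             word.neighborhood_density, word.log_frequency])
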