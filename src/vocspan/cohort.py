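"""Synthetic study cohort with correlated latent abilities.

Generates a full synthetic session — recall trials, sentence trials,
reaction-time trials, and participant covariates — with the statistical
structure the downstream analysis assumes, so the whole pipeline is
testable without human data and parameter recovery can be verified.

Generative model
----------------
Each participant carries five standard-normal latents: ``serial_ability``
(short-term serial memory), ``sentence_skill`` (sentence recognition
ability, correlated 0.73 with serial ability so the observed composite
correlation lands near 0.65 after measurement noise), ``vocoder_sensitivity``
(how much degraded spectral resolution hurts word identification),
``reasoning`` (fluid intelligence), and ``speed`` (general response
slowness, negatively correlated with reasoning and serial ability).

Every recall/keyword slot is a Bernoulli draw with

    p = logistic(intercept − length_penalty·(length − ref)
                 + skill_slope·latent − voc_slope·vocoder_sensitivity
                 + block_sd·block_noise)

where ``block_noise`` is a per-participant, per-condition state term that
keeps conditions from being perfectly correlated. Digit conditions carry no
vocoding penalty (digit recall is insensitive to spectral resolution).
Condition intercepts are solved numerically (Gauss–Hermite quadrature +
root finding) so that the expected group accuracies equal the configured
targets: sentences 88.1/77.1/39.1 % with between-participant SDs
5.6/6.4/7.2 %, digits 81 % in every condition, words 86/82/65 %.

Reaction times are ex-Gaussian: RT = N(μ + speed·shift + condition cost, σ)
+ Exp(τ), 80 trials per condition, with a configurable contaminant rate to
exercise outlier trimming. Condition costs default to the calibrated study
effects (switch cost 145 ms; Stroop incongruent costs 153/137 ms vs
neutral/congruent).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .lists import Word, generate_digit_list, generate_word_lists

__all__ = [
    "CohortConfig",
    "Cohort",
    "sample_cohort",
    "simulate_covariates",
    "simulate_accuracy_table",
    "simulate_recall_trials",
    "simulate_rt_trials",
    "accuracy_column",
]

CONDITIONS = ("16", "8", "4")


@dataclass(frozen=True)
class CohortConfig:
    """All generative parameters of the synthetic study.

    Defaults encode the study conditions: 32 participants, three spectral
    resolutions, the group accuracy targets, 80 RT trials per condition,
    and the latent correlation structure described in the module docstring.
    """

    n_participants: int = 32
    conditions: tuple[str, ...] = CONDITIONS

    # latent correlation structure
    rho_serial_sentence: float = 0.73
    rho_serial_reasoning: float = 0.35
    rho_speed_serial: float = -0.35
    rho_speed_reasoning: float = -0.45

    # sentence recognition (key-word slots)
    sentence_target_means: tuple[float, ...] = (0.881, 0.771, 0.391)
    sentence_target_sds: tuple[float, ...] = (0.056, 0.064, 0.072)
    sentence_voc_fraction: tuple[float, ...] = (0.0, 0.20, 0.25)
    sentence_block_fraction: float = 0.15
    n_sentences_per_condition: int = 36
    keywords_per_condition: int = 152

    # digit serial recall
    digit_lengths: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9)
    digit_trials_per_length: int = 2
    digit_target_mean: float = 0.81
    digit_serial_slope: float = 0.55
    digit_block_sd: float = 0.22
    digit_length_slope: float = 0.50

    # word serial recall (phoneme slots)
    word_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    word_trials_per_length: int = 10
    word_target_means: tuple[float, ...] = (0.86, 0.82, 0.65)
    word_serial_slope: float = 0.55
    word_voc_slopes: tuple[float, ...] = (0.10, 0.25, 0.60)
    word_block_sd: float = 0.22
    word_length_slope: float = 0.35

    # reaction-time tasks (ms)
    rt_trials_per_condition: int = 80
    colorshape_mu: float = 700.0
    colorshape_sigma: float = 90.0
    colorshape_tau: float = 180.0
    switch_cost_mean: float = 145.0
    switch_cost_sd: float = 15.0
    stroop_mu: float = 650.0
    stroop_sigma: float = 85.0
    stroop_tau: float = 170.0
    congruent_offset_mean: float = 16.0
    congruent_offset_sd: float = 5.0
    incongruent_cost_mean: float = 153.0
    incongruent_cost_sd: float = 15.0
    speed_slope_ms: float = 60.0
    contaminant_rate: float = 0.01
    rt_accuracy: float = 0.985

    # covariates
    reasoning_mean: float = 103.0
    reasoning_sd: float = 10.8

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix over (serial, sentence, vocoder, reasoning, speed)."""
        rs, rr = self.rho_serial_sentence, self.rho_serial_reasoning
        ps, pr = self.rho_speed_serial, self.rho_speed_reasoning
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = rs
        corr[0, 3] = corr[3, 0] = rr
        corr[1, 3] = corr[3, 1] = rs * rr          # implied via serial
        corr[0, 4] = corr[4, 0] = ps
        corr[1, 4] = corr[4, 1] = rs * ps          # implied via serial
        corr[3, 4] = corr[4, 3] = pr
        return corr


@dataclass(frozen=True)
class Cohort:
    """Sampled latent profiles, one entry per participant."""

    serial_ability: np.ndarray
    sentence_skill: np.ndarray
    vocoder_sensitivity: np.ndarray
    reasoning: np.ndarray
    speed: np.ndarray

    @property
    def n(self) -> int:
        return self.serial_ability.size

    @property
    def participants(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n)]


def sample_cohort(config: CohortConfig, rng: np.random.Generator) -> Cohort:
    """Multivariate-normal latent profiles with the configured correlations."""
    corr = config.latent_correlation()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent correlation matrix is not positive definite") from exc
    z = rng.standard_normal((config.n_participants, 5))
    latents = z @ chol.T
    return Cohort(
        serial_ability=latents[:, 0],
        sentence_skill=latents[:, 1],
        vocoder_sensitivity=latents[:, 2],
        reasoning=latents[:, 3],
        speed=latents[:, 4],
    )


# ---------------------------------------------------------------------------
# intercept calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)  # E[f(Z)] = sum w f(x)


def _pooled_accuracy(intercept: float, latent_sd: float,
                     length_offsets: np.ndarray, slot_weights: np.ndarray) -> float:
    """Expected slot-pooled accuracy over the latent distribution."""
    logits = (intercept + length_offsets[:, None]
              + latent_sd * _GH_NODES[None, :])
    p = expit(logits)
    per_latent = slot_weights @ p / slot_weights.sum()
    return float(per_latent @ _GH_WEIGHTS)


def _accuracy_sd(intercept: float, latent_sd: float,
                 length_offsets: np.ndarray, slot_weights: np.ndarray) -> float:
    """Predicted between-participant SD of pooled accuracy (incl. binomial)."""
    logits = (intercept + length_offsets[:, None]
              + latent_sd * _GH_NODES[None, :])
    p = expit(logits)
    weights = slot_weights / slot_weights.sum()
    acc = weights @ p
    mean = float(acc @ _GH_WEIGHTS)
    var_latent = float((acc**2) @ _GH_WEIGHTS) - mean**2
    # pooled binomial variance: sum_len slots·p(1−p) / total² = (w/total)·p(1−p)
    binom = float(((weights / slot_weights.sum()) @ (p * (1 - p))) @ _GH_WEIGHTS)
    return float(np.sqrt(var_latent + binom))


def _solve_intercept(target: float, latent_sd: float,
                     length_offsets: np.ndarray, slot_weights: np.ndarray) -> float:
    return brentq(
        lambda b: _pooled_accuracy(b, latent_sd, length_offsets, slot_weights) - target,
        -15.0, 15.0, xtol=1e-10,
    )


@dataclass(frozen=True)
class _SlotModel:
    intercept: float
    skill_slope: float      # multiplies serial ability (or sentence skill)
    voc_slope: float        # multiplies vocoder sensitivity (negatively)
    block_sd: float
    length_offsets: np.ndarray
    lengths: tuple[int, ...]
    slots_per_length: np.ndarray    # total slots per length across the block


def _digit_model(config: CohortConfig) -> _SlotModel:
    lengths = np.array(config.digit_lengths, dtype=float)
    offsets = -config.digit_length_slope * (lengths - lengths.mean())
    slots = lengths * config.digit_trials_per_length
    latent_sd = float(np.hypot(config.digit_serial_slope, config.digit_block_sd))
    intercept = _solve_intercept(config.digit_target_mean, latent_sd, offsets, slots)
    return _SlotModel(intercept, config.digit_serial_slope, 0.0,
                      config.digit_block_sd, offsets, config.digit_lengths, slots)


def _word_model(config: CohortConfig, cond_index: int) -> _SlotModel:
    lengths = np.array(config.word_lengths, dtype=float)
    offsets = -config.word_length_slope * (lengths - lengths.mean())
    slots = 3 * lengths * config.word_trials_per_length
    voc = config.word_voc_slopes[cond_index]
    latent_sd = float(np.sqrt(config.word_serial_slope**2 + voc**2
                              + config.word_block_sd**2))
    intercept = _solve_intercept(config.word_target_means[cond_index],
                                 latent_sd, offsets, slots)
    return _SlotModel(intercept, config.word_serial_slope, voc,
                      config.word_block_sd, offsets, config.word_lengths, slots)


def _sentence_model(config: CohortConfig, cond_index: int) -> _SlotModel:
    """Solve (intercept, total latent SD) to hit the target mean and SD."""
    offsets = np.zeros(1)
    slots = np.array([float(config.keywords_per_condition)])
    target_mean = config.sentence_target_means[cond_index]
    target_sd = config.sentence_target_sds[cond_index]

    def sd_gap(latent_sd: float) -> float:
        b = _solve_intercept(target_mean, latent_sd, offsets, slots)
        return _accuracy_sd(b, latent_sd, offsets, slots) - target_sd

    total_sd = brentq(sd_gap, 1e-6, 5.0, xtol=1e-9)
    intercept = _solve_intercept(target_mean, total_sd, offsets, slots)
    voc_frac = config.sentence_voc_fraction[cond_index]
    block_frac = config.sentence_block_fraction
    skill_frac_sq = 1.0 - voc_frac**2 - block_frac**2
    if skill_frac_sq <= 0:
        raise ValueError("sentence variance fractions exceed 1")
    return _SlotModel(
        intercept, total_sd * float(np.sqrt(skill_frac_sq)),
        total_sd * voc_frac, total_sd * block_frac,
        offsets, (1,), slots,
    )


@lru_cache(maxsize=8)
def _calibrated_models(config: CohortConfig):
    return {
        ("digit", cond): _digit_model(config)
        for cond in config.conditions
    } | {
        ("word", cond): _word_model(config, i)
        for i, cond in enumerate(config.conditions)
    } | {
        ("sentence", cond): _sentence_model(config, i)
        for i, cond in enumerate(config.conditions)
    }


def _participant_logits(model: _SlotModel, kind: str, cohort: Cohort,
                        block_noise: np.ndarray) -> np.ndarray:
    """Per-participant logit offset (before length terms)."""
    skill = cohort.sentence_skill if kind == "sentence" else cohort.serial_ability
    return (model.intercept
            + model.skill_slope * skill
            - model.voc_slope * cohort.vocoder_sensitivity
            + model.block_sd * block_noise)


def accuracy_column(kind: str, condition: str) -> str:
    return f"{kind}_{condition}"


def simulate_accuracy_table(
    cohort: Cohort, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Participant × (kind, condition) pooled-accuracy table.

    Draws slot outcomes binomially per list length — distributionally
    identical to the trial-level path but without materializing item
    sequences; used for replicate studies and calibration checks.
    """
    models = _calibrated_models(config)
    columns: dict[str, np.ndarray] = {}
    for kind in ("sentence", "digit", "word"):
        for cond in config.conditions:
            model = models[(kind, cond)]
            noise = rng.standard_normal(cohort.n)
            base = _participant_logits(model, kind, cohort, noise)
            n_corr = np.zeros(cohort.n)
            n_tot = 0.0
            for offset, slot in zip(model.length_offsets, model.slots_per_length):
                per_len = int(round(float(slot)))
                p = expit(base + offset)
                n_corr += rng.binomial(per_len, p)
                n_tot += per_len
            columns[accuracy_column(kind, cond)] = n_corr / n_tot
    frame = pd.DataFrame(columns, index=cohort.participants)
    frame.index.name = "participant"
    return frame


def simulate_covariates(
    cohort: Cohort, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Participant covariate table: reasoning index and TOVA percentiles.

    The reasoning score is a normed index (configured mean/SD) derived from
    the reasoning latent; the four TOVA percentile scores are independent
    of everything else, mirroring their role as null covariates.
    """
    from scipy.stats import norm

    pri = np.round(config.reasoning_mean + config.reasoning_sd * cohort.reasoning)
    rows = {"participant": cohort.participants,
            "reasoning_pri": np.clip(pri, 55, 145).astype(int)}
    for name in ("tova_rt_cns", "tova_var_cns", "tova_com_cns", "tova_omi_cns"):
        z = rng.standard_normal(cohort.n)
        rows[name] = np.clip(np.round(100 * norm.cdf(z)), 1, 99).astype(int)
    return pd.DataFrame(rows).set_index("participant")


# ---------------------------------------------------------------------------
# trial-level simulation

def _keyword_counts(config: CohortConfig) -> list[int]:
    n = config.n_sentences_per_condition
    counts = [4] * n
    extra = config.keywords_per_condition - 4 * n
    if extra < 0 or extra > n:
        raise ValueError("keyword total incompatible with sentence count")
    for i in range(extra):
        counts[(i * 4) % n] += 1
    return counts


def simulate_recall_trials(
    cohort: Cohort,
    config: CohortConfig,
    rng: np.random.Generator,
    inventory: list[Word] | None = None,
) -> pd.DataFrame:
    """Full trial-level records for digit, word and sentence tasks.

    Target item sequences come from the stimulus-list generators (digit
    lists respect the no-±1 rule; word lists satisfy the usage, phoneme and
    balance constraints). Each slot outcome is a Bernoulli draw from the
    participant's slot probability; responses are constructed to realize
    exactly those outcomes (a wrong slot receives a random different item
    or phoneme). Columns: participant, kind, condition, trial, target,
    response, n_slots, n_correct.
    """
    from .lists import build_synthetic_inventory

    models = _calibrated_models(config)
    if inventory is None:
        inventory = build_synthetic_inventory(seed=int(rng.integers(2**31)))
    word_blocks = generate_word_lists(
        inventory, rng, n_blocks=len(config.conditions),
        trials_per_length=config.word_trials_per_length,
        conditions=list(config.conditions),
    )
    digit_blocks = {
        cond: [
            generate_digit_list(length, rng, condition=cond)
            for length in config.digit_lengths
            for _ in range(config.digit_trials_per_length)
        ]
        for cond in config.conditions
    }
    keyword_counts = _keyword_counts(config)

    records: list[dict] = []
    for kind in ("digit", "word", "sentence"):
        for cond in config.conditions:
            model = models[(kind, cond)]
            noise = rng.standard_normal(cohort.n)
            base = _participant_logits(model, kind, cohort, noise)
            length_offset = dict(zip(model.lengths, model.length_offsets))
            for pi, participant in enumerate(cohort.participants):
                if kind == "digit":
                    trials = digit_blocks[cond]
                    for ti, rl in enumerate(trials):
                        p = expit(base[pi] + length_offset[len(rl)])
                        outcome = rng.random(len(rl)) < p
                        response = [
                            d if ok else _wrong_digit(d, rng)
                            for d, ok in zip(rl.items, outcome)
                        ]
                        records.append(_record(participant, kind, cond, ti,
                                               _fmt_digits(rl.items),
                                               _fmt_digits(response),
                                               len(rl), int(outcome.sum())))
                elif kind == "word":
                    trials = word_blocks[cond]
                    for ti, rl in enumerate(trials):
                        p = expit(base[pi] + length_offset[len(rl)])
                        outcome = rng.random(3 * len(rl)) < p
                        response = []
                        for wi, word in enumerate(rl.items):
                            phonemes = tuple(
                                ph if outcome[3 * wi + j] else _wrong_phoneme(ph, j, rng)
                                for j, ph in enumerate(word.phonemes)
                            )
                            response.append(phonemes)
                        records.append(_record(
                            participant, kind, cond, ti,
                            _fmt_words([w.phonemes for w in rl.items]),
                            _fmt_words(response),
                            3 * len(rl), int(outcome.sum()),
                        ))
                else:
                    p = expit(base[pi])
                    kw_index = 0
                    for ti, count in enumerate(keyword_counts):
                        keywords = [f"kw{cond}_{kw_index + k:03d}" for k in range(count)]
                        kw_index += count
                        outcome = rng.random(count) < p
                        response = [kw for kw, ok in zip(keywords, outcome) if ok]
                        records.append(_record(participant, kind, cond, ti,
                                               "|".join(keywords),
                                               "|".join(response),
                                               count, int(outcome.sum())))
    return pd.DataFrame.from_records(records)


def _record(participant, kind, cond, trial, target, response, n_slots, n_correct):
    return {"participant": participant, "kind": kind, "condition": cond,
            "trial": trial, "target": target, "response": response,
            "n_slots": n_slots, "n_correct": n_correct}


def _fmt_digits(digits) -> str:
    return "|".join(str(d) for d in digits)


def _fmt_words(words) -> str:
    return "|".join(".".join(phonemes) for phonemes in words)


def _wrong_digit(digit: int, rng: np.random.Generator) -> int:
    choices = [d for d in range(1, 10) if d != digit]
    return int(choices[rng.integers(0, len(choices))])


def _wrong_phoneme(phoneme: str, position: int, rng: np.random.Generator) -> str:
    from .lists import FINAL_CONSONANTS, INITIAL_CONSONANTS, VOWELS

    pools = (INITIAL_CONSONANTS, VOWELS, FINAL_CONSONANTS)
    choices = [p for p in pools[position] if p != phoneme]
    return str(choices[rng.integers(0, len(choices))])


# ---------------------------------------------------------------------------
# reaction times

RT_CONDITIONS = (
    ("colorshape", "repeat"),
    ("colorshape", "switch"),
    ("stroop", "neutral"),
    ("stroop", "congruent"),
    ("stroop", "incongruent"),
)


def simulate_rt_trials(
    cohort: Cohort, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-trial reaction times for the color–shape and Stroop tasks.

    RT = Normal(μ + speed shift + condition cost, σ) + Exponential(τ), 80
    trials per condition per participant. A small contaminant fraction is
    replaced by uniform draws far above the bulk (mean + 5–10 SD) so that
    iterative trimming has work to do. Each trial carries a ``correct``
    flag; incorrect trials are meant to be discarded before RT analysis.
    Columns: participant, task, condition, trial, rt_ms, correct.
    """
    n_trials = config.rt_trials_per_condition
    switch_cost = rng.normal(config.switch_cost_mean, config.switch_cost_sd, cohort.n)
    incong_cost = rng.normal(config.incongruent_cost_mean,
                             config.incongruent_cost_sd, cohort.n)
    cong_offset = rng.normal(config.congruent_offset_mean,
                             config.congruent_offset_sd, cohort.n)
    frames = []
    for task, condition in RT_CONDITIONS:
        if task == "colorshape":
            mu0, sigma, tau = (config.colorshape_mu, config.colorshape_sigma,
                               config.colorshape_tau)
            cost = switch_cost if condition == "switch" else np.zeros(cohort.n)
        else:
            mu0, sigma, tau = config.stroop_mu, config.stroop_sigma, config.stroop_tau
            cost = {"neutral": np.zeros(cohort.n),
                    "congruent": cong_offset,
                    "incongruent": incong_cost}[condition]
        mu = mu0 + config.speed_slope_ms * cohort.speed + cost
        gauss = rng.normal(mu[:, None], sigma, size=(cohort.n, n_trials))
        tail = rng.exponential(tau, size=(cohort.n, n_trials))
        rts = gauss + tail
        theo_mean = mu[:, None] + tau
        theo_sd = float(np.hypot(sigma, tau))
        contaminate = rng.random((cohort.n, n_trials)) < config.contaminant_rate
        rts = np.where(
            contaminate,
            theo_mean + rng.uniform(5 * theo_sd, 10 * theo_sd, size=rts.shape),
            rts,
        )
        rts = np.maximum(rts, 150.0)  # physiological floor
        correct = rng.random((cohort.n, n_trials)) < config.rt_accuracy
        frames.append(pd.DataFrame({
            "participant": np.repeat(cohort.participants, n_trials),
            "task": task,
            "condition": condition,
            "trial": np.tile(np.arange(n_trials), cohort.n),
            "rt_ms": rts.ravel(),
            "correct": correct.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
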