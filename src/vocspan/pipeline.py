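"""The individual-differences analysis chain, end to end.

Takes trial-level tables (recall/sentence trials, RT trials) and a
participant covariate table, and produces the full analysis bundle:

1. re-score every trial from its target/response item sequences;
2. aggregate to a participant × (task, condition) accuracy table;
3. PCA composites — sentence recognition across the three spectral
   resolutions (first component = composite sentence score) and serial
   recall across the six stimulus × resolution cells (component 1 =
   overall serial recall ability, component 2 = vocoder sensitivity,
   retained by prior-findings override despite its eigenvalue < 1);
4. correlation tables with explicit Bonferroni families: serial accuracy
   vs sentence accuracy in matched conditions (family 6), the two serial
   components vs the three resolutions + composite (family 8), pairwise
   cross-resolution sentence correlations (Pearson), serial ability vs
   the reasoning index;
5. reaction-time analysis: incorrect trials dropped, iterative 4-SD
   trimming, geometric-mean condition costs (switch; Stroop incongruent
   vs neutral/congruent), Wilcoxon signed-rank Z on the paired costs, and
   per-participant ex-Gaussian fits whose parameters (mean RT, μ, σ, τ,
   averaged over all five task conditions) feed the attention correlation
   tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring, stats
from .cohort import accuracy_column
from .stats import CompositeModel, RTFit

__all__ = [
    "AnalysisBundle",
    "score_trial_table",
    "accuracy_table_from_trials",
    "rt_condition_stats",
    "rt_costs",
    "analyze_study",
]

SENTENCE_CONDITIONS = ("16", "8", "4")


def replicate_study(
    config=None,
    base_seed: int = 0,
    n_reps: int = 100,
    rt: bool = True,
) -> pd.DataFrame:
    """Monte-Carlo replicates of the study's headline statistics.

    Each replicate draws a fresh cohort at the configured sample size,
    simulates slot-level accuracies (binomially, the same generative model
    as the trial-level path) and reaction times, and records the group
    statistics the analysis reports: condition accuracy means/SDs, PCA
    eigenvalues, the serial-vs-sentence composite correlation, the
    serial-vs-reasoning correlation, the true-vs-recovered ability
    correlation, and the geometric-mean RT condition costs with their
    Wilcoxon Z. One row per replicate.
    """
    from scipy.stats import spearmanr

    from . import cohort as cohort_mod

    config = config or cohort_mod.CohortConfig()
    rows = []
    master = np.random.default_rng(base_seed)
    for streams in master.spawn(n_reps):
        sub = streams.spawn(3)
        people = cohort_mod.sample_cohort(config, sub[0])
        acc = cohort_mod.simulate_accuracy_table(people, config, sub[1])
        sent_cols = [accuracy_column("sentence", c) for c in config.conditions]
        ser_cols = [accuracy_column(k, c)
                    for k in ("digit", "word") for c in config.conditions]
        sent_pca = stats.pca_composite(acc[sent_cols])
        ser_pca = stats.pca_composite(acc[ser_cols], retain=(0, 1))
        reasoning = (config.reasoning_mean
                     + config.reasoning_sd * people.reasoning).round()
        row = {
            **{f"mean_{c}": acc[c].mean() for c in acc.columns},
            **{f"sd_{c}": acc[c].std(ddof=1) for c in acc.columns},
            "sentence_eig1": sent_pca.eigenvalues[0],
            "sentence_var1": sent_pca.variance_explained[0],
            "serial_eig1": ser_pca.eigenvalues[0],
            "serial_var1": ser_pca.variance_explained[0],
            "composite_rho": spearmanr(ser_pca.scores[:, 0],
                                       sent_pca.scores[:, 0]).statistic,
            "reasoning_rho": spearmanr(ser_pca.scores[:, 0],
                                       reasoning).statistic,
            "ability_recovery_r": float(np.corrcoef(
                people.serial_ability, ser_pca.scores[:, 0])[0, 1]),
        }
        if rt:
            rt_trials = cohort_mod.simulate_rt_trials(people, config, sub[2])
            costs = rt_costs(rt_condition_stats(rt_trials, fit=False))
            for name in ("switch_cost", "stroop_incongruent_neutral",
                         "stroop_incongruent_congruent"):
                vec = costs[name].to_numpy()
                z, _ = stats.wilcoxon_signed_rank(vec, np.zeros_like(vec))
                row[f"median_{name}"] = float(np.median(vec))
                row[f"z_{name}"] = z
        rows.append(row)
    return pd.DataFrame(rows)


def _parse_items(kind: str, text: str) -> list:
    if text == "":
        return []
    items = text.split("|")
    if kind == "digit":
        return [int(d) for d in items]
    if kind == "word":
        return [tuple(word.split(".")) for word in items]
    return items


def score_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Re-score every trial from its target and response sequences.

    Returns a copy with ``n_slots``/``n_correct`` recomputed by the
    scoring rules for the trial's kind (serial positions for digits,
    phoneme slots for words, order-free key words for sentences).
    """
    out = trials.copy()
    n_slots = np.empty(len(trials), dtype=int)
    n_correct = np.empty(len(trials), dtype=int)
    for row_idx, row in enumerate(trials.itertuples(index=False)):
        target = _parse_items(row.kind, row.target)
        response = _parse_items(row.kind, row.response)
        if row.kind == "digit":
            score = scoring.score_serial_positions(target, response)
        elif row.kind == "word":
            score = scoring.score_word_phonemes(target, response)
        elif row.kind == "sentence":
            score = scoring.score_keywords(target, response)
        else:
            raise ValueError(f"unknown trial kind {row.kind!r}")
        n_slots[row_idx] = score.n_slots
        n_correct[row_idx] = score.n_correct
    out["n_slots"] = n_slots
    out["n_correct"] = n_correct
    return out


def accuracy_table_from_trials(trials: pd.DataFrame,
                               weighting: str = "pooled") -> pd.DataFrame:
    """Participant × (kind, condition) accuracy table from scored trials."""
    rows: dict[str, dict[str, float]] = {}
    for (participant, kind, condition), group in trials.groupby(
            ["participant", "kind", "condition"], sort=False):
        summary = scoring.aggregate_condition_accuracy(
            (scoring.TrialScore(int(s), int(c))
             for s, c in zip(group["n_slots"], group["n_correct"])),
            participant=str(participant), condition=str(condition),
            kind=str(kind), weighting=weighting,
        )
        rows.setdefault(str(participant), {})[
            accuracy_column(str(kind), str(condition))] = summary.mean_proportion
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "participant"
    return frame


# ---------------------------------------------------------------------------
# reaction times


def rt_condition_stats(
    rt_trials: pd.DataFrame, fit: bool = True
) -> pd.DataFrame:
    """Per participant × task × condition RT statistics.

    Incorrect trials are discarded, the remainder trimmed iteratively at
    mean + 4 SD, and the geometric mean plus (optionally) maximum-
    likelihood ex-Gaussian parameters computed on the kept set.
    """
    rows = []
    correct = rt_trials[rt_trials["correct"]] if "correct" in rt_trials else rt_trials
    for (participant, task, condition), group in correct.groupby(
            ["participant", "task", "condition"], sort=False):
        kept, n_removed = stats.trim_outliers(group["rt_ms"].to_numpy())
        row = {
            "participant": participant, "task": task, "condition": condition,
            "n_trials": len(group), "n_removed": n_removed,
            "geometric_mean": stats.geometric_mean_rt(kept),
            "mean_rt": float(kept.mean()),
        }
        if fit:
            rt_fit: RTFit = stats.fit_exgaussian(kept, n_removed=n_removed)
            row.update(mu=rt_fit.mu, sigma=rt_fit.sigma, tau=rt_fit.tau,
                       converged=rt_fit.converged)
        rows.append(row)
    return pd.DataFrame(rows)


def rt_costs(condition_stats: pd.DataFrame) -> pd.DataFrame:
    """Per-participant geometric-mean condition costs (wide, ms)."""
    gm = condition_stats.pivot_table(index="participant",
                                     columns=["task", "condition"],
                                     values="geometric_mean")
    out = pd.DataFrame(index=gm.index)
    out["switch_cost"] = gm[("colorshape", "switch")] - gm[("colorshape", "repeat")]
    out["stroop_incongruent_neutral"] = (gm[("stroop", "incongruent")]
                                         - gm[("stroop", "neutral")])
    out["stroop_incongruent_congruent"] = (gm[("stroop", "incongruent")]
                                           - gm[("stroop", "congruent")])
    out["stroop_neutral_congruent"] = (gm[("stroop", "neutral")]
                                       - gm[("stroop", "congruent")])
    return out


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class AnalysisBundle:
    """Everything the analysis computes, as plain DataFrames/objects."""

    accuracy: pd.DataFrame
    sentence_pca: CompositeModel
    serial_pca: CompositeModel
    composite_scores: pd.DataFrame        # sentence composite + serial components
    cross_resolution: pd.DataFrame        # pairwise Pearson between resolutions
    serial_vs_sentence: pd.DataFrame      # matched-condition accuracy correlations
    components_vs_sentence: pd.DataFrame  # serial components vs sentence outcomes
    serial_vs_reasoning: stats.CorrelationCell
    rt_stats: pd.DataFrame | None
    rt_cost_table: pd.DataFrame | None
    cost_tests: pd.DataFrame | None       # median cost + Wilcoxon Z/p per contrast
    attention_vs_sentence: pd.DataFrame | None
    attention_vs_cognition: pd.DataFrame | None
    rt_params_vs_outcomes: pd.DataFrame | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def pca_summary(self, which: str) -> pd.DataFrame:
        model = self.sentence_pca if which == "sentence" else self.serial_pca
        frame = pd.DataFrame(model.loadings,
                             index=model.variables,
                             columns=[f"component_{i + 1}"
                                      for i in range(model.loadings.shape[1])])
        frame.loc["eigenvalue"] = model.eigenvalues
        frame.loc["variance_explained"] = model.variance_explained
        return frame


def analyze_study(
    trials: pd.DataFrame,
    covariates: pd.DataFrame,
    rt_trials: pd.DataFrame | None = None,
    rescore: bool = True,
    fit_rt: bool = True,
) -> AnalysisBundle:
    """Run the complete analysis on trial-level and covariate tables."""
    if rescore:
        trials = score_trial_table(trials)
    accuracy = accuracy_table_from_trials(trials)

    sentence_cols = [accuracy_column("sentence", c) for c in SENTENCE_CONDITIONS]
    serial_cols = [accuracy_column(k, c)
                   for k in ("digit", "word") for c in SENTENCE_CONDITIONS]
    sentence_pca = stats.pca_composite(accuracy[sentence_cols])
    serial_pca = stats.pca_composite(accuracy[serial_cols], retain=(0, 1))

    composite = pd.DataFrame({
        "sentence_composite": sentence_pca.scores[:, 0],
        "serial_ability": serial_pca.scores[:, 0],
        "vocoder_sensitivity_score": serial_pca.scores[:, 1],
    }, index=accuracy.index)

    # pairwise Pearson correlations of sentence accuracy across resolutions
    cross_cells = []
    for i in range(3):
        for j in range(i + 1, 3):
            cross_cells.append(stats.correlate(
                accuracy[sentence_cols[i]], accuracy[sentence_cols[j]],
                method="pearson", family_size=3,
                x_name=sentence_cols[i], y_name=sentence_cols[j]))
    cross_resolution = stats.correlation_table_frame(cross_cells)

    # serial accuracy vs sentence accuracy in matched conditions (family 6)
    matched_cells = [
        stats.correlate(
            accuracy[accuracy_column(kind, cond)],
            accuracy[accuracy_column("sentence", cond)],
            method="spearman", family_size=6,
            x_name=accuracy_column(kind, cond),
            y_name=accuracy_column("sentence", cond))
        for kind in ("digit", "word") for cond in SENTENCE_CONDITIONS
    ]
    serial_vs_sentence = stats.correlation_table_frame(matched_cells)

    # serial components vs sentence outcomes (3 resolutions + composite, family 8)
    outcome_frame = pd.concat(
        [accuracy[sentence_cols], composite[["sentence_composite"]]], axis=1)
    component_cells = [
        stats.correlate(composite[comp], outcome_frame[outcome],
                        method="spearman", family_size=8,
                        x_name=comp, y_name=outcome)
        for comp in ("serial_ability", "vocoder_sensitivity_score")
        for outcome in outcome_frame.columns
    ]
    components_vs_sentence = stats.correlation_table_frame(component_cells)

    merged = composite.join(covariates, how="inner")
    serial_vs_reasoning = stats.correlate(
        merged["serial_ability"], merged["reasoning_pri"],
        method="spearman", family_size=1,
        x_name="serial_ability", y_name="reasoning_pri")

    rt_stats_df = rt_cost_table = cost_tests = None
    attention_vs_sentence = attention_vs_cognition = rt_params_vs_outcomes = None
    if rt_trials is not None:
        rt_stats_df = rt_condition_stats(rt_trials, fit=fit_rt)
        rt_cost_table = rt_costs(rt_stats_df)
        contrasts = []
        for name in ("switch_cost", "stroop_incongruent_neutral",
                     "stroop_incongruent_congruent", "stroop_neutral_congruent"):
            costs = rt_cost_table[name].to_numpy()
            z, p = stats.wilcoxon_signed_rank(costs, np.zeros_like(costs))
            contrasts.append({"contrast": name,
                              "median_cost_ms": float(np.median(costs)),
                              "wilcoxon_z": z, "p": p})
        cost_tests = pd.DataFrame(contrasts).set_index("contrast")

        attention = rt_cost_table[["switch_cost", "stroop_incongruent_congruent",
                                   "stroop_incongruent_neutral"]].join(
            covariates[["tova_rt_cns", "tova_var_cns",
                        "tova_com_cns", "tova_omi_cns"]], how="inner")
        attention_outcomes = outcome_frame
        data3 = attention.join(attention_outcomes, how="inner")
        predictors3 = list(attention.columns)
        attention_vs_sentence = stats.correlation_table_frame(
            stats.build_correlation_tables(
                data3, predictors3, list(attention_outcomes.columns),
                family_size=len(predictors3) * len(attention_outcomes.columns),
                method="spearman"))

        cognition = merged[["reasoning_pri", "serial_ability",
                            "vocoder_sensitivity_score"]]
        data4 = attention.join(cognition, how="inner")
        attention_vs_cognition = stats.correlation_table_frame(
            stats.build_correlation_tables(
                data4, predictors3, list(cognition.columns),
                family_size=len(predictors3) * len(cognition.columns),
                method="spearman"))

        if fit_rt:
            params = rt_stats_df.groupby("participant")[
                ["mean_rt", "mu", "sigma", "tau"]].mean()
            params.columns = ["mean_rt", "mean_mu", "mean_sigma", "mean_tau"]
            outcomes5 = outcome_frame.join(
                merged[["reasoning_pri", "serial_ability",
                        "vocoder_sensitivity_score"]], how="inner")
            data5 = params.join(outcomes5, how="inner")
            rt_params_vs_outcomes = stats.correlation_table_frame(
                stats.build_correlation_tables(
                    data5, list(params.columns), list(outcomes5.columns),
                    family_size=len(params.columns) * len(outcomes5.columns),
                    method="spearman"))

    bundle = AnalysisBundle(
        accuracy=accuracy,
        sentence_pca=sentence_pca,
        serial_pca=serial_pca,
        composite_scores=composite,
        cross_resolution=cross_resolution,
        serial_vs_sentence=serial_vs_sentence,
        components_vs_sentence=components_vs_sentence,
        serial_vs_reasoning=serial_vs_reasoning,
        rt_stats=rt_stats_df,
        rt_cost_table=rt_cost_table,
        cost_tests=cost_tests,
        attention_vs_sentence=attention_vs_sentence,
        attention_vs_cognition=attention_vs_cognition,
        rt_params_vs_outcomes=rt_params_vs_outcomes,
    )
    bundle.tables = {
        "accuracy": accuracy,
        "sentence_pca": bundle.pca_summary("sentence"),
        "serial_pca": bundle.pca_summary("serial"),
        "composite_scores": composite,
        "cross_resolution": cross_resolution,
        "serial_vs_sentence": serial_vs_sentence,
        "components_vs_sentence": components_vs_sentence,
    }
    for name, frame in (("rt_stats", rt_stats_df),
                        ("rt_costs", rt_cost_table),
                        ("cost_tests", cost_tests),
                        ("attention_vs_sentence", attention_vs_sentence),
                        ("attention_vs_cognition", attention_vs_cognition),
                        ("rt_params_vs_outcomes", rt_params_vs_outcomes)):
        if frame is not None:
            bundle.tables[name] = frame
    return bundle
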