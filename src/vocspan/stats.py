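"""Individual-differences statistics for accuracy and reaction-time data.

The analysis chain this module supports:

* **PCA composites.** Accuracy across conditions is highly correlated
  within participants, so a participants × conditions accuracy matrix is
  reduced with principal components analysis of the correlation matrix.
  Components with eigenvalue > 1 are retained by default (Kaiser rule),
  with an explicit override for theory-driven retention. Per-participant
  scores on the first component serve as a single composite ability
  estimate.
* **Correlation cells** (Pearson or Spearman) with explicit Bonferroni
  family sizes — the family is always caller-specified, never inferred.
* **Standard major axis (SMA) regression**, the symmetric line fit
  appropriate when both variables carry error: slope = sign(r)·sd(y)/sd(x).
* **Reaction-time analysis**: iterative upper-tail outlier trimming
  (remove everything above mean + 4 SD, recompute, repeat), geometric mean
  RTs, Wilcoxon signed-rank Z for paired condition costs, and
  maximum-likelihood ex-Gaussian fits. The ex-Gaussian — a Gaussian (μ, σ)
  convolved with an exponential (τ) — is the standard description of RT
  distributions; τ indexes the long slow tail attributed to attentional
  lapses. Its mean is μ + τ and its variance σ² + τ².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "CompositeModel",
    "CorrelationCell",
    "RTFit",
    "pca_composite",
    "correlate",
    "sma_fit",
    "trim_outliers",
    "fit_exgaussian",
    "geometric_mean_rt",
    "wilcoxon_signed_rank",
    "condition_contrasts",
    "build_correlation_tables",
    "correlation_table_frame",
]


# ---------------------------------------------------------------------------
# PCA composites


@dataclass(frozen=True)
class CompositeModel:
    """Correlation-matrix PCA of a participants × conditions table."""

    variables: tuple[str, ...]
    loadings: np.ndarray          # variables × components, unit-norm columns
    eigenvalues: np.ndarray       # non-increasing; sums to n_variables
    variance_explained: np.ndarray
    scores: np.ndarray            # participants × components
    retained: tuple[int, ...]     # component indices with eigenvalue > 1


def pca_composite(
    table: pd.DataFrame | np.ndarray,
    standardize: bool = True,
    retain: tuple[int, ...] | None = None,
) -> CompositeModel:
    """Principal components of the columns' correlation matrix.

    Columns are standardized (mean 0, SD 1, ddof=1) and the correlation
    matrix eigendecomposed. Loadings are unit-norm eigenvectors with sign
    fixed so each component's mean loading is positive; scores are the
    standardized data projected onto them. ``retain`` overrides the
    eigenvalue > 1 rule when prior findings justify keeping a smaller
    component.
    """
    if isinstance(table, pd.DataFrame):
        names = tuple(str(c) for c in table.columns)
        data = table.to_numpy(dtype=float)
    else:
        data = np.asarray(table, dtype=float)
        names = tuple(f"var{i + 1}" for i in range(data.shape[1]))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D table with at least two columns")
    if data.shape[0] <= data.shape[1]:
        raise ValueError("need more rows (participants) than columns")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed; impute or drop upstream")
    sd = data.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise ValueError(f"zero-variance column(s): {[names[i] for i in zero_var]}")
    z = (data - data.mean(axis=0)) / sd if standardize else data - data.mean(axis=0)
    corr = np.corrcoef(data, rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]
    for comp in range(vectors.shape[1]):
        column = vectors[:, comp]
        mean_loading = column.mean()
        if mean_loading < 0 or (mean_loading == 0 and column[np.argmax(np.abs(column))] < 0):
            vectors[:, comp] = -column
    scores = z @ vectors
    retained = retain if retain is not None else tuple(
        int(i) for i in np.flatnonzero(eigenvalues > 1.0)
    )
    return CompositeModel(
        variables=names,
        loadings=vectors,
        eigenvalues=eigenvalues,
        variance_explained=eigenvalues / eigenvalues.sum(),
        scores=scores,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationCell:
    """One predictor × outcome correlation with its Bonferroni context."""

    x_name: str
    y_name: str
    method: str
    coefficient: float
    p_value: float
    n: int
    family_size: int
    missing: bool = False

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / self.family_size

    @property
    def significant_raw(self) -> bool:
        return (not self.missing) and self.p_value < 0.05

    @property
    def significant_bonferroni(self) -> bool:
        return (not self.missing) and self.p_value < self.bonferroni_threshold


def correlate(
    x, y, method: str = "pearson", family_size: int = 1,
    x_name: str = "x", y_name: str = "y",
) -> CorrelationCell:
    """Pearson or Spearman correlation with a two-sided t-approximation p.

    ``family_size`` sets the Bonferroni threshold 0.05 / m recorded on the
    cell; it must be supplied by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed upstream (pairwise deletion)")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        result = sps.pearsonr(x, y)
        coefficient, p_value = float(result.statistic), float(result.pvalue)
    elif method == "spearman":
        coefficient, p_value = (float(v) for v in sps.spearmanr(x, y))
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationCell(
        x_name=x_name, y_name=y_name, method=method,
        coefficient=coefficient, p_value=p_value,
        n=int(x.size), family_size=int(family_size),
    )


def sma_fit(x, y) -> tuple[float, float]:
    """Standard major axis regression: slope = sign(r) · sd(y)/sd(x).

    Symmetric in the sense that fitting y on x and x on y gives reciprocal
    slopes. Requires a nonzero correlation to orient the line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sd_x = x.std(ddof=1)
    sd_y = y.std(ddof=1)
    if sd_x == 0 or sd_y == 0:
        raise ValueError("both variables must be non-constant")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0:
        raise ValueError("zero correlation: SMA slope sign is undefined")
    slope = float(np.sign(r) * sd_y / sd_x)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


# ---------------------------------------------------------------------------
# reaction times


def trim_outliers(rts) -> tuple[np.ndarray, int]:
    """Iteratively remove reaction times above mean + 4 SD.

    All values above the current mean + 4 sample SDs are removed in one
    pass; the mean and SD are recomputed and the process repeats until no
    value exceeds the threshold. Only the upper tail is trimmed — fast
    responses are never removed.
    """
    kept = np.asarray(rts, dtype=float)
    if kept.size < 10:
        raise ValueError("need at least 10 observations to trim")
    n_raw = kept.size
    while True:
        threshold = kept.mean() + 4 * kept.std(ddof=1)
        mask = kept <= threshold
        if mask.all():
            break
        kept = kept[mask]
    return kept, int(n_raw - kept.size)


@dataclass(frozen=True)
class RTFit:
    """Maximum-likelihood ex-Gaussian parameters of a trimmed RT set."""

    n_raw: int
    n_removed: int
    mu: float
    sigma: float
    tau: float
    log_likelihood: float
    converged: bool

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def variance(self) -> float:
        return self.sigma**2 + self.tau**2


_SCALE_FLOOR = 0.5  # ms; lower bound on sigma and tau


def _exgauss_nll(params: np.ndarray, rts: np.ndarray) -> float:
    mu, sigma, tau = params
    logpdf = sps.exponnorm.logpdf(rts, K=tau / sigma, loc=mu, scale=sigma)
    if not np.all(np.isfinite(logpdf)):
        return 1e12
    return -float(logpdf.sum())


def fit_exgaussian(rts, n_removed: int = 0) -> RTFit:
    """Fit an ex-Gaussian distribution to reaction times by maximum likelihood.

    Initialization is moment based: τ₀ = max(cbrt(m₃/2), 1) from the third
    central moment (for an ex-Gaussian m₃ = 2τ³), μ₀ = mean − τ₀,
    σ₀ = sqrt(max(var − τ₀², 1)). The exact log-density is maximized with
    L-BFGS-B under σ, τ ≥ 0.5 ms. Non-convergence is flagged on the result,
    not raised.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 50:
        raise ValueError("need at least 50 observations for a stable fit")
    if np.any(rts <= 0):
        raise ValueError("reaction times must be positive")
    mean = rts.mean()
    variance = rts.var(ddof=1)
    m3 = float(np.mean((rts - mean) ** 3))
    tau0 = max(np.cbrt(max(m3, 0.0) / 2.0), 1.0)
    mu0 = mean - tau0
    sigma0 = np.sqrt(max(variance - tau0**2, 1.0))
    x0 = np.array([mu0, max(sigma0, _SCALE_FLOOR), max(tau0, _SCALE_FLOOR)])
    result = optimize.minimize(
        _exgauss_nll, x0, args=(rts,), method="L-BFGS-B",
        bounds=[(None, None), (_SCALE_FLOOR, None), (_SCALE_FLOOR, None)],
    )
    mu, sigma, tau = result.x
    return RTFit(
        n_raw=int(rts.size + n_removed), n_removed=int(n_removed),
        mu=float(mu), sigma=float(sigma), tau=float(tau),
        log_likelihood=-float(result.fun), converged=bool(result.success),
    )


def geometric_mean_rt(rts) -> float:
    """Geometric mean exp(mean(log RT)); requires strictly positive values."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("empty input")
    if np.any(rts <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(rts))))


def wilcoxon_signed_rank(
    x_paired, y_paired, continuity: bool = True
) -> tuple[float, float]:
    """Wilcoxon signed-rank Z (normal approximation) and two-sided p.

    Zero differences are dropped (classic handling); tied absolute
    differences get average ranks and the normal variance carries the
    standard tie correction Σ(t³ − t)/48. A continuity correction of 0.5
    is applied by default — it keeps the normal approximation within a few
    hundredths of the exact permutation p even at small n. Z is positive
    when x tends to exceed y.
    """
    x = np.asarray(x_paired, dtype=float)
    y = np.asarray(y_paired, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    diffs = x - y
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n < 6:
        raise ValueError("need at least 6 nonzero paired differences")
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mean_w = n * (n + 1) / 4.0
    variance = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    variance -= ((tie_counts**3 - tie_counts) / 48.0).sum()
    deviation = w_plus - mean_w
    if continuity:
        magnitude = max(abs(deviation) - 0.5, 0.0)
    else:
        magnitude = abs(deviation)
    z = np.sign(deviation) * magnitude / np.sqrt(variance)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# condition contrasts and correlation tables


def condition_contrasts(
    table: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Within-participant condition means and paired contrasts.

    ``table`` is wide: one row per participant, one column per condition,
    with complete data (every participant in every condition — a balanced
    design, in which fixed-effect condition estimates equal condition
    means). Each non-reference condition is contrasted against
    ``reference`` with a paired t test.

    Returns a frame indexed by condition with columns ``mean``,
    ``mean_diff`` (condition − reference), ``t`` and ``p``.
    """
    if table.isna().any().any():
        raise ValueError(
            "unbalanced data: every participant needs every condition; "
            "drop incomplete participants before contrasting"
        )
    if reference not in table.columns:
        raise ValueError(f"reference condition {reference!r} not in table")
    rows = []
    ref_values = table[reference].to_numpy(dtype=float)
    for condition in table.columns:
        values = table[condition].to_numpy(dtype=float)
        if condition == reference:
            t_stat, p_value, diff = np.nan, np.nan, 0.0
        else:
            diff = float(values.mean() - ref_values.mean())
            if np.allclose(values, ref_values):
                t_stat, p_value = 0.0, 1.0
            else:
                res = sps.ttest_rel(values, ref_values)
                t_stat, p_value = float(res.statistic), float(res.pvalue)
        rows.append({"condition": condition, "mean": float(values.mean()),
                     "mean_diff": diff, "t": t_stat, "p": p_value})
    return pd.DataFrame(rows).set_index("condition")


def build_correlation_tables(
    data: pd.DataFrame,
    predictors: list[str],
    outcomes: list[str],
    family_size: int,
    method: str = "spearman",
) -> list[CorrelationCell]:
    """The full predictor × outcome grid of correlation cells.

    Pairwise deletion is applied per cell; cells left with fewer than 3
    complete pairs are flagged missing rather than computed. The Bonferroni
    ``family_size`` must be given explicitly.
    """
    cells: list[CorrelationCell] = []
    for predictor in predictors:
        for outcome in outcomes:
            pair = data[[predictor, outcome]].dropna()
            if len(pair) < 3:
                cells.append(CorrelationCell(
                    x_name=predictor, y_name=outcome, method=method,
                    coefficient=np.nan, p_value=np.nan, n=len(pair),
                    family_size=family_size, missing=True,
                ))
                continue
            cells.append(correlate(
                pair[predictor], pair[outcome], method=method,
                family_size=family_size, x_name=predictor, y_name=outcome,
            ))
    return cells


def correlation_table_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    """Long-format DataFrame view of a list of correlation cells."""
    return pd.DataFrame([
        {
            "predictor": c.x_name, "outcome": c.y_name, "method": c.method,
            "coefficient": c.coefficient, "p_value": c.p_value, "n": c.n,
            "family_size": c.family_size,
            "significant_raw": c.significant_raw,
            "significant_bonferroni": c.significant_bonferroni,
            "missing": c.missing,
        }
        for c in cells
    ])
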