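"""Cohort statistics: eligibility filtering, baseline comparison,
covariate-adjusted group models, ROC analysis and post hoc power.

The adjusted group comparison is an ordinary least-squares fit of each OCTA
metric on group indicators (control as reference) plus covariates; adjusted
group means are estimated-marginal-means style predictions at the pooled
sample-mean covariate profile, so the group coefficient equals the adjusted
mean difference exactly.  AUCs use the rank (Mann-Whitney) formulation with
ties counted 1/2, and paired AUC differences are tested with the DeLong
structural-components covariance.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AdjustedModelResult",
    "RocResult",
    "PowerInputs",
    "DEFAULT_COVARIATES",
    "apply_eligibility_filters",
    "select_analysis_eye",
    "baseline_comparison",
    "fit_adjusted_model",
    "bonferroni_threshold",
    "roc_auc",
    "roc_curve_points",
    "sensitivity_at_specificity",
    "compare_auc_paired",
    "posthoc_power",
]

#: covariate set of the adjusted models: demographics, diabetes, blood
#: pressure (systolic and diastolic) and scan signal strength
DEFAULT_COVARIATES = ["age", "female", "chinese", "diabetes", "sbp", "dbp", "signal_strength"]

GROUPS = ("AD", "MCI", "control")

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eligibility and eye selection

_EXCLUSION_ORDER = ("fatigue", "quality", "eye_disease")


def apply_eligibility_filters(
    enrolled: pd.DataFrame, quality_threshold: float = 7.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter an enrollment roster down to analyzable participants.

    A participant is excluded when any exclusion flag is set or when every
    scanned eye fails quality (signal strength below ``quality_threshold``).
    Exclusion reasons are tallied with fixed precedence fatigue -> quality ->
    eye disease (the first matching reason is the one counted).

    ``enrolled`` needs boolean columns ``fatigue`` and ``eye_disease`` and
    per-eye ``signal_strength_od`` / ``signal_strength_os`` columns (NaN for
    an unscanned eye).
    """
    required = ["fatigue", "eye_disease", "signal_strength_od", "signal_strength_os"]
    missing = [c for c in required if c not in enrolled.columns]
    if missing:
        raise ValueError(f"enrollment table is missing flag column(s): {missing}")

    ss = enrolled[["signal_strength_od", "signal_strength_os"]].to_numpy(dtype=float)
    scanned = ~np.isnan(ss)
    good = scanned & (ss >= quality_threshold)
    quality_fail = ~good.any(axis=1)

    tally = {k: 0 for k in _EXCLUSION_ORDER}
    keep = np.ones(len(enrolled), dtype=bool)
    for i in range(len(enrolled)):
        if bool(enrolled["fatigue"].iloc[i]):
            tally["fatigue"] += 1
            keep[i] = False
        elif quality_fail[i]:
            tally["quality"] += 1
            keep[i] = False
        elif bool(enrolled["eye_disease"].iloc[i]):
            tally["eye_disease"] += 1
            keep[i] = False
    return enrolled.loc[keep].reset_index(drop=True), tally


def select_analysis_eye(
    participant_id: str, eligible_eyes: list[str], seed: int = 0
) -> str:
    """Pick the analysis eye uniformly among a participant's eligible eyes.

    Deterministic per (participant, seed): the participant id is hashed into
    the stream so distinct participants draw independently under one seed.
    """
    if not eligible_eyes:
        raise ValueError(f"participant {participant_id!r} has no eligible eye")
    if len(eligible_eyes) == 1:
        return eligible_eyes[0]
    stream = (int(seed) + zlib.crc32(str(participant_id).encode())) % (2**31)
    rng = np.random.default_rng(stream)
    return eligible_eyes[int(rng.integers(len(eligible_eyes)))]


# ---------------------------------------------------------------------------
# baseline table


def baseline_comparison(
    cohort: pd.DataFrame, variable: str, kind: str = "auto", group_col: str = "group"
) -> tuple[float, float]:
    """Compare a baseline characteristic across groups.

    Continuous variables get a one-way ANOVA (F, p); categorical variables a
    Pearson chi-square on the group-by-level contingency table.  A constant
    continuous variable returns (0.0, 1.0) rather than raising.
    """
    if variable not in cohort.columns:
        raise ValueError(f"no column {variable!r} in cohort table")
    groups = [g.dropna().to_numpy() for _, g in cohort.groupby(group_col)[variable]]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    values = cohort[variable].dropna()
    if kind == "auto":
        kind = "categorical" if values.nunique() <= 4 else "continuous"
    if kind == "continuous":
        if any(len(g) < 2 for g in groups):
            raise ValueError("each group needs at least 2 observations for ANOVA")
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            return 0.0, 1.0
        f, p = sps.f_oneway(*groups)
        if not np.isfinite(f):
            return 0.0, 1.0
        return float(f), float(p)
    table = pd.crosstab(cohort[group_col], cohort[variable])
    if (table.to_numpy().sum(axis=0) == 0).any() or table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# adjusted models


@dataclass
class AdjustedModelResult:
    """Covariate-adjusted group comparison for one outcome metric."""

    outcome: str
    groups: list[str]
    beta: dict[str, float]  # per non-reference group
    ci: dict[str, tuple[float, float]]
    p_value: dict[str, float]
    adjusted_mean: dict[str, float]  # per group incl. reference
    adjusted_se: dict[str, float]  # model-based SE of the adjusted mean
    raw_sd: dict[str, float]  # plain within-group SD of the outcome
    covariate_coefs: dict[str, float]
    n: int
    residual_scale: float

    def to_row_frame(self) -> pd.DataFrame:
        """Publication-style rows: group, adjusted mean, beta, CI, p."""
        rows = []
        for g in self.groups:
            rows.append(
                {
                    "outcome": self.outcome,
                    "group": g,
                    "adjusted_mean": self.adjusted_mean[g],
                    "raw_sd": self.raw_sd[g],
                    "beta": self.beta.get(g, 0.0) if g in self.beta else np.nan,
                    "ci_low": self.ci[g][0] if g in self.ci else np.nan,
                    "ci_high": self.ci[g][1] if g in self.ci else np.nan,
                    "p_value": self.p_value.get(g, np.nan),
                }
            )
        return pd.DataFrame(rows)


def fit_adjusted_model(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    group_col: str = "group",
    reference: str = "control",
    alpha: float = 0.05,
) -> AdjustedModelResult:
    """Multivariable linear regression of an outcome on group plus covariates.

    Group enters as indicator variables with ``reference`` as the baseline
    level.  Adjusted group means are predictions at the pooled sample-mean
    covariate vector, so ``adjusted_mean[g] - adjusted_mean[reference]``
    equals the group coefficient exactly.  CIs and two-sided p-values come
    from the t distribution of the fit.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in cohort.columns]
    missing = [c for c in [outcome, group_col, *covariates] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {missing}")

    df = cohort[[outcome, group_col, *covariates]].dropna().reset_index(drop=True)
    constant = [c for c in covariates if df[c].nunique() <= 1]
    if constant:
        # a constant covariate carries no adjustment information and would
        # alias the intercept
        logger.warning("dropping constant covariate(s): %s", constant)
        covariates = [c for c in covariates if c not in constant]
    levels = list(pd.unique(df[group_col]))
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    others = [g for g in levels if g != reference]

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for g in others:
        X[f"group[{g}]"] = (df[group_col] == g).astype(float)
    for c in covariates:
        X[c] = df[c].astype(float)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        cols = X.columns.tolist()
        for j in range(1, X.shape[1]):
            sub = X.iloc[:, : j + 1].to_numpy()
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")

    res = sm.OLS(df[outcome].astype(float), X).fit()
    conf = res.conf_int(alpha=alpha)

    # adjusted means: prediction at pooled covariate means per group
    xbar = {c: float(df[c].astype(float).mean()) for c in covariates}
    adjusted_mean, adjusted_se = {}, {}
    for g in levels:
        row = pd.DataFrame(
            [
                {
                    "const": 1.0,
                    **{f"group[{h}]": 1.0 if h == g else 0.0 for h in others},
                    **xbar,
                }
            ]
        )[X.columns]
        pred = res.get_prediction(row)
        adjusted_mean[g] = float(pred.predicted_mean[0])
        adjusted_se[g] = float(pred.se_mean[0])

    beta = {g: float(res.params[f"group[{g}]"]) for g in others}
    ci = {
        g: (float(conf.loc[f"group[{g}]", 0]), float(conf.loc[f"group[{g}]", 1]))
        for g in others
    }
    p_value = {g: float(res.pvalues[f"group[{g}]"]) for g in others}
    raw_sd = {g: float(df.loc[df[group_col] == g, outcome].std(ddof=1)) for g in levels}
    covariate_coefs = {c: float(res.params[c]) for c in covariates}

    order = [reference] + others
    return AdjustedModelResult(
        outcome=outcome,
        groups=order,
        beta=beta,
        ci=ci,
        p_value=p_value,
        adjusted_mean=adjusted_mean,
        adjusted_se=adjusted_se,
        raw_sd=raw_sd,
        covariate_coefs=covariate_coefs,
        n=len(df),
        residual_scale=float(np.sqrt(res.scale)),
    )


def bonferroni_threshold(alpha: float, k_outcomes: int) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k_outcomes < 1:
        raise ValueError("k_outcomes must be at least 1")
    return alpha / k_outcomes


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    n_cases: int
    n_controls: int
    sensitivity_at_specificity: dict[float, float] = field(default_factory=dict)
    below_chance: bool = False


def _check_roc_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> RocResult:
    """AUC by the rank (Mann-Whitney) formulation with ties counted 1/2.

    The orientation of the scores is reported as-is: an AUC below 0.5 means
    the marker ranks cases *lower* than controls (flagged, never flipped).
    """
    scores, labels = _check_roc_inputs(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    auc = (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    return RocResult(
        auc=float(auc),
        n_cases=len(pos),
        n_controls=len(neg),
        below_chance=bool(auc < 0.5),
    )


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC vertices (FPR, TPR) sweeping the threshold from high to low."""
    scores, labels = _check_roc_inputs(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep only the last index of each distinct score (tie groups collapse)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def sensitivity_at_specificity(scores, labels, specificity: float = 0.415) -> float:
    """Sensitivity at a fixed specificity, linearly interpolated on the ROC."""
    if not 0 <= specificity <= 1:
        raise ValueError("specificity must lie in [0, 1]")
    fpr, tpr = roc_curve_points(scores, labels)
    target_fpr = 1.0 - specificity
    return float(np.interp(target_fpr, fpr, tpr))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus its structural components V10 (per case) and V01 (per control)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(auc), v10, v01


def compare_auc_paired(marker_a, marker_b, labels) -> tuple[float, float]:
    """DeLong paired test of two markers' AUCs on the same subjects.

    Returns ``(auc_a - auc_b, two-sided p)``.  A marker compared against
    itself has zero-variance difference and returns (0.0, 1.0) by convention.
    """
    a, labels = _check_roc_inputs(marker_a, labels)
    b, _ = _check_roc_inputs(marker_b, labels)
    auc_a, v10_a, v01_a = _delong_components(a, labels)
    auc_b, v10_b, v01_b = _delong_components(b, labels)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 1e-15:
        return (0.0, 1.0) if abs(delta) < 1e-12 else (float(delta), 0.0)
    z = delta / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# power


@dataclass
class PowerInputs:
    """Two-sample comparison summary for a post hoc power calculation."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 observations")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def posthoc_power(inputs: PowerInputs) -> float:
    """Post hoc power of a two-sample unequal-variance comparison.

    Normal approximation: power = Phi(|delta| / se - z_{1-alpha/2}) with
    se = sqrt(sd1^2/n1 + sd2^2/n2).  At delta = 0 this equals alpha/2, the
    one-sided rejection probability in the favored direction.
    """
    se = np.sqrt(inputs.sd1**2 / inputs.n1 + inputs.sd2**2 / inputs.n2)
    z_crit = sps.norm.ppf(1.0 - inputs.alpha / 2.0)
    delta = abs(inputs.mean1 - inputs.mean2)
    return float(sps.norm.cdf(delta / se - z_crit))
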