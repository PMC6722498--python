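"""Multivariate logistic prediction of below-cutoff metabolic ratio.

The modeling pipeline mirrors the study's two preselection approaches:

1. forward stepwise logistic regression (likelihood-ratio entry test,
   entry p < 0.05) over the candidate predictors — SNP minor-allele dosages
   coded additively plus, in Approach 1, the binary CYP2D6 impaired
   indicator;
2. ranking of the selected variables by the -2 log-likelihood of the model
   refit without each variable (largest degradation = rank 1);
3. cumulative Nagelkerke pseudo-R^2 and ROC AUC along the ranked order;
4. a model-building gate that retains a ranked variable only when it raises
   the AUC by at least 0.005 (the first variable is compared against the
   0.5 chance baseline);
5. 10-fold cross-validated AUC, sensitivity, specificity, PPV and NPV of
   the final variable set, reported as the mean of the per-fold values
   (pooled out-of-fold confusion counts are reported alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold


class ModelError(ValueError):
    """Invalid input to a modeling operation."""


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class ModelDataset:
    """Complete-case predictors and the binary below-cutoff MR outcome."""

    predictors: pd.DataFrame  # numeric candidate predictors, one column each
    outcome: np.ndarray  # bool, True = MR below cutoff
    n_dropped_incomplete: int = 0

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=bool)
        if len(self.predictors) != self.outcome.size:
            raise ModelError("predictors and outcome length mismatch")
        if self.outcome.all() or not self.outcome.any():
            raise ModelError("outcome is constant; cannot model")
        if self.predictors.isna().any().any():
            raise ModelError("predictors contain missing values after complete-case masking")

    @classmethod
    def complete_cases(cls, predictors: pd.DataFrame, outcome) -> "ModelDataset":
        """Keep only samples with no missing predictor values."""
        outcome = np.asarray(outcome, dtype=bool)
        mask = ~predictors.isna().any(axis=1).to_numpy()
        return cls(
            predictors.loc[mask].reset_index(drop=True),
            outcome[mask],
            n_dropped_incomplete=int((~mask).sum()),
        )

    @property
    def n(self) -> int:
        return self.outcome.size


# ---------------------------------------------------------------------------
# Logistic regression (statsmodels backend)


@dataclass
class LogisticFit:
    variables: list[str]
    coefficients: np.ndarray  # aligned with variables
    intercept: float
    log_likelihood: float
    n: int
    converged: bool
    separation: bool = False
    bse: np.ndarray | None = None

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        """Predicted below-cutoff probabilities."""
        eta = self.intercept + (
            predictors[self.variables].to_numpy(dtype=float) @ self.coefficients
            if self.variables
            else 0.0
        )
        return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def fit_logistic(predictors: pd.DataFrame | None, outcome) -> LogisticFit:
    """Maximum-likelihood logistic fit of the outcome on the predictors.

    ``predictors`` may be None/empty for the intercept-only (null) model.
    Quasi-separated fits are flagged rather than raised: Newton iterations
    are capped and the fit refreshed with a damped optimiser.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size == 0 or not ((y == 0).any() and (y == 1).any()):
        raise ModelError("outcome must contain at least one case and one control")
    if predictors is None or predictors.shape[1] == 0:
        names: list[str] = []
        x = np.ones((y.size, 1))
    else:
        if len(predictors) != y.size:
            raise ModelError("predictors and outcome length mismatch")
        names = list(predictors.columns)
        x = sm.add_constant(predictors.to_numpy(dtype=float), prepend=True, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, x)
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        except Exception:  # singular Hessian / perfect separation
            separation = True
            res = model.fit(disp=0, method="bfgs", maxiter=200)
    params = np.asarray(res.params, dtype=float)
    if not separation and np.abs(params).max(initial=0.0) > 25:
        separation = True  # quasi-separation: coefficients running away
    return LogisticFit(
        variables=names,
        coefficients=params[1:],
        intercept=float(params[0]),
        log_likelihood=float(res.llf),
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        bse=np.asarray(res.bse, dtype=float),
    )


def likelihood_ratio_p(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    """Two-sided p of the LR chi-square for nested logistic models."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(stat, df=df))


# ---------------------------------------------------------------------------
# Selection and ranking


def forward_stepwise(
    candidates: pd.DataFrame, outcome, entry_p: float = 0.05
) -> list[tuple[str, float]]:
    """Forward selection by likelihood-ratio entry test.

    At each step the candidate with the smallest LR p-value against the
    current model enters, provided that p < ``entry_p``; ties break toward
    the earlier candidate column. Returns (variable, entry p) in selection
    order; may be empty.
    """
    if candidates.shape[1] == 0:
        raise ModelError("forward selection needs at least one candidate")
    selected: list[tuple[str, float]] = []
    current = fit_logistic(None, outcome)
    remaining = list(candidates.columns)
    while remaining:
        best_name, best_p, best_fit = None, np.inf, None
        for name in remaining:
            trial = fit_logistic(candidates[[v for v, _ in selected] + [name]], outcome)
            p = likelihood_ratio_p(trial.log_likelihood, current.log_likelihood)
            if p < best_p:  # strict: ties keep the earlier candidate
                best_name, best_p, best_fit = name, p, trial
        if best_name is None or best_p >= entry_p:
            break
        selected.append((best_name, best_p))
        remaining.remove(best_name)
        current = best_fit
    return selected


def rank_variables(selected: list[str], dataset: ModelDataset) -> pd.DataFrame:
    """Rank selected variables by the -2 LL of the model omitting each one.

    The model refit without the most important variable degrades the most,
    i.e. has the largest -2 log-likelihood; it gets rank 1. Ties break
    toward the earlier variable in ``selected``.
    """
    if not selected:
        raise ModelError("ranking needs a non-empty selection")
    rows = []
    for i, name in enumerate(selected):
        others = [v for v in selected if v != name]
        reduced = fit_logistic(
            dataset.predictors[others] if others else None, dataset.outcome
        )
        rows.append((name, -2.0 * reduced.log_likelihood, i))
    rows.sort(key=lambda r: (-r[1], r[2]))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "variable": [r[0] for r in rows],
            "minus2ll_reduced": [r[1] for r in rows],
        }
    )


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 (Cox-Snell rescaled to a [0, 1] range)."""
    if n <= 0:
        raise ModelError("n must be positive")
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    r2_max = 1.0 - np.exp((2.0 / n) * ll_null)
    if r2_max <= 0:
        return 0.0
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ModelError("scores and labels must be equal-length 1-d vectors")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ModelError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Confusion metrics and cross-validation


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")


def confusion_metrics(probabilities, labels, prob_cutoff: float = 0.5) -> ConfusionCounts:
    """Classify positive iff probability >= ``prob_cutoff`` and count outcomes."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = p >= prob_cutoff
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


@dataclass
class PredictionReport:
    """Cross-validated performance of one final model (percent metrics)."""

    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    pooled: ConfusionCounts
    pooled_auc: float
    k: int
    seed: int
    fold_metrics: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "auc": round(self.auc, 3),
            "sensitivity_pct": round(self.sensitivity, 1),
            "specificity_pct": round(self.specificity, 1),
            "ppv_pct": round(self.ppv, 1),
            "npv_pct": round(self.npv, 1),
            "pooled_counts": {
                "tp": self.pooled.tp,
                "fp": self.pooled.fp,
                "fn": self.pooled.fn,
                "tn": self.pooled.tn,
            },
            "pooled": {
                "auc": round(self.pooled_auc, 3),
                "sensitivity_pct": round(self.pooled.sensitivity, 1),
                "specificity_pct": round(self.pooled.specificity, 1),
                "ppv_pct": round(self.pooled.ppv, 1),
                "npv_pct": round(self.pooled.npv, 1),
            },
            "k": self.k,
            "seed": self.seed,
        }


def _partition(n: int, k: int, outcome: np.ndarray, seed: int, max_retries: int = 20):
    """Random k-way split with fold sizes differing by <= 1.

    Redrawn (with a shifted seed) until every training fold contains both
    outcome classes; gives up after ``max_retries`` draws.
    """
    for attempt in range(max_retries):
        folds = list(KFold(n_splits=k, shuffle=True, random_state=seed + attempt).split(np.arange(n)))
        if all(
            outcome[train].any() and not outcome[train].all() for train, _ in folds
        ):
            return folds
    raise ModelError(f"could not draw a {k}-fold partition with both classes in every training fold")


def kfold_cv(
    dataset: ModelDataset,
    variables: list[str],
    k: int = 10,
    seed: int = 0,
    prob_cutoff: float = 0.5,
) -> PredictionReport:
    """K-fold cross-validated performance of a fixed variable set.

    The dataset is split randomly into ``k`` near-equal parts; for each part
    the model is refit on the remainder and scored on the held-out part.
    Headline metrics are means of the per-fold values; pooled out-of-fold
    confusion counts and pooled AUC are reported alongside. Per-fold metrics
    with an empty denominator (or a single-class test fold, for AUC) are
    excluded from the mean.
    """
    if dataset.n < k:
        raise ModelError("need at least k samples for k-fold CV")
    folds = _partition(dataset.n, k, dataset.outcome, seed)
    per_fold = []
    oof_prob = np.full(dataset.n, np.nan)
    for train, test in folds:
        fit = fit_logistic(
            dataset.predictors.iloc[train][variables] if variables else None,
            dataset.outcome[train],
        )
        prob = (
            fit.predict(dataset.predictors.iloc[test])
            if variables
            else np.full(test.size, 1 / (1 + np.exp(-fit.intercept)))
        )
        oof_prob[test] = prob
        y_test = dataset.outcome[test]
        counts = confusion_metrics(prob, y_test, prob_cutoff)
        try:
            fold_auc = roc_auc(prob, y_test)
        except ModelError:
            fold_auc = float("nan")
        per_fold.append(
            {
                "auc": fold_auc,
                "sensitivity": counts.sensitivity,
                "specificity": counts.specificity,
                "ppv": counts.ppv,
                "npv": counts.npv,
            }
        )
    fold_frame = pd.DataFrame(per_fold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns in degenerate folds
        means = fold_frame.mean(skipna=True)
    pooled = confusion_metrics(oof_prob, dataset.outcome, prob_cutoff)
    return PredictionReport(
        auc=float(means["auc"]),
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        ppv=float(means["ppv"]),
        npv=float(means["npv"]),
        pooled=pooled,
        pooled_auc=roc_auc(oof_prob, dataset.outcome),
        k=k,
        seed=seed,
        fold_metrics=fold_frame,
    )


# ---------------------------------------------------------------------------
# The AUC gate and the full approach


def apply_auc_gate(auc_sequence, delta: float = 0.005, baseline: float = 0.5) -> list[bool]:
    """Retain flags for a rank-ordered AUC sequence.

    Walks the sequence keeping a current best (starting at the chance
    ``baseline``); entry i is retained iff ``auc[i] - current >= delta``,
    and only retained entries advance the current value.
    """
    current = baseline
    flags = []
    for auc in auc_sequence:
        keep = (auc - current) >= delta - 1e-12
        flags.append(bool(keep))
        if keep:
            current = auc
    return flags


def auc_gated_build(
    trace: pd.DataFrame,
    dataset: ModelDataset,
    delta: float = 0.005,
    auc_mode: str = "cv",
    k: int = 10,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Build the final model by walking ranked variables through the AUC gate.

    For each variable, in rank order, the AUC of the current model plus that
    variable is computed (cross-validated for ``auc_mode='cv'``, in-sample
    refit otherwise); the variable is retained iff the gain over the carried
    model is at least ``delta`` (the first comparison is against 0.5).
    Excluded variables do not enter the carried model. Returns the final
    variable list and the trace annotated with gate AUCs and retained flags.
    """
    if auc_mode not in ("cv", "in_sample"):
        raise ModelError(f"unknown auc_mode {auc_mode!r}")
    current_vars: list[str] = []
    current_auc = 0.5
    gate_aucs, flags = [], []
    for name in trace["variable"]:
        candidate = current_vars + [name]
        if auc_mode == "cv":
            auc = kfold_cv(dataset, candidate, k=k, seed=seed).auc
        else:
            fit = fit_logistic(dataset.predictors[candidate], dataset.outcome)
            auc = roc_auc(fit.predict(dataset.predictors), dataset.outcome)
        keep = (auc - current_auc) >= delta - 1e-12
        gate_aucs.append(auc)
        flags.append(bool(keep))
        if keep:
            current_vars = candidate
            current_auc = auc
    annotated = trace.copy()
    annotated["gate_auc"] = gate_aucs
    annotated["retained"] = flags
    return current_vars, annotated


@dataclass
class ApproachResult:
    approach: int
    selected: list[tuple[str, float]]  # stepwise order with entry p
    trace: pd.DataFrame  # Table-3/4-shaped ranked trace
    final_variables: list[str]
    final_fit: LogisticFit | None
    report: PredictionReport | None


def run_approach(
    dataset: ModelDataset,
    approach: int,
    entry_p: float = 0.05,
    delta: float = 0.005,
    k: int = 10,
    seed: int = 0,
    auc_mode: str = "cv",
    prob_cutoff: float = 0.5,
) -> ApproachResult:
    """Full preselection -> ranking -> gated build -> cross-validation.

    ``dataset.predictors`` must already hold the approach's candidate set
    (Approach 1: verified SNP dosages plus the binary CYP2D6 impaired
    indicator; Approach 2: the SNP dosages plus the CYP2D6-region SNP
    dosages instead of the genotype indicator). The trace mirrors the
    published model tables: per rank, the -2 LL of the reduced and the
    cumulative model, cumulative Nagelkerke R^2 and in-sample AUC, the
    multivariate OR with Wald 95% CI and p, and the gate's retained flag.
    """
    selected = forward_stepwise(dataset.predictors, dataset.outcome, entry_p)
    if not selected:
        return ApproachResult(approach, [], pd.DataFrame(), [], None, None)
    names = [v for v, _ in selected]
    trace = rank_variables(names, dataset)
    null_fit = fit_logistic(None, dataset.outcome)
    full_fit = fit_logistic(dataset.predictors[names], dataset.outcome)
    # Cumulative columns along the ranked order.
    r2s, aucs, m2ll_cum = [], [], []
    for i in range(len(trace)):
        upto = trace["variable"].iloc[: i + 1].tolist()
        fit = fit_logistic(dataset.predictors[upto], dataset.outcome)
        r2s.append(nagelkerke_r2(fit.log_likelihood, null_fit.log_likelihood, dataset.n))
        aucs.append(roc_auc(fit.predict(dataset.predictors), dataset.outcome))
        m2ll_cum.append(-2.0 * fit.log_likelihood)
    trace["minus2ll_cumulative"] = m2ll_cum
    trace["r2_cumulative"] = r2s
    trace["auc_cumulative"] = aucs
    # Multivariate per-variable effect estimates from the full selected model.
    z = stats.norm.ppf(0.975)
    coef = dict(zip(full_fit.variables, full_fit.coefficients))
    se = dict(zip(full_fit.variables, full_fit.bse[1:]))
    trace["or"] = [float(np.exp(coef[v])) for v in trace["variable"]]
    trace["ci_low"] = [float(np.exp(coef[v] - z * se[v])) for v in trace["variable"]]
    trace["ci_high"] = [float(np.exp(coef[v] + z * se[v])) for v in trace["variable"]]
    trace["p_wald"] = [
        float(2 * stats.norm.sf(abs(coef[v] / se[v]))) for v in trace["variable"]
    ]
    final_vars, trace = auc_gated_build(trace, dataset, delta, auc_mode, k=k, seed=seed)
    final_fit = fit_logistic(dataset.predictors[final_vars], dataset.outcome) if final_vars else None
    report = kfold_cv(dataset, final_vars, k=k, seed=seed, prob_cutoff=prob_cutoff)
    return ApproachResult(approach, selected, trace, final_vars, final_fit, report)
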