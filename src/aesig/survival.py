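"""Survival and response evaluation: KM/log-rank, Cox models, C-index,
four-group stratification and responder statistics.

Model fitting is delegated to ``lifelines``; this module owns the contracts
(dichotomization rule, tie handling, orientation of the concordance index,
rank-sum AUC identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

logger = logging.getLogger(__name__)

FOUR_GROUPS = ("TEhi/TIlo", "TEhi/TIhi", "TElo/TIlo", "TElo/TIhi")


class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalResult:
    """Cox fit summary: per-covariate HR with 95% CI and Wald p."""

    summary: pd.DataFrame  # index covariate; columns hr, ci_lower, ci_upper, p
    n: int
    events: int
    log_likelihood: float
    linear_predictor: pd.Series | None = None


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    logrank_p: float


@dataclass
class ResponseResult:
    contrasts: dict[str, float]  # contrast label -> two-sided rank-sum p
    auc: float
    roc: pd.DataFrame = field(repr=False, default=None)


def dichotomize(scores) -> np.ndarray:
    """Median split: score > median -> "high", score <= median -> "low".

    Ties at the median go to the low group.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise ValueError("need a 1-d vector of >= 2 scores")
    if np.ptp(s) == 0:
        raise ValueError("all scores equal; cannot dichotomize")
    med = np.median(s)
    labels = np.where(s > med, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("median split produced a single group")
    return labels


def km_logrank(groups, clinical: pd.DataFrame) -> KMResult:
    """Kaplan-Meier curves per group plus a multi-group log-rank p.

    ``clinical`` needs ``time`` and ``event`` columns aligned with
    ``groups`` (positionally).
    """
    groups = np.asarray(groups)
    time = np.asarray(clinical["time"], dtype=float)
    event = np.asarray(clinical["event"], dtype=float)
    if len(groups) != len(time):
        raise ValueError("groups and clinical table have different lengths")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g in uniq:
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[str(g)] = curve
        medians[str(g)] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(time, groups, event)
    return KMResult(curves=curves, medians=medians, logrank_p=float(res.p_value))


def _prepare_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Listwise-drop missing rows and dummy-code categoricals."""
    cols = ["time", "event"] + list(covariates)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"covariate columns not found: {missing}")
    sub = df[cols].dropna()
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("dropped %d samples with missing covariate values", dropped)
    design = pd.get_dummies(sub, columns=[
        c for c in covariates if sub[c].dtype == object or str(sub[c].dtype) == "category"
    ], drop_first=True)
    for c in design.columns:
        if c in ("time", "event"):
            continue
        vals = design[c].astype(float)
        if vals.nunique() < 2:
            raise ValueError(f"covariate {c!r} has a single level after filtering")
        design[c] = vals
    return design


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    penalizer: float = 0.0,
) -> SurvivalResult:
    """Partial-likelihood proportional-hazards fit.

    ``df`` carries ``time``, ``event`` and the covariate columns; rows with
    missing values are dropped listwise (count logged). Univariate when one
    covariate is given. Non-convergence raises :class:`CoxConvergenceError`.
    """
    if not covariates:
        raise ValueError("at least one covariate required")
    design = _prepare_design(df, covariates)
    n = len(design)
    events = int(design["event"].sum())
    n_cov = design.shape[1] - 2
    if events < n_cov:
        raise ValueError(f"{events} events < {n_cov} covariates; fit unidentified")
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise CoxConvergenceError(f"Cox model did not converge: {exc}") from exc
    summ = pd.DataFrame(
        {
            "hr": np.exp(cph.params_),
            "ci_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p": cph.summary["p"],
        }
    )
    summ.index = cph.params_.index
    lp = pd.Series(
        design.drop(columns=["time", "event"]).to_numpy() @ cph.params_.to_numpy(),
        index=design.index,
    )
    return SurvivalResult(
        summary=summ,
        n=n,
        events=events,
        log_likelihood=float(cph.log_likelihood_),
        linear_predictor=lp,
    )


def four_group_stratify(te_scores: pd.Series, ti_scores: pd.Series) -> pd.Series:
    """Cross of the two median dichotomizations over a shared sample set."""
    te = pd.Series(te_scores)
    ti = pd.Series(ti_scores)
    if set(te.index) != set(ti.index):
        raise ValueError("TE and TI scores cover different sample sets")
    ti = ti.loc[te.index]
    te_lab = dichotomize(te.to_numpy())
    ti_lab = dichotomize(ti.to_numpy())
    labels = [f"TE{a}/TI{b}" for a, b in zip(te_lab, ti_lab)]
    labels = [lab.replace("high", "hi").replace("low", "lo") for lab in labels]
    return pd.Series(labels, index=te.index, name="group")


def compare_models(
    df: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    penalizer: float = 0.0,
) -> dict[str, float]:
    """Harrell's C-index of the Cox linear predictor for each feature set.

    Evaluation is in-sample (mirroring per-cohort reporting); the linear
    predictor is negated before scoring so that higher predicted risk
    counts as concordant with shorter survival.
    """
    out: dict[str, float] = {}
    for label, covs in feature_sets.items():
        res = cox_fit(df, covariates=list(covs), penalizer=penalizer)
        idx = res.linear_predictor.index
        c = concordance_index(
            df.loc[idx, "time"],
            -res.linear_predictor,
            df.loc[idx, "event"],
        )
        out[label] = float(c)
    return out


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney U statistic: U / (n1 * n2)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def _roc_curve(scores: np.ndarray, positive: np.ndarray) -> pd.DataFrame:
    order = np.argsort(-scores, kind="stable")
    y = positive[order].astype(float)
    tp = np.concatenate([[0.0], np.cumsum(y)])
    fp = np.concatenate([[0.0], np.cumsum(1 - y)])
    return pd.DataFrame({"fpr": fp / fp[-1], "tpr": tp / tp[-1]})


def response_stats(
    scores,
    labels,
    positive: str | None = None,
) -> ResponseResult:
    """Rank-sum tests and rank-based AUC for therapy-response labels.

    Two-level labels give one contrast; three-level labels (e.g. NR/LS/CR)
    give each non-reference level vs the reference (the most frequent of
    the conventional non-responder codes, else the first level), with AUC
    computed for ``positive``-vs-rest (default: last contrast level).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    levels = list(pd.unique(lab))
    if len(levels) < 2:
        raise ValueError("need at least two response classes")
    for lv in levels:
        if (lab == lv).sum() < 2:
            raise ValueError(f"class {lv!r} has fewer than 2 samples")

    reference = None
    for cand in ("NR", "non-responder", "nonresponder", "0"):
        if cand in levels:
            reference = cand
            break
    if reference is None:
        reference = levels[0]
    contrasts: dict[str, float] = {}
    for lv in levels:
        if lv == reference:
            continue
        u = stats.mannwhitneyu(
            s[lab == lv], s[lab == reference], alternative="two-sided"
        )
        contrasts[f"{lv}_vs_{reference}"] = float(u.pvalue)

    if positive is None:
        positive = [lv for lv in levels if lv != reference][-1]
    pos_mask = lab == positive
    auc = _rank_auc(s[pos_mask], s[~pos_mask])
    roc = _roc_curve(s, pos_mask)
    return ResponseResult(contrasts=contrasts, auc=auc, roc=roc)
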