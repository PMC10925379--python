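"""Discrimination/classification metrics, paired model-comparison tests,
permutation feature importance and baseline cohort statistics.

AUC is the Mann-Whitney concordance probability; correlated AUCs are compared
with DeLong's placement-covariance estimator, paired sensitivities and
specificities with McNemar's test on discordant pairs.  Baseline cohort
descriptions follow the usual clinical-table conventions: counts (percent)
with chi-square for categoricals, mean +/- SD with Welch's two-sample t-test
for continuous variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .tabular_io import FeatureSchema

DEFAULT_CUTOFF = 0.5
# Discordant-pair count below which McNemar switches to the exact binomial test.
MCNEMAR_EXACT_LIMIT = 25


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    ci: tuple[float, float] | None = None
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------

def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(
    labels: Sequence[int],
    probs: Sequence[float],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, float]:
    """Accuracy / sensitivity / specificity at a fixed probability cutoff.

    Predicted positive iff prob >= cutoff.  If a class is absent, the
    corresponding conditional metric is reported as NaN rather than raising.
    """
    y = np.asarray(labels)
    pred = np.asarray(probs, dtype=float) >= cutoff
    pos = y == 1
    neg = y == 0
    acc = float(np.mean(pred == pos))
    sens = float(np.mean(pred[pos])) if pos.any() else float("nan")
    spec = float(np.mean(~pred[neg])) if neg.any() else float("nan")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


# ---------------------------------------------------------------------------
# DeLong test for correlated AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(labels: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-positive (V10) and per-negative (V01) placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(
    labels: Sequence[int],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
) -> ComparisonResult:
    """Two-sided DeLong test of the difference between two correlated AUCs.

    Returns the AUC difference (a - b), its normal-theory p-value, and 95%
    confidence intervals on each AUC in ``extras``.  Degenerate variance
    (e.g. identical score vectors) is flagged and reported as p = 1.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong test needs both classes")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if not (len(y) == len(sa) == len(sb)):
        raise ValueError("paired scores must align with labels")

    auc_a, v10_a, v01_a = _delong_placements(y, sa)
    auc_b, v10_b, v01_b = _delong_placements(y, sb)
    m, n = len(v10_a), len(v01_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)

    z95 = stats.norm.ppf(0.975)
    ci_a = (auc_a - z95 * math.sqrt(max(cov[0, 0], 0.0)),
            auc_a + z95 * math.sqrt(max(cov[0, 0], 0.0)))
    ci_b = (auc_b - z95 * math.sqrt(max(cov[1, 1], 0.0)),
            auc_b + z95 * math.sqrt(max(cov[1, 1], 0.0)))

    delta = auc_a - auc_b
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_delta <= 1e-16:
        return ComparisonResult(
            "delong_auc", statistic=float("nan"), p_value=1.0, degenerate=True,
            extras={"auc_a": auc_a, "auc_b": auc_b, "delta_auc": delta,
                    "ci_a": ci_a, "ci_b": ci_b},
        )
    z = delta / math.sqrt(var_delta)
    p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(
        "delong_auc", statistic=float(z), p_value=p,
        ci=(delta - z95 * math.sqrt(var_delta), delta + z95 * math.sqrt(var_delta)),
        extras={"auc_a": auc_a, "auc_b": auc_b, "delta_auc": delta,
                "ci_a": ci_a, "ci_b": ci_b},
    )


# ---------------------------------------------------------------------------
# McNemar test on paired correctness
# ---------------------------------------------------------------------------

def mcnemar_test(
    correct_a: Sequence[int],
    correct_b: Sequence[int],
    exact_limit: int = MCNEMAR_EXACT_LIMIT,
) -> ComparisonResult:
    """McNemar's test on discordant pairs of per-patient correctness.

    Uses the exact binomial test when the discordant count b + c is below
    ``exact_limit``, otherwise the chi-square version with continuity
    correction.  Zero discordance yields p = 1 with a degenerate flag.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if len(a) != len(b):
        raise ValueError("paired correctness vectors must have equal length")
    n01 = int(np.sum(a & ~b))  # a correct, b wrong
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        return ComparisonResult("mcnemar", statistic=0.0, p_value=1.0,
                                degenerate=True, extras={"b": n01, "c": n10})
    table = [[0, n01], [n10, 0]]
    exact = (n01 + n10) < exact_limit
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return ComparisonResult(
        "mcnemar", statistic=float(res.statistic), p_value=float(res.pvalue),
        extras={"b": n01, "c": n10, "exact": exact},
    )


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model,
    table,
    metric=roc_auc,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance of each input feature for an uncertainty ensemble.

    For every feature, the raw column is shuffled ``n_permutations`` times and
    the drop in the metric is computed per ensemble member, then averaged
    within the ensemble (member-level drops first, members second).  Positive
    values mean the model relies on the feature.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    y = table.y.to_numpy()

    member_probs = model.member_probabilities(table)  # n x B
    baseline = np.array([metric(y, member_probs[:, j])
                         for j in range(member_probs.shape[1])])

    importances = {}
    for feat in model.preprocess.feature_list:
        drops = np.zeros_like(baseline)
        for _ in range(n_permutations):
            shuffled = table.X.copy()
            shuffled[feat] = rng.permutation(shuffled[feat].to_numpy())
            perm_table = type(table)(X=shuffled, y=table.y,
                                     stage_of=dict(table.stage_of))
            probs = model.member_probabilities(perm_table)
            drops += baseline - np.array(
                [metric(y, probs[:, j]) for j in range(probs.shape[1])]
            )
        importances[feat] = float(np.mean(drops / n_permutations))
    return pd.Series(importances, name="importance")


# ---------------------------------------------------------------------------
# Baseline cohort statistics
# ---------------------------------------------------------------------------

def cohort_summary(df: pd.DataFrame, outcome: str = "response") -> dict:
    """Headline cohort counts and percentages (overall n, responders,
    non-responders, and each binary variable's count/percent)."""
    n = len(df)
    y = df[outcome].astype(int)
    out = {
        "n": n,
        "responders_n": int(y.sum()),
        "responders_pct": round(100.0 * y.mean(), 1),
        "nonresponders_n": int((1 - y).sum()),
        "nonresponders_pct": round(100.0 * (1 - y).mean(), 1),
    }
    for col in df.columns:
        if col == outcome:
            continue
        vals = df[col].dropna().unique()
        if set(vals) <= {0, 1}:
            out[f"{col}_n"] = int(df[col].sum())
            out[f"{col}_pct"] = round(100.0 * df[col].mean(), 1)
    return out


def baseline_table(df: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Per-variable baseline summary stratified by outcome.

    Continuous variables: mean +/- SD per group with a Welch two-sample
    t-test.  Binary and categorical variables: count (percent) per group with
    a chi-square test of independence; a zero expected cell flags the test.
    """
    y = df[schema.outcome_name].astype(int)
    groups = {"overall": np.ones(len(df), bool),
              "response": (y == 1).to_numpy(),
              "nonresponse": (y == 0).to_numpy()}
    rows = []
    for name, fdef in schema.features.items():
        col = df[name]
        if fdef.kind == "continuous":
            cells = {g: f"{col[m].mean():.1f} ± {col[m].std(ddof=1):.1f}"
                     for g, m in groups.items()}
            t, p = stats.ttest_ind(col[groups["response"]],
                                   col[groups["nonresponse"]], equal_var=False)
            rows.append({"variable": name, "kind": fdef.kind, **cells,
                         "statistic": float(t), "p_value": float(p), "flag": ""})
        else:
            ct = pd.crosstab(col, y)
            flag = ""
            if ct.shape[0] < 2 or ct.shape[1] < 2:
                chi2, p = float("nan"), float("nan")
                flag = "degenerate"
            else:
                chi2, p, _, expected = stats.chi2_contingency(ct)
                if (expected == 0).any():
                    flag = "zero expected cell"
            levels = sorted(col.unique())
            for lev in levels:
                cells = {}
                for g, m in groups.items():
                    cnt = int(((col == lev) & m).sum())
                    cells[g] = f"{cnt} ({100.0 * cnt / max(m.sum(), 1):.1f}%)"
                rows.append({"variable": f"{name}={lev}" if len(levels) > 2 else name,
                             "kind": fdef.kind, **cells,
                             "statistic": float(chi2), "p_value": float(p),
                             "flag": flag})
                if len(levels) <= 2:
                    break  # binary: one row suffices
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Guideline-vs-model comparison
# ---------------------------------------------------------------------------

def guideline_comparison(
    labels: Sequence[int],
    probs_model: Sequence[float],
    preds_guideline: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, ComparisonResult | None]:
    """Compare a probabilistic model against a binary guideline rule.

    Sensitivity and specificity are compared with McNemar's test restricted
    to the relevant class.  An AUC comparison is not applicable to a binary
    rule and is reported as None.
    """
    y = np.asarray(labels)
    pred_m = np.asarray(probs_model, dtype=float) >= cutoff
    pred_g = np.asarray(preds_guideline, dtype=bool)
    pos = y == 1
    neg = y == 0
    return {
        "delong_auc": None,  # AUC undefined for a hard binary rule
        "mcnemar_sens": mcnemar_test(pred_m[pos], pred_g[pos]),
        "mcnemar_spec": mcnemar_test(~pred_m[neg], ~pred_g[neg]),
    }


# ---------------------------------------------------------------------------
# Across-fold aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Across-fold mean (SD) of AUC/accuracy/sensitivity/specificity, plus the
    distribution of the fraction of patients resolved at stage 1."""

    mean: dict[str, float]
    std: dict[str, float]
    fraction_stage1: dict[str, float] | None = None

    def to_json(self) -> dict:
        out = {"mean": self.mean, "std": self.std}
        if self.fraction_stage1 is not None:
            out["fraction_stage1"] = self.fraction_stage1
        return out


def aggregate_fold_metrics(
    per_fold: list[dict[str, float]],
    fractions_stage1: list[float] | None = None,
) -> MetricsReport:
    """Unweighted mean and sample SD of each metric across outer folds."""
    keys = per_fold[0].keys()
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
    std = {k: float(np.std([f[k] for f in per_fold], ddof=1)) if len(per_fold) > 1
           else 0.0 for k in keys}
    frac = None
    if fractions_stage1 is not None:
        arr = np.asarray(fractions_stage1, dtype=float)
        frac = {
            "mean": float(arr.mean()),
            "q25": float(np.percentile(arr, 25)),
            "q50": float(np.percentile(arr, 50)),
            "q75": float(np.percentile(arr, 75)),
        }
    return MetricsReport(mean=mean, std=std, fraction_stage1=frac)
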