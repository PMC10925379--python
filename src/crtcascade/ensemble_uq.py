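"""Pseudo-bootstrapped ensembles of elastic-net logistic regressions with
per-patient predictive mean and standard deviation.

Each ensemble member is an elastic-net penalized logistic regression fitted
on a random subsample (fraction phi, drawn WITHOUT replacement — hence
"pseudo" bootstrap) of the training partition.  At inference every member
emits a response probability; the arithmetic mean is the ensemble prediction
and the sample standard deviation across members quantifies its uncertainty:
patients on whom subsample-perturbed models disagree get a high standard
deviation.

The penalized objective for a member with coefficients w and intercept b is

    sum_i log(1 + exp(-y_i (x_i.w + b)))  +  lam * (alpha*|w|_1 + (1-alpha)/2*|w|_2^2)

with the intercept unpenalized; alpha in [0, 1] mixes lasso (1) and ridge (0).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc
from .tabular_io import (
    FeatureTable,
    PreprocessParams,
    apply_preprocess,
    fit_preprocess,
)

MAX_SUBSAMPLE_RETRIES = 10


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseLearnerSpec:
    """Elastic-net logistic regression hyperparameters."""

    alpha: float = 0.5      # L1/L2 mixing: 0 = ridge, 1 = lasso
    lam: float = 1.0        # total penalty strength
    tol: float = 1e-6
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0.0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble size B and the pseudo-bootstrap subsample fraction phi."""

    n_models: int = 25
    sample_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")


@dataclass
class UncertaintyPrediction:
    """Per-patient ensemble member probabilities with their mean and SD."""

    member_probs: np.ndarray  # n x B
    p_mean: np.ndarray
    p_std: np.ndarray

    @classmethod
    def from_members(cls, member_probs: np.ndarray) -> "UncertaintyPrediction":
        member_probs = np.atleast_2d(member_probs)
        p_mean = member_probs.mean(axis=1)
        if member_probs.shape[1] < 2:
            warnings.warn("single-member ensemble: p_std reported as 0", stacklevel=2)
            p_std = np.zeros(member_probs.shape[0])
        else:
            p_std = member_probs.std(axis=1, ddof=1)
        return cls(member_probs=member_probs, p_mean=p_mean, p_std=p_std)


# ---------------------------------------------------------------------------
# Pseudo-bootstrap subsampling
# ---------------------------------------------------------------------------

def draw_pseudo_bootstrap(n: int, spec: EnsembleSpec) -> list[np.ndarray]:
    """Draw B index subsets of size round(phi * n), uniformly WITHOUT
    replacement, fully determined by the spec's seed."""
    size = int(np.rint(spec.sample_fraction * n))
    if n < 2 or size < 2:
        raise ValueError(f"subset size {size} too small (n={n})")
    rng = np.random.default_rng(spec.seed)
    # sorted: membership is what matters, and row order must not perturb fits
    return [np.sort(rng.choice(n, size=size, replace=False))
            for _ in range(spec.n_models)]


# ---------------------------------------------------------------------------
# Base learner
# ---------------------------------------------------------------------------

@dataclass
class FittedBase:
    coef: np.ndarray
    intercept: float
    converged: bool = True

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        eta = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


def _refit_intercept(eta: np.ndarray, y: np.ndarray, b0: float) -> float:
    """Exact unpenalized intercept given fixed slopes (1-D Newton)."""
    b = b0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(eta + b)))
        grad = float(np.sum(p - y))
        hess = float(np.sum(p * (1.0 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    return b


def fit_base(Z: np.ndarray, y: Sequence[int], spec: BaseLearnerSpec) -> FittedBase:
    """Fit one elastic-net logistic regression on standardized rows.

    Solver choice follows the penalty: lbfgs for pure-ridge or unpenalized
    fits, saga for any L1 component.  The unpenalized intercept is refit
    exactly afterwards (saga resolves it slowly under heavy penalty).
    Non-convergence is reported through a warning and the returned flag,
    never silently swallowed.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("base learner needs both outcome classes")

    if spec.lam == 0.0:
        kwargs = dict(C=np.inf, l1_ratio=0.0, solver="lbfgs")
    elif spec.alpha == 0.0:
        kwargs = dict(C=1.0 / spec.lam, l1_ratio=0.0, solver="lbfgs")
    else:
        kwargs = dict(C=1.0 / spec.lam, l1_ratio=spec.alpha, solver="saga")
    clf = LogisticRegression(tol=spec.tol, max_iter=spec.max_iter,
                             random_state=0, **kwargs)
    Z = np.asarray(Z, dtype=float)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Z, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn("base learner did not converge within max_iter",
                          stacklevel=2)
    coef = clf.coef_.ravel().copy()
    intercept = _refit_intercept(Z @ coef, y, float(clf.intercept_[0]))
    return FittedBase(coef=coef, intercept=intercept, converged=converged)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """B fitted base learners sharing one preprocessing transform and one
    feature list, everything needed for standalone inference."""

    bases: list[FittedBase]
    preprocess: PreprocessParams
    espec: EnsembleSpec
    bspec: BaseLearnerSpec

    @property
    def features(self) -> list[str]:
        return self.preprocess.feature_list

    def member_probabilities(self, table: FeatureTable) -> np.ndarray:
        Z = apply_preprocess(self.preprocess, table).X.to_numpy(dtype=float)
        return np.column_stack([b.predict_proba(Z) for b in self.bases])

    def predict(self, table: FeatureTable) -> UncertaintyPrediction:
        return UncertaintyPrediction.from_members(self.member_probabilities(table))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "bases": [{"coef": b.coef.tolist(), "intercept": b.intercept,
                       "converged": b.converged} for b in self.bases],
            "preprocess": self.preprocess.to_json(),
            "espec": {"n_models": self.espec.n_models,
                      "sample_fraction": self.espec.sample_fraction,
                      "seed": self.espec.seed},
            "bspec": {"alpha": self.bspec.alpha, "lam": self.bspec.lam,
                      "tol": self.bspec.tol, "max_iter": self.bspec.max_iter},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def from_json(cls, raw: dict) -> "EnsembleModel":
        return cls(
            bases=[FittedBase(coef=np.asarray(b["coef"]), intercept=b["intercept"],
                              converged=b.get("converged", True))
                   for b in raw["bases"]],
            preprocess=PreprocessParams.from_json(raw["preprocess"]),
            espec=EnsembleSpec(**raw["espec"]),
            bspec=BaseLearnerSpec(**raw["bspec"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_ensemble(
    table: FeatureTable,
    features: list[str] | None,
    espec: EnsembleSpec,
    bspec: BaseLearnerSpec,
    spatial_sign: bool = True,
) -> EnsembleModel:
    """Fit a pseudo-bootstrapped ensemble on a training partition.

    Preprocessing is fitted once on the full training partition and shared by
    all members; members then fit on their own subsample of the transformed
    rows.  A subsample that collapses to a single class is redrawn with a
    shifted seed, up to a retry cap.
    """
    table.check_both_classes()
    params = fit_preprocess(table, features, spatial_sign=spatial_sign)
    Z = apply_preprocess(params, table).X.to_numpy(dtype=float)
    y = table.y.to_numpy()

    subsets = draw_pseudo_bootstrap(table.n, espec)
    bases: list[FittedBase] = []
    for k, idx in enumerate(subsets):
        for retry in range(MAX_SUBSAMPLE_RETRIES + 1):
            if len(np.unique(y[idx])) == 2:
                break
            shifted = EnsembleSpec(n_models=1, sample_fraction=espec.sample_fraction,
                                   seed=espec.seed + 1000 * (retry + 1) + k)
            idx = draw_pseudo_bootstrap(table.n, shifted)[0]
        else:
            raise ValueError(f"member {k}: could not draw a two-class subsample")
        bases.append(fit_base(Z[idx], y[idx], bspec))
    return EnsembleModel(bases=bases, preprocess=params, espec=espec, bspec=bspec)


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

def select_features_rfe(
    table: FeatureTable,
    bspec: BaseLearnerSpec,
    cv_folds: int = 5,
    seed: int = 0,
    features: list[str] | None = None,
    spatial_sign: bool = True,
) -> list[str]:
    """Recursive feature elimination with a halving schedule.

    Features are ranked by the absolute coefficient of a single elastic-net
    fit on the standardized training partition; the weakest half is dropped
    at each step down to one feature.  The candidate subset maximizing
    stratified cross-validated AUC is returned; ties favour the smaller set.
    """
    features = list(features or table.feature_names)
    if len(features) < 1:
        raise ValueError("no features to select from")
    if len(features) == 1:
        return features

    def cv_auc(feats: list[str]) -> float:
        y = table.y.to_numpy()
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(np.zeros(table.n), y):
            train = table.subset(tr)
            params = fit_preprocess(train, feats, spatial_sign=spatial_sign)
            Ztr = apply_preprocess(params, train).X.to_numpy(dtype=float)
            base = fit_base(Ztr, y[tr], bspec)
            Zte = apply_preprocess(params, table.subset(te)).X.to_numpy(dtype=float)
            aucs.append(roc_auc(y[te], base.predict_proba(Zte)))
        return float(np.mean(aucs))

    # Build the nested candidate subsets by repeated halving.
    candidates = [features]
    current = features
    while len(current) > 1:
        params = fit_preprocess(table, current, spatial_sign=spatial_sign)
        Z = apply_preprocess(params, table).X.to_numpy(dtype=float)
        base = fit_base(Z, table.y.to_numpy(), bspec)
        ranked = [f for _, f in sorted(
            zip(np.abs(base.coef), params.feature_list),
            key=lambda t: (-t[0], t[1]))]
        keep = max(1, len(current) // 2)
        current = ranked[:keep]
        candidates.append(current)

    scored = [(cv_auc(c), -len(c), i) for i, c in enumerate(candidates)]
    best_idx = max(scored)[2]
    return list(candidates[best_idx])


# ---------------------------------------------------------------------------
# Inner-CV hyperparameter tuning
# ---------------------------------------------------------------------------

def tune_ensemble(
    table: FeatureTable,
    features: list[str] | None = None,
    b_grid: Sequence[int] = (25,),
    phi_grid: Sequence[float] = (0.95,),
    alpha_grid: Sequence[float] = (0.5,),
    lambda_grid: Sequence[float] = (1.0,),
    inner_folds: int = 5,
    seed: int = 0,
    spatial_sign: bool = True,
    one_se_rule: bool = True,
) -> tuple[EnsembleSpec, BaseLearnerSpec]:
    """Grid search over ensemble and base-learner hyperparameters by mean
    inner-CV AUC of the ensemble's aggregated probability.

    With ``one_se_rule`` (the glmnet-style default) the most-regularized grid
    point whose mean AUC lies within one standard error of the best is
    selected: when discrimination is flat in lambda, the parsimonious model
    wins.  Exact ties break toward the smaller ensemble (fewer base models),
    then the larger subsample fraction.
    """
    grid = list(itertools.product(b_grid, phi_grid, alpha_grid, lambda_grid))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = table.y.to_numpy()
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(table.n), y))

    scored = []
    for B, phi, alpha, lam in grid:
        bspec = BaseLearnerSpec(alpha=alpha, lam=lam)
        aucs = []
        for fold_i, (tr, te) in enumerate(splits):
            espec = EnsembleSpec(n_models=B, sample_fraction=phi,
                                 seed=seed + 7919 * fold_i)
            model = fit_ensemble(table.subset(tr), features, espec, bspec,
                                 spatial_sign=spatial_sign)
            pred = model.predict(table.subset(te))
            aucs.append(roc_auc(y[te], pred.p_mean))
        mean_auc = float(np.mean(aucs))
        se = float(np.std(aucs, ddof=1) / math.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
        scored.append((mean_auc, se, B, phi, bspec))

    best_mean, best_se = max((m, s) for m, s, *_ in scored)
    if one_se_rule:
        admissible = [t for t in scored if t[0] >= best_mean - best_se]
        # most regularization first, then the spec'd tie order
        _, _, B, phi, bspec = max(admissible,
                                  key=lambda t: (t[4].lam, -t[2], t[3], t[0]))
    else:
        _, _, B, phi, bspec = max(scored, key=lambda t: (t[0], -t[2], t[3]))
    return EnsembleSpec(n_models=B, sample_fraction=phi, seed=seed), bspec
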