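"""Protocol orchestration: nested cross-validation with dual validation
slices, per-fold cascade tuning, final evaluation and the sample-size
simulation.

One outer fold proceeds as: split off the test fold; slice two stratified
validation sets from the outer training partition; on the remaining training
rows run feature selection and inner-CV hyperparameter tuning per stage and
fit Ensemble 1 (stage-1 features) and Ensemble 2 (stage-1 + stage-2
features); tune the gate thresholds on validation set 1 once per scaling
parameter; pick the scaling parameter by plain AUC on validation set 2; and
finally evaluate cascade, both ensembles and the guideline comparator on the
untouched test fold.  Test rows are never seen by preprocessing fits,
feature selection, inner CV or threshold tuning — a programmatic leakage
audit asserts the disjointness on every fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .ensemble_uq import (
    BaseLearnerSpec,
    EnsembleModel,
    EnsembleSpec,
    fit_ensemble,
    select_features_rfe,
    tune_ensemble,
)
from .evaluation import (
    MetricsReport,
    aggregate_fold_metrics,
    confusion_metrics,
    guideline_comparison,
    roc_auc,
)
from .stage_gate import (
    DEFAULT_MIDWAY_GRID,
    DEFAULT_SCALING_GRID,
    DEFAULT_STD_GRID,
    GatePolicy,
    cascade_from_predictions,
    select_scaling_on_predictions,
    tune_thresholds_on_predictions,
)
from .tabular_io import FeatureTable, split_stages

logger = logging.getLogger("crtcascade")

MAX_RESAMPLE_RETRIES = 10


# ---------------------------------------------------------------------------
# Plans and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Nested-CV layout: 10 stratified outer folds and two validation slices
    of 20 patients each cut from every outer training partition."""

    n_outer_folds: int = 10
    validation1_size: int = 20
    validation2_size: int = 20
    n_inner_folds: int = 5
    stratified: bool = True
    seed: int = 0


@dataclass
class ExperimentConfig:
    """Search grids and pipeline switches for one experiment run."""

    b_grid: tuple[int, ...] = (25,)
    phi_grid: tuple[float, ...] = (0.70,)
    alpha_grid: tuple[float, ...] = (0.5,)
    lambda_grid: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0)
    std_grid: tuple[float, ...] = DEFAULT_STD_GRID
    midway_grid: tuple[float, ...] = DEFAULT_MIDWAY_GRID
    scaling_grid: tuple[float, ...] = DEFAULT_SCALING_GRID
    run_rfe: bool = False
    tune_hyperparameters: bool = False
    spatial_sign: bool = True
    guideline_preds: np.ndarray | None = None  # per-row 0/1, aligned to the table

    def first_specs(self, seed: int) -> tuple[EnsembleSpec, BaseLearnerSpec]:
        return (EnsembleSpec(self.b_grid[0], self.phi_grid[0], seed=seed),
                BaseLearnerSpec(self.alpha_grid[0], self.lambda_grid[0]))


@dataclass(frozen=True)
class SimulationGrid:
    """Training-set-size sweep: fractions of the training fold resampled with
    replacement, each repeated a few times."""

    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if not (np.all(np.diff(f) > 0) and f[0] > 0 and f[-1] <= 1.0):
            raise ValueError("fractions must be strictly increasing within (0, 1]")


@dataclass
class FoldResult:
    fold: int
    policy: GatePolicy
    espec1: EnsembleSpec
    espec2: EnsembleSpec
    bspec1: BaseLearnerSpec
    bspec2: BaseLearnerSpec
    features1: list[str]
    features2: list[str]
    fraction_stage1: float
    metrics: dict[str, dict[str, float]]
    predictions: dict[str, np.ndarray]
    test_idx: np.ndarray
    train_idx: np.ndarray


@dataclass
class NestedCVResult:
    folds: list[FoldResult]
    reports: dict[str, MetricsReport]
    plan: CVPlan
    complete: bool = True


# ---------------------------------------------------------------------------
# Fold machinery
# ---------------------------------------------------------------------------

def _outer_folds(y: np.ndarray, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    if plan.stratified:
        skf = StratifiedKFold(n_splits=plan.n_outer_folds, shuffle=True,
                              random_state=plan.seed)
        return list(skf.split(np.zeros(len(y)), y))
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(len(y))
    chunks = np.array_split(perm, plan.n_outer_folds)
    return [(np.setdiff1d(perm, c), c) for c in chunks]


def slice_validation_sets(
    train_idx: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut validation1 and validation2 from the outer training partition,
    stratified by outcome; returns (remaining_train, val1, val2)."""
    strat = y[train_idx] if plan.stratified else None
    rem, val1 = train_test_split(train_idx, test_size=plan.validation1_size,
                                 stratify=strat, random_state=fold_seed)
    strat2 = y[rem] if plan.stratified else None
    rem, val2 = train_test_split(rem, test_size=plan.validation2_size,
                                 stratify=strat2, random_state=fold_seed + 1)
    n_rem_classes = len(np.unique(y[rem]))
    if n_rem_classes < 2 or min(np.bincount(y[rem])) < 2:
        raise ValueError("remaining training partition leaves < 2 patients per class")
    return np.sort(rem), np.sort(val1), np.sort(val2)


def leakage_audit(train: np.ndarray, val1: np.ndarray, val2: np.ndarray,
                  test: np.ndarray) -> None:
    """Assert that test rows never intersect any fitting or tuning slice."""
    parts = {"train": set(train.tolist()), "val1": set(val1.tolist()),
             "val2": set(val2.tolist()), "test": set(test.tolist())}
    names = list(parts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = parts[a] & parts[b]
            if overlap:
                raise AssertionError(f"leakage: {a} and {b} share rows {sorted(overlap)[:5]}")


def _fit_stage_ensemble(
    view: FeatureTable,
    rem_idx: np.ndarray,
    plan: CVPlan,
    config: ExperimentConfig,
    fold_seed: int,
) -> tuple[EnsembleModel, list[str], EnsembleSpec, BaseLearnerSpec]:
    train = view.subset(rem_idx)
    espec0, bspec0 = config.first_specs(fold_seed)
    features = train.feature_names
    if config.run_rfe:
        features = select_features_rfe(train, bspec0, cv_folds=plan.n_inner_folds,
                                       seed=fold_seed, spatial_sign=config.spatial_sign)
    if config.tune_hyperparameters:
        espec, bspec = tune_ensemble(
            train, features,
            b_grid=config.b_grid, phi_grid=config.phi_grid,
            alpha_grid=config.alpha_grid, lambda_grid=config.lambda_grid,
            inner_folds=plan.n_inner_folds, seed=fold_seed,
            spatial_sign=config.spatial_sign,
        )
    else:
        espec, bspec = espec0, bspec0
    model = fit_ensemble(train, features, espec, bspec,
                         spatial_sign=config.spatial_sign)
    return model, features, espec, bspec


def run_fold(
    table: FeatureTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fold: int,
    plan: CVPlan,
    config: ExperimentConfig,
) -> FoldResult:
    y = table.y.to_numpy()
    fold_seed = int(np.random.SeedSequence([plan.seed, fold]).generate_state(1)[0] % 2**31)
    rem_idx, v1_idx, v2_idx = slice_validation_sets(train_idx, y, plan, fold_seed)
    leakage_audit(rem_idx, v1_idx, v2_idx, test_idx)

    s1_view, s2_view = split_stages(table)
    ens1, feats1, espec1, bspec1 = _fit_stage_ensemble(s1_view, rem_idx, plan,
                                                       config, fold_seed)
    ens2, feats2, espec2, bspec2 = _fit_stage_ensemble(s2_view, rem_idx, plan,
                                                       config, fold_seed + 1)

    pred1 = {k: ens1.predict(s1_view.subset(idx))
             for k, idx in (("v1", v1_idx), ("v2", v2_idx), ("test", test_idx))}
    pred2 = {k: ens2.predict(s2_view.subset(idx))
             for k, idx in (("v1", v1_idx), ("v2", v2_idx), ("test", test_idx))}

    candidates = [
        tune_thresholds_on_predictions(y[v1_idx], pred1["v1"], pred2["v1"], s,
                                       config.std_grid, config.midway_grid)
        for s in config.scaling_grid
    ]
    policy = select_scaling_on_predictions(y[v2_idx], pred1["v2"], pred2["v2"],
                                           candidates)

    cascade_probs, needs, f = cascade_from_predictions(pred1["test"], pred2["test"],
                                                       policy)
    y_test = y[test_idx]
    metrics: dict[str, dict[str, float]] = {}
    predictions = {"multi_stage": cascade_probs,
                   "ensemble1": pred1["test"].p_mean,
                   "ensemble2": pred2["test"].p_mean}
    for name, probs in predictions.items():
        metrics[name] = {"auc": roc_auc(y_test, probs),
                         **confusion_metrics(y_test, probs)}
    if config.guideline_preds is not None:
        g = np.asarray(config.guideline_preds)[test_idx].astype(float)
        metrics["guideline"] = confusion_metrics(y_test, g)
        predictions["guideline"] = g

    return FoldResult(
        fold=fold, policy=policy,
        espec1=espec1, espec2=espec2, bspec1=bspec1, bspec2=bspec2,
        features1=feats1, features2=feats2,
        fraction_stage1=f, metrics=metrics, predictions=predictions,
        test_idx=np.asarray(test_idx), train_idx=np.asarray(train_idx),
    )


def run_nested_cv(
    table: FeatureTable,
    plan: CVPlan = CVPlan(),
    config: ExperimentConfig | None = None,
) -> NestedCVResult:
    """Run the full nested-CV protocol and aggregate across outer folds."""
    config = config or ExperimentConfig()
    y = table.y.to_numpy()
    folds = []
    for fold, (train_idx, test_idx) in enumerate(_outer_folds(y, plan)):
        folds.append(run_fold(table, train_idx, test_idx, fold, plan, config))

    model_names = list(folds[0].metrics)
    reports = {}
    for name in model_names:
        fractions = [fr.fraction_stage1 for fr in folds] if name == "multi_stage" else None
        reports[name] = aggregate_fold_metrics(
            [fr.metrics[name] for fr in folds], fractions)
    return NestedCVResult(folds=folds, reports=reports, plan=plan)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def emit_report(result: NestedCVResult, out_dir: str | Path | None = None) -> dict:
    """Machine-readable report: aggregate table, per-fold hyperparameters and
    the seeds/plan needed to replay the run bit-for-bit."""
    report = {
        "complete": result.complete and len(result.folds) == result.plan.n_outer_folds,
        "plan": {"n_outer_folds": result.plan.n_outer_folds,
                 "validation1_size": result.plan.validation1_size,
                 "validation2_size": result.plan.validation2_size,
                 "n_inner_folds": result.plan.n_inner_folds,
                 "stratified": result.plan.stratified,
                 "seed": result.plan.seed},
        "aggregate": {name: rep.to_json() for name, rep in result.reports.items()},
        "folds": [
            {
                "fold": fr.fold,
                "std_threshold": fr.policy.std_threshold,
                "midway_threshold": fr.policy.midway_threshold,
                "scaling_weight": fr.policy.scaling_weight,
                "ensemble1": {"n_models": fr.espec1.n_models,
                              "sample_fraction": fr.espec1.sample_fraction},
                "ensemble2": {"n_models": fr.espec2.n_models,
                              "sample_fraction": fr.espec2.sample_fraction},
                "fraction_stage1": fr.fraction_stage1,
                "metrics": fr.metrics,
            }
            for fr in result.folds
        ],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
        pd.DataFrame([{"fold": f["fold"], "std_threshold": f["std_threshold"],
                       "midway_threshold": f["midway_threshold"],
                       "scaling_weight": f["scaling_weight"],
                       "fraction_stage1": f["fraction_stage1"]}
                      for f in report["folds"]]).to_csv(out / "folds.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Sample-size simulation
# ---------------------------------------------------------------------------

def _resample_with_replacement(rng: np.random.Generator, idx: np.ndarray,
                               size: int, y: np.ndarray) -> np.ndarray:
    for _ in range(MAX_RESAMPLE_RETRIES + 1):
        draw = rng.choice(idx, size=size, replace=True)
        if len(np.unique(y[draw])) == 2:
            return draw
    raise ValueError("resample repeatedly yielded a single class")


def sample_size_simulation(
    table: FeatureTable,
    grid: SimulationGrid = SimulationGrid(),
    plan: CVPlan = CVPlan(),
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Effect of training-set size on cascade performance.

    For every outer fold, fraction and repeat, the remaining training rows
    are resampled WITH replacement at that fraction (distinct from the
    without-replacement pseudo-bootstrap inside ensembles), both ensembles
    are retrained, the gate is retuned, and the unchanged outer test fold is
    evaluated.  Returns per-fraction mean and SD of each metric.
    """
    config = config or ExperimentConfig()
    y = table.y.to_numpy()
    s1_view, s2_view = split_stages(table)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(_outer_folds(y, plan)):
        fold_seed = int(np.random.SeedSequence([plan.seed, fold]).generate_state(1)[0] % 2**31)
        rem_idx, v1_idx, v2_idx = slice_validation_sets(train_idx, y, plan, fold_seed)
        for frac in grid.fractions:
            for rep in range(grid.repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence([grid.seed, fold, rep,
                                            int(frac * 100)]).generate_state(1)[0])
                size = max(4, int(np.rint(frac * len(rem_idx))))
                draw = _resample_with_replacement(rng, rem_idx, size, y)
                sub_cfg_seed = fold_seed + 31 * rep + int(frac * 100)
                espec, bspec = config.first_specs(sub_cfg_seed)
                ens1 = fit_ensemble(s1_view.subset(draw), None, espec, bspec,
                                    spatial_sign=config.spatial_sign)
                ens2 = fit_ensemble(s2_view.subset(draw), None, espec, bspec,
                                    spatial_sign=config.spatial_sign)
                p1 = {k: ens1.predict(s1_view.subset(i))
                      for k, i in (("v1", v1_idx), ("v2", v2_idx), ("test", test_idx))}
                p2 = {k: ens2.predict(s2_view.subset(i))
                      for k, i in (("v1", v1_idx), ("v2", v2_idx), ("test", test_idx))}
                candidates = [
                    tune_thresholds_on_predictions(y[v1_idx], p1["v1"], p2["v1"], s,
                                                   config.std_grid, config.midway_grid)
                    for s in config.scaling_grid
                ]
                policy = select_scaling_on_predictions(y[v2_idx], p1["v2"],
                                                       p2["v2"], candidates)
                probs, _, f = cascade_from_predictions(p1["test"], p2["test"], policy)
                y_test = y[test_idx]
                rows.append({"fraction": frac, "fold": fold, "repeat": rep,
                             "auc": roc_auc(y_test, probs),
                             **confusion_metrics(y_test, probs),
                             "fraction_stage1": f})
    raw = pd.DataFrame(rows)
    agg = raw.groupby("fraction").agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
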