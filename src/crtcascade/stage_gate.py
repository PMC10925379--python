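"""The uncertainty gate and two-stage cascade.

A patient is first predicted by Ensemble 1 (cheap, stage-1 features).  The
gate escalates the patient to Ensemble 2 (which additionally uses the
expensive stage-2 features) when the stage-1 prediction is uncertain:

    escalate  <=>  p_std > tau_sigma   OR   |p_mean - 0.5| < tau_m

The standard-deviation threshold tau_sigma bounds the tolerable ensemble
disagreement; the "midway" threshold tau_m flags mean probabilities too
close to the 0.5 decision midpoint.  Escalated patients take Ensemble 2's
probability; everyone else keeps Ensemble 1's.

Threshold tuning maximizes a *scaled weighted AUC* on a first validation
set: the cascade's AUC multiplied by w(f; s) = f**(1/s), where f is the
fraction of patients resolved at stage 1 and s in [0.5, 9] scales how hard
the objective penalizes escalation.  A second validation set then picks the
scaling parameter whose learned thresholds give the highest plain AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble_uq import EnsembleModel, UncertaintyPrediction
from .evaluation import roc_auc
from .tabular_io import FeatureTable, SchemaError

# Default search grids: std threshold 0.01..0.20, midway threshold 0.02..0.10
# (both step 0.01), scaling parameter {0.5} + integers 1..9.
DEFAULT_STD_GRID = tuple(np.round(np.arange(0.01, 0.201, 0.01), 2))
DEFAULT_MIDWAY_GRID = tuple(np.round(np.arange(0.02, 0.101, 0.01), 2))
DEFAULT_SCALING_GRID = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass(frozen=True)
class GatePolicy:
    """The two gate thresholds plus the scaling parameter they were tuned under."""

    std_threshold: float
    midway_threshold: float
    scaling_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.std_threshold < 0:
            raise ValueError("std_threshold must be >= 0")
        if not 0.0 <= self.midway_threshold <= 0.5:
            raise ValueError("midway_threshold must lie in [0, 0.5]")
        if not 0.5 <= self.scaling_weight <= 9.0:
            raise ValueError("scaling_weight must lie in [0.5, 9]")

    def to_json(self) -> dict:
        return {"std_threshold": float(self.std_threshold),
                "midway_threshold": float(self.midway_threshold),
                "scaling_weight": float(self.scaling_weight)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "GatePolicy":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CohortGateSummary:
    fraction_stage1: float

    @property
    def fraction_stage2(self) -> float:
        return 1.0 - self.fraction_stage1


# ---------------------------------------------------------------------------
# Gate rule
# ---------------------------------------------------------------------------

def gate_decision(pred: UncertaintyPrediction, policy: GatePolicy) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gate rule: returns (needs_stage2, reason) per patient.

    Reasons: 'none', 'high_std', 'near_midway', 'both'.
    """
    high_std = pred.p_std > policy.std_threshold
    near_mid = np.abs(pred.p_mean - 0.5) < policy.midway_threshold
    needs = high_std | near_mid
    reason = np.where(high_std & near_mid, "both",
                      np.where(high_std, "high_std",
                               np.where(near_mid, "near_midway", "none")))
    return needs, reason


# ---------------------------------------------------------------------------
# Tuning objective
# ---------------------------------------------------------------------------

def scaling_weight_fn(f: float, s: float) -> float:
    """Escalation-penalty weight w(f; s) = f**(1/s).

    Monotone nondecreasing in both arguments on [0,1] x [0.5, 9], with
    w(0)=0 and w(1)=1: keeping everyone at stage 1 costs nothing, escalating
    everyone zeroes the objective, and larger s weakens the penalty.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if not 0.5 <= s <= 9.0:
        raise ValueError("s must lie in [0.5, 9]")
    return float(f ** (1.0 / s))


def scaled_weighted_auc(
    labels: Sequence[int],
    cascade_probs: Sequence[float],
    f: float,
    s: float,
) -> float:
    """Cascade AUC multiplied by the stage-1 retention weight w(f; s)."""
    return roc_auc(labels, cascade_probs) * scaling_weight_fn(f, s)


# ---------------------------------------------------------------------------
# Cascade prediction
# ---------------------------------------------------------------------------

def cascade_from_predictions(
    pred1: UncertaintyPrediction,
    pred2: UncertaintyPrediction,
    policy: GatePolicy,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Combine precomputed stage predictions under a gate policy.

    Returns (final_probs, needs_stage2 mask, fraction kept at stage 1).
    """
    needs, _ = gate_decision(pred1, policy)
    probs = np.where(needs, pred2.p_mean, pred1.p_mean)
    f = float(1.0 - needs.mean()) if len(needs) else 1.0
    return probs, needs, f


def predict_cascade(
    ens1: EnsembleModel,
    ens2: EnsembleModel,
    policy: GatePolicy,
    table: FeatureTable,
) -> tuple[pd.DataFrame, CohortGateSummary]:
    """Run the full cascade on a cohort.

    Returns a per-patient frame (final_prob, stage_used, reason) and the
    cohort summary.  Escalated patients require the stage-2 features; if the
    table lacks them, an explicit acquisition-required error lists who.
    """
    pred1 = ens1.predict(table)  # preprocessing selects ens1's own features
    needs, reason = gate_decision(pred1, policy)

    final = pred1.p_mean.copy()
    if needs.any():
        missing = [c for c in ens2.features if c not in table.X.columns]
        if missing:
            ids = list(np.flatnonzero(needs))
            raise SchemaError(
                f"stage-2 acquisition required for patients {ids} but "
                f"features {missing} are absent from the table"
            )
        pred2 = ens2.predict(table)
        final[needs] = pred2.p_mean[needs]

    frame = pd.DataFrame({
        "final_prob": final,
        "stage_used": np.where(needs, 2, 1),
        "reason": reason,
    })
    return frame, CohortGateSummary(fraction_stage1=float(1.0 - needs.mean()))


# ---------------------------------------------------------------------------
# Threshold tuning (validation set 1)
# ---------------------------------------------------------------------------

def tune_thresholds_on_predictions(
    labels: np.ndarray,
    pred1: UncertaintyPrediction,
    pred2: UncertaintyPrediction,
    s: float,
    std_grid: Sequence[float] = DEFAULT_STD_GRID,
    midway_grid: Sequence[float] = DEFAULT_MIDWAY_GRID,
) -> GatePolicy:
    """Exhaustive (tau_sigma, tau_m) grid search maximizing the scaled
    weighted AUC of the cascade.  Ties break toward fewer escalations
    (larger f), then the larger std threshold."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels contain a single class")
    best_key, best_policy = None, None
    for tau_s in std_grid:
        for tau_m in midway_grid:
            policy = GatePolicy(tau_s, tau_m, s)
            probs, _, f = cascade_from_predictions(pred1, pred2, policy)
            obj = scaled_weighted_auc(labels, probs, f, s)
            key = (obj, f, tau_s)
            if best_key is None or key > best_key:
                best_key, best_policy = key, policy
    return best_policy


def tune_thresholds(
    ens1: EnsembleModel,
    ens2: EnsembleModel,
    validation1: FeatureTable,
    s: float,
    std_grid: Sequence[float] = DEFAULT_STD_GRID,
    midway_grid: Sequence[float] = DEFAULT_MIDWAY_GRID,
) -> GatePolicy:
    """Tune the gate thresholds for one scaling parameter on validation set 1."""
    pred1 = ens1.predict(validation1)
    pred2 = ens2.predict(validation1)
    return tune_thresholds_on_predictions(
        validation1.y.to_numpy(), pred1, pred2, s, std_grid, midway_grid)


# ---------------------------------------------------------------------------
# Scaling-parameter selection (validation set 2)
# ---------------------------------------------------------------------------

def select_scaling_on_predictions(
    labels: np.ndarray,
    pred1: UncertaintyPrediction,
    pred2: UncertaintyPrediction,
    candidates: Sequence[GatePolicy],
) -> GatePolicy:
    """Among per-s tuned policies, pick the one whose cascade attains the
    highest PLAIN AUC on validation set 2; ties favour the candidate keeping
    more patients at stage 1."""
    if not candidates:
        raise ValueError("no candidate policies")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels contain a single class")
    best_key, best = None, None
    for policy in candidates:
        probs, _, f = cascade_from_predictions(pred1, pred2, policy)
        key = (roc_auc(labels, probs), f)
        if best_key is None or key > best_key:
            best_key, best = key, policy
    return best


def select_scaling(
    ens1: EnsembleModel,
    ens2: EnsembleModel,
    validation2: FeatureTable,
    candidates: Sequence[GatePolicy],
) -> GatePolicy:
    pred1 = ens1.predict(validation2)
    pred2 = ens2.predict(validation2)
    return select_scaling_on_predictions(
        validation2.y.to_numpy(), pred1, pred2, candidates)
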