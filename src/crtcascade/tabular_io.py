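"""Loading, validation, stage partitioning and preprocessing of patient feature tables.

A cohort arrives as a CSV with one row per patient, a binary outcome column
(1 = responder, 0 = non-responder) and features annotated by acquisition
stage: stage 1 holds the cheap variables (clinical + ECG), stage 2 the
expensive ones (SPECT MPI derived).  The preprocessing recipe is the classic
robust one for penalized linear models on clinical tabular data: centre and
scale each feature on the training rows, then project each sample onto the
unit sphere ("spatial sign") to blunt the influence of outliers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crtcascade")

ValueKind = Literal["continuous", "binary", "categorical"]


class SchemaError(ValueError):
    """A feature schema or cohort table violates its contract."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    kind: ValueKind
    stage: int

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise SchemaError(f"unknown value kind {self.kind!r}")
        if self.stage not in (1, 2):
            raise SchemaError(f"stage must be 1 or 2, got {self.stage!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Maps each feature name to its value kind and acquisition stage."""

    features: dict[str, FeatureDef]
    outcome_name: str

    def __post_init__(self) -> None:
        if self.outcome_name in self.features:
            raise SchemaError(
                f"outcome {self.outcome_name!r} must not be listed among features"
            )
        if not self.features:
            raise SchemaError("schema lists no features")

    def stage_features(self, stage: int) -> list[str]:
        return [n for n, d in self.features.items() if d.stage == stage]

    def require_two_stages(self) -> None:
        """Cascade mode needs at least one feature at each stage."""
        for stage in (1, 2):
            if not self.stage_features(stage):
                raise SchemaError(f"cascade mode requires stage-{stage} features")

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSchema":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        feats = {
            name: FeatureDef(kind=spec["kind"], stage=int(spec["stage"]))
            for name, spec in raw["features"].items()
        }
        return cls(features=feats, outcome_name=raw["outcome"])

    def to_file(self, path: str | Path) -> None:
        raw = {
            "outcome": self.outcome_name,
            "features": {
                n: {"kind": d.kind, "stage": d.stage} for n, d in self.features.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Validated patients-by-features table with a binary outcome vector.

    ``X`` holds the feature columns (categoricals already expanded to
    indicator columns), ``y`` the outcome.  ``stage_of`` maps every column of
    ``X`` to its stage.  ``preprocessed`` records whether the (non-idempotent)
    spatial-sign transform has already been applied, so applying it twice is
    prevented by contract.
    """

    X: pd.DataFrame
    y: pd.Series
    stage_of: dict[str, int]
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise SchemaError("feature matrix and outcome length differ")
        bad = set(self.X.columns) - set(self.stage_of)
        if bad:
            raise SchemaError(f"columns without stage assignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx: Iterable[int]) -> "FeatureTable":
        idx = np.asarray(list(idx))
        return FeatureTable(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y.iloc[idx].reset_index(drop=True),
            stage_of=dict(self.stage_of),
            preprocessed=self.preprocessed,
        )

    def with_columns(self, cols: list[str]) -> "FeatureTable":
        missing = [c for c in cols if c not in self.X.columns]
        if missing:
            raise SchemaError(f"columns absent from table: {missing}")
        return FeatureTable(
            X=self.X[cols].copy(),
            y=self.y,
            stage_of={c: self.stage_of[c] for c in cols},
            preprocessed=self.preprocessed,
        )

    def check_both_classes(self) -> None:
        classes = set(self.y.unique())
        if classes != {0, 1}:
            raise SchemaError(
                f"training partition must contain both outcome classes, got {sorted(classes)}"
            )


def _expand_categoricals(df: pd.DataFrame, schema: FeatureSchema) -> tuple[pd.DataFrame, dict[str, int]]:
    """One-hot expand categorical features, retaining all levels."""
    cols: list[pd.DataFrame | pd.Series] = []
    stage_of: dict[str, int] = {}
    for name, fdef in schema.features.items():
        if fdef.kind == "categorical":
            dummies = pd.get_dummies(df[name].astype(str), prefix=name, dtype=float)
            cols.append(dummies)
            for c in dummies.columns:
                stage_of[c] = fdef.stage
        else:
            cols.append(df[name].astype(float))
            stage_of[name] = fdef.stage
    return pd.concat(cols, axis=1), stage_of


def load_cohort(
    path: str | Path,
    schema: FeatureSchema,
    missing: Literal["error", "drop"] = "error",
) -> FeatureTable:
    """Load and validate a cohort CSV against a schema.

    ``missing='error'`` rejects any row with a missing feature, naming the
    offending row and column; ``missing='drop'`` removes such rows and logs
    the count (mirrors excluding incomplete patients before analysis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return table_from_frame(df, schema, missing=missing)


def table_from_frame(
    df: pd.DataFrame,
    schema: FeatureSchema,
    missing: Literal["error", "drop"] = "error",
) -> FeatureTable:
    """Validate an in-memory DataFrame against a schema (see :func:`load_cohort`)."""
    expected = set(schema.features) | {schema.outcome_name}
    unknown = set(df.columns) - expected
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    absent = expected - set(df.columns)
    if absent:
        raise SchemaError(f"schema columns missing from file: {sorted(absent)}")

    for name in schema.features:
        if df[name].isna().all():
            raise SchemaError(f"feature {name!r} is entirely missing")

    na_mask = df[list(schema.features)].isna()
    if na_mask.any().any():
        if missing == "error":
            row = int(na_mask.any(axis=1).idxmax())
            col = na_mask.loc[row].idxmax()
            raise SchemaError(f"missing value at row {row}, column {col!r}")
        n_before = len(df)
        df = df.loc[~na_mask.any(axis=1)].reset_index(drop=True)
        logger.info("dropped %d rows with missing features", n_before - len(df))

    y_raw = df[schema.outcome_name]
    if y_raw.isna().any():
        raise SchemaError("outcome contains missing values")
    if not set(y_raw.unique()) <= {0, 1}:
        bad = sorted(set(y_raw.unique()) - {0, 1})
        raise SchemaError(f"outcome must be binary 0/1, found {bad}")

    X, stage_of = _expand_categoricals(df, schema)
    return FeatureTable(X=X, y=y_raw.astype(int).rename("outcome"), stage_of=stage_of)


def split_stages(table: FeatureTable, schema: FeatureSchema | None = None) -> tuple[FeatureTable, FeatureTable]:
    """Return (stage-1 view, stage-1+stage-2 view); row order preserved.

    The second view is a strict superset of the first's columns, matching the
    cascade's data access pattern: Ensemble 1 sees cheap features only,
    Ensemble 2 sees everything.
    """
    if schema is not None:
        schema.require_two_stages()
    s1_cols = [c for c in table.feature_names if table.stage_of[c] == 1]
    if not s1_cols or len(s1_cols) == len(table.feature_names):
        raise SchemaError("cascade requires features at both stages")
    return table.with_columns(s1_cols), table.with_columns(table.feature_names)


# ---------------------------------------------------------------------------
# Preprocessing: centre/scale + spatial sign
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    """Per-feature centring/scaling learned on training rows, plus the
    spatial-sign flag.  Zero-variance features are dropped and recorded."""

    mean: dict[str, float]
    std: dict[str, float]
    feature_list: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    spatial_sign: bool = True

    def to_json(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "feature_list": self.feature_list,
            "dropped": self.dropped,
            "spatial_sign": self.spatial_sign,
        }

    @classmethod
    def from_json(cls, raw: dict) -> "PreprocessParams":
        return cls(**raw)


def fit_preprocess(
    table: FeatureTable,
    features: list[str] | None = None,
    spatial_sign: bool = True,
) -> PreprocessParams:
    """Learn centring (mean) and scaling (sample std, n-1 denominator) on
    training rows.  Constant features carry no information for a scaled
    linear model and are excluded with a warning."""
    if table.n < 2:
        raise SchemaError("need at least 2 rows to fit preprocessing")
    features = features or table.feature_names
    missing = [f for f in features if f not in table.X.columns]
    if missing:
        raise SchemaError(f"features absent from table: {missing}")

    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    kept: list[str] = []
    dropped: list[str] = []
    for f in features:
        col = table.X[f].to_numpy(dtype=float)
        s = float(np.std(col, ddof=1))
        if s <= 0.0:
            dropped.append(f)
            continue
        mean[f] = float(np.mean(col))
        std[f] = s
        kept.append(f)
    if dropped:
        warnings.warn(f"zero-variance features dropped: {dropped}", stacklevel=2)
    if not kept:
        raise SchemaError("all features have zero variance")
    return PreprocessParams(mean=mean, std=std, feature_list=kept,
                            dropped=dropped, spatial_sign=spatial_sign)


def apply_preprocess(params: PreprocessParams, table: FeatureTable) -> FeatureTable:
    """Standardize each retained feature, then (if enabled) divide each row by
    its Euclidean norm across the transformed features.

    The sphere projection is not idempotent on re-standardized data, so the
    returned table is flagged ``preprocessed`` and re-application raises.
    """
    if table.preprocessed:
        raise SchemaError("table already preprocessed; transform is not re-applicable")
    missing = [f for f in params.feature_list if f not in table.X.columns]
    if missing:
        raise SchemaError(f"params cover features absent from table: {missing}")

    Z = table.X[params.feature_list].to_numpy(dtype=float).copy()
    mu = np.array([params.mean[f] for f in params.feature_list])
    sd = np.array([params.std[f] for f in params.feature_list])
    Z = (Z - mu) / sd
    if params.spatial_sign:
        norms = np.linalg.norm(Z, axis=1)
        degenerate = norms == 0.0
        if degenerate.any():
            logger.warning("%d all-zero rows left at zero by spatial sign",
                           int(degenerate.sum()))
        norms[degenerate] = 1.0
        Z = Z / norms[:, None]
    out = pd.DataFrame(Z, columns=params.feature_list, index=table.X.index)
    return FeatureTable(
        X=out,
        y=table.y,
        stage_of={c: table.stage_of[c] for c in params.feature_list},
        preprocessed=True,
    )
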