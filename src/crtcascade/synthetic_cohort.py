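"""Synthetic CRT-like cohorts with known ground truth.

Real CRT-response cohorts are small and unshareable, so every pipeline stage
is exercised on generated cohorts that emulate their structure: a binary
response with ~55.5% prevalence, a mix of continuous and binary features
split across a cheap stage 1 (clinical + ECG analogue) and an expensive
stage 2 (SPECT analogue), and — crucially for the gate — an *ambiguous
subgroup*: a fraction rho of patients whose stage-1 linear predictor is
shrunk toward zero (their cheap variables are unremarkable) while the
stage-2 features carry the signal.  On such patients a stage-1 model can
only hover near the decision midpoint, which is exactly the uncertainty the
cascade's gate exploits.

Outcome model:  y ~ Bernoulli(sigmoid(beta0 + x1.beta1 + w2 * x2.beta2)),
with the informative stage-1 values multiplied by ``attenuation`` inside the
subgroup and beta0 calibrated by bisection so the cohort's expected
prevalence hits the target.  By default the stage-2 signal is confined to
the subgroup (w2 = 1 inside, 0 outside): the expensive modality is
incrementally informative exactly for the patients whose cheap data is
insufficient, the regime a staged acquisition policy is designed for.
``stage2_signal_scope='global'`` instead applies beta2 to every row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tabular_io import FeatureDef, FeatureSchema, FeatureTable

# Default effect sizes: moderate clinical signal at stage 1; a decisive
# imaging signal at stage 2.  The staged-acquisition premise is that the
# expensive modality *resolves* the patients whose cheap data is
# uninformative, so the within-subgroup stage-2 discrimination is set high
# (within-subgroup AUC ~0.95).  The raw stage-2 coefficients are inflated by
# ~1/rho on top of that because the signal lives only in the subgroup
# (fraction rho of rows) and a model fitted on the whole mixture dilutes
# them by ~rho.
DEFAULT_BETA1 = (1.0, 0.9, 0.8, 0.7)
DEFAULT_BETA2 = (5.5, 5.0, 4.5, 4.0, 3.5, 3.0)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n: int = 218
    prevalence: float = 0.555
    subgroup_fraction: float = 0.4     # rho
    attenuation: float = 0.0           # stage-1 signal multiplier inside subgroup
    beta1: tuple[float, ...] = DEFAULT_BETA1  # on leading stage-1 continuous feats
    beta2: tuple[float, ...] = DEFAULT_BETA2  # on leading stage-2 continuous feats
    stage1_continuous: int = 8
    stage1_binary: int = 6
    stage2_continuous: int = 24
    stage2_binary: int = 6
    feature_correlation: float = 0.0   # equicorrelation among continuous features
    stage2_signal_scope: str = "subgroup"  # 'subgroup' | 'global'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be >= 20")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.subgroup_fraction <= 1.0:
            raise ValueError("subgroup_fraction must lie in [0, 1]")
        if len(self.beta1) > self.stage1_continuous:
            raise ValueError("more beta1 coefficients than stage-1 continuous features")
        if len(self.beta2) > self.stage2_continuous:
            raise ValueError("more beta2 coefficients than stage-2 continuous features")
        if self.stage2_signal_scope not in ("subgroup", "global"):
            raise ValueError("stage2_signal_scope must be 'subgroup' or 'global'")


@dataclass
class GeneratedCohort:
    table: FeatureTable
    schema: FeatureSchema
    truth: dict
    guideline: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.X.copy()
        df[self.schema.outcome_name] = self.table.y
        return df


def _correlated_normal(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, p))
    if rho > 0.0 and p > 1:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(1 - rho) * z + np.sqrt(rho) * shared
    return z


def _calibrate_intercept(eta_rest: np.ndarray, target: float, tol: float = 0.01) -> float:
    """Bisection on beta0 so mean(sigmoid(beta0 + eta)) hits the target prevalence."""
    lo, hi = -15.0, 15.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta_rest)))))
        if abs(prev - target) < tol:
            return mid
        if prev < target:
            lo = mid
        else:
            hi = mid
    raise ValueError("intercept calibration failed to converge; "
                     "prevalence infeasible under the given coefficients")


def generate(spec: SyntheticCohortSpec, include_guideline: bool = True) -> GeneratedCohort:
    """Generate one cohort; fully deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)

    x1c = _correlated_normal(rng, spec.n, spec.stage1_continuous, spec.feature_correlation)
    x2c = _correlated_normal(rng, spec.n, spec.stage2_continuous, spec.feature_correlation)
    # Binary comorbidity-like features: fixed plausible prevalences, pure noise.
    b1_prev = 0.15 + 0.5 * rng.random(spec.stage1_binary)
    b2_prev = 0.15 + 0.5 * rng.random(spec.stage2_binary)
    x1b = (rng.random((spec.n, spec.stage1_binary)) < b1_prev).astype(float)
    x2b = (rng.random((spec.n, spec.stage2_binary)) < b2_prev).astype(float)

    n_sub = int(np.rint(spec.subgroup_fraction * spec.n))
    subgroup = np.zeros(spec.n, dtype=bool)
    subgroup[rng.choice(spec.n, size=n_sub, replace=False)] = True

    # Shrink the informative stage-1 values inside the subgroup: their cheap
    # variables are unremarkable, so the stage-1 linear predictor collapses.
    k1 = len(spec.beta1)
    x1c[subgroup, :k1] *= spec.attenuation

    beta1 = np.zeros(spec.stage1_continuous)
    beta1[:k1] = spec.beta1
    beta2 = np.zeros(spec.stage2_continuous)
    beta2[: len(spec.beta2)] = spec.beta2

    w2 = np.ones(spec.n)
    if spec.stage2_signal_scope == "subgroup":
        w2 = subgroup.astype(float)
    eta = x1c @ beta1 + w2 * (x2c @ beta2)
    beta0 = _calibrate_intercept(eta, spec.prevalence)
    p = 1.0 / (1.0 + np.exp(-(beta0 + eta)))
    y = (rng.random(spec.n) < p).astype(int)

    cols: dict[str, np.ndarray] = {}
    stage_of: dict[str, int] = {}
    schema_feats: dict[str, FeatureDef] = {}
    for j in range(spec.stage1_continuous):
        name = f"clin_c{j + 1}"
        cols[name] = x1c[:, j]
        stage_of[name] = 1
        schema_feats[name] = FeatureDef("continuous", 1)
    for j in range(spec.stage1_binary):
        name = f"clin_b{j + 1}"
        cols[name] = x1b[:, j]
        stage_of[name] = 1
        schema_feats[name] = FeatureDef("binary", 1)
    for j in range(spec.stage2_continuous):
        name = f"spect_c{j + 1}"
        cols[name] = x2c[:, j]
        stage_of[name] = 2
        schema_feats[name] = FeatureDef("continuous", 2)
    for j in range(spec.stage2_binary):
        name = f"spect_b{j + 1}"
        cols[name] = x2b[:, j]
        stage_of[name] = 2
        schema_feats[name] = FeatureDef("binary", 2)

    table = FeatureTable(X=pd.DataFrame(cols), y=pd.Series(y, name="response"),
                         stage_of=stage_of)
    schema = FeatureSchema(features=schema_feats, outcome_name="response")
    truth = {
        "eta": beta0 + eta,
        "subgroup": subgroup,
        "beta0": beta0,
        "beta1": beta1,
        "beta2": beta2,
        "prob": p,
    }

    guideline = pd.DataFrame()
    if include_guideline:
        # Guideline fields mirroring the cohort's published distributions:
        # LVEF 27.7 +/- 11, QRSd 158.6 +/- 27.2, LBBB ~98%, NYHA II/III/IV.
        guideline = pd.DataFrame({
            "lvef": np.clip(rng.normal(27.7, 11.0, spec.n), 5.0, 95.0),
            "qrsd": np.clip(rng.normal(158.6, 27.2, spec.n), 80.0, 260.0),
            "lbbb": (rng.random(spec.n) < 0.98).astype(int),
            "nyha": rng.choice(["II", "III", "IV"], size=spec.n,
                               p=[0.27, 0.58, 0.15]),
        })

    return GeneratedCohort(table=table, schema=schema, truth=truth,
                           guideline=guideline)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def make_fixture_suite(out_dir: str | Path) -> dict:
    """Write the small synthetic CSV fixtures + schemas used by the tests.

    All fixtures are generated, never hand-entered; the manifest records the
    generator seeds and the properties each fixture is meant to exhibit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"generator_version": 1, "fixtures": {}}

    def write(name: str, cohort: GeneratedCohort, props: dict) -> None:
        cohort.to_frame().to_csv(out / f"{name}.csv", index=False)
        cohort.schema.to_file(out / f"{name}.schema.yaml")
        manifest["fixtures"][name] = {"seed": props.pop("seed"), **props}

    separable = SyntheticCohortSpec(
        n=40, prevalence=0.5, subgroup_fraction=0.0,
        beta1=(4.0, 4.0), beta2=(0.5,),
        stage1_continuous=2, stage1_binary=1, stage2_continuous=2,
        stage2_binary=1, seed=11,
    )
    write("separable", generate(separable, include_guideline=False),
          {"seed": 11, "property": "near-separable at stage 1; ensemble AUC > 0.95"})

    ambiguous = SyntheticCohortSpec(n=218, subgroup_fraction=0.4, seed=13)
    write("ambiguous_subgroup", generate(ambiguous, include_guideline=False),
          {"seed": 13, "property": "rho=0.4 subgroup where only stage 2 informs; "
                                   "mean p_std higher inside subgroup"})

    tiny = SyntheticCohortSpec(
        n=24, prevalence=0.12, subgroup_fraction=0.0, beta1=(0.5,),
        beta2=(0.5,), stage1_continuous=2, stage1_binary=1,
        stage2_continuous=2, stage2_binary=1, seed=17,
    )
    write("rare_class", generate(tiny, include_guideline=False),
          {"seed": 17, "property": "low prevalence: small slices can go single-class"})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
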