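"""The seven candidate classification algorithms behind one fit/score contract.

Algorithms: logistic regression (LogReg); support vector machines with
linear (LSVM), quadratic (QSVM), cubic (CSVM) and Gaussian (GSVM) kernels;
linear discriminant analysis (LDA); and random forest (RF).  Every fitted
model emits a calibrated high-risk probability in [0, 1]:

* features are standardized to zero mean / unit sd using training rows
  only (zero-variance features keep scale 1 so the 110-column manifest
  stays stable);
* margin-based algorithms (the four SVMs) get a Platt-style sigmoid
  probability calibration fitted on internal 3-fold held-out decision
  values; LogReg, LDA and RF emit native probabilities;
* the polynomial kernels are inhomogeneous by default,
  ``(1 + gamma * u.v)^d``, so lower-order terms are representable
  (a homogeneous ``(gamma * u.v)^d`` variant is available by config);
* ``gamma`` defaults to 1/p for p features.

Hyperparameter defaults (box constraint 1, gamma 1/p, 100 trees,
L2-regularized LogReg with strength 1, LDA with automatic shrinkage) are
frozen here so experiments are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    DegenerateTrainingError,
    InvalidSpecError,
    SchemaError,
    UnsupportedParameterError,
)

ALGORITHMS = ("LogReg", "LSVM", "QSVM", "CSVM", "GSVM", "LDA", "RF")
SVM_ALGORITHMS = ("LSVM", "QSVM", "CSVM", "GSVM")
_POLY_DEGREE = {"QSVM": 2, "CSVM": 3}

#: Frozen hyperparameter defaults, overridable per LearnerSpec.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LogReg": {"C": 1.0, "max_iter": 5000},
    "LSVM": {"C": 1.0},
    "QSVM": {"C": 1.0, "gamma": None, "inhomogeneous": True},
    "CSVM": {"C": 1.0, "gamma": None, "inhomogeneous": True},
    "GSVM": {"C": 1.0, "gamma": None},
    "LDA": {"solver": "lsqr", "shrinkage": "auto"},
    "RF": {"n_estimators": 100},
}


@dataclass(frozen=True)
class LearnerSpec:
    """One algorithm plus hyperparameters and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidSpecError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparameters)
        return params


def default_specs(seed: int = 0) -> list[LearnerSpec]:
    """The seven candidate algorithms at their frozen defaults."""
    return [LearnerSpec(a, seed=seed) for a in ALGORITHMS]


def kernel_value(u: np.ndarray, v: np.ndarray, spec: LearnerSpec) -> float:
    """Kernel evaluation for the SVM algorithms.

    linear: u.v; quadratic: (1 + g u.v)^2; cubic: (1 + g u.v)^3;
    Gaussian: exp(-g ||u - v||^2); g defaults to 1/p.
    """
    if spec.algorithm not in SVM_ALGORITHMS:
        raise UnsupportedParameterError(f"{spec.algorithm} has no kernel")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidSpecError("u and v must have the same length")
    params = spec.resolved()
    gamma = params.get("gamma") or 1.0 / u.size
    if spec.algorithm == "LSVM":
        return float(u @ v)
    if spec.algorithm == "GSVM":
        return float(np.exp(-gamma * np.sum((u - v) ** 2)))
    offset = 1.0 if params.get("inhomogeneous", True) else 0.0
    return float((offset + gamma * (u @ v)) ** _POLY_DEGREE[spec.algorithm])


def _build_estimator(spec: LearnerSpec):
    p = spec.resolved()
    alg = spec.algorithm
    if alg == "LogReg":
        return LogisticRegression(C=p["C"], max_iter=p["max_iter"]), False
    if alg == "LDA":
        return LinearDiscriminantAnalysis(solver=p["solver"], shrinkage=p["shrinkage"]), False
    if alg == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], random_state=spec.seed
        ), False
    gamma = p.get("gamma") or "auto"  # sklearn 'auto' == 1/n_features
    if alg == "LSVM":
        return SVC(kernel="linear", C=p["C"]), True
    if alg == "GSVM":
        return SVC(kernel="rbf", C=p["C"], gamma=gamma), True
    coef0 = 1.0 if p.get("inhomogeneous", True) else 0.0
    return SVC(
        kernel="poly", degree=_POLY_DEGREE[alg], gamma=gamma, coef0=coef0, C=p["C"]
    ), True


@dataclass
class TrainedModel:
    """Standardizer + fitted core + probability calibration.

    ``score`` refuses feature tables whose columns do not match the
    training manifest exactly (names and order).
    """

    spec: LearnerSpec
    pipeline: Pipeline
    feature_names: list[str]

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Calibrated high-risk probability per row, in input order."""
        X = _feature_matrix(table, self.feature_names)
        proba = self.pipeline.predict_proba(X)
        col = list(self.pipeline.classes_).index("high")
        return np.clip(proba[:, col], 0.0, 1.0)

    def save(self, directory) -> Path:
        """Persist as versioned JSON metadata + a joblib core file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "algorithm": self.spec.algorithm,
            "hyperparameters": self.spec.resolved(),
            "seed": self.spec.seed,
            "feature_names": self.feature_names,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.pipeline, directory / "core.joblib")
        return directory

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec = LearnerSpec(meta["algorithm"], meta["hyperparameters"], meta["seed"])
        pipeline = joblib.load(directory / "core.joblib")
        return cls(spec, pipeline, meta["feature_names"])


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything except label/pirads)."""
    return [c for c in table.columns if c not in ("label", "pirads")]


def _feature_matrix(table: pd.DataFrame, expected: list[str]) -> np.ndarray:
    got = feature_columns(table)
    if got != expected:
        raise SchemaError(
            "feature columns do not match the model manifest "
            f"(got {len(got)} columns, expected {len(expected)})"
        )
    return table[expected].to_numpy(dtype=float)


def fit(spec: LearnerSpec, table: pd.DataFrame) -> TrainedModel:
    """Fit one algorithm on a feature table with a ``label`` column.

    Standardization parameters are learned from the given rows only.
    SVMs are wrapped in a sigmoid calibration fitted on internal 3-fold
    held-out decision values.  Deterministic given ``spec.seed``.
    """
    labels = table["label"].to_numpy(dtype=object)
    classes = set(labels)
    if len(classes) < 2:
        raise DegenerateTrainingError(f"training data has a single class {classes}")
    names = feature_columns(table)
    X = table[names].to_numpy(dtype=float)

    core, needs_calibration = _build_estimator(spec)
    if needs_calibration:
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed)
        core = CalibratedClassifierCV(core, method="sigmoid", cv=cv)
    pipeline = Pipeline([("standardize", StandardScaler()), ("clf", core)])
    pipeline.fit(X, labels)
    return TrainedModel(spec=spec, pipeline=pipeline, feature_names=names)
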