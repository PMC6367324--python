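"""Study configuration: frozen defaults, optionally overridden from YAML.

The YAML file may contain any of the top-level keys ``features``
(``levels_glcm``, ``levels_hist``), ``cv`` (``folds``, ``runs``,
``base_seed``, ``oversample``), ``learners`` (per-algorithm hyperparameter
maps, e.g. ``learners: {QSVM: {C: 2.0}}``) and ``final``
(``oversample``).  Anything absent keeps its frozen default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .learners import ALGORITHMS, LearnerSpec
from .model_selection import CVPlan


@dataclass(frozen=True)
class StudyConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVPlan = field(default_factory=CVPlan)
    learner_overrides: dict = field(default_factory=dict)
    final_oversample: bool = True

    def learner_specs(self, seed: int = 0) -> list[LearnerSpec]:
        return [
            LearnerSpec(a, dict(self.learner_overrides.get(a, {})), seed=seed)
            for a in ALGORITHMS
        ]


def load_config(path=None) -> StudyConfig:
    """Build a :class:`StudyConfig`, merging a YAML file over the defaults."""
    if path is None:
        return StudyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    feat = raw.get("features", {})
    cv = raw.get("cv", {})
    return StudyConfig(
        features=FeatureConfig(
            levels_glcm=feat.get("levels_glcm", 32),
            levels_hist=feat.get("levels_hist", 64),
        ),
        cv=CVPlan(
            folds=cv.get("folds", 5),
            runs=cv.get("runs", 10),
            stratified=cv.get("stratified", True),
            base_seed=cv.get("base_seed", 0),
            oversample=cv.get("oversample", True),
        ),
        learner_overrides=raw.get("learners", {}),
        final_oversample=raw.get("final", {}).get("oversample", True),
    )
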