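"""Point-based multivariate prognostic models with optional IEL scores.

The 2-point model uses two consensus histological features (bulbous/drop
shaped rete pegs, loss of epithelial cohesion); the 6-point model adds
hyperchromatism, loss of stratification, suprabasal mitoses and nuclear
pleomorphism. Each model is a multivariate Cox PH fit over the 0/1
consensus-feature indicators (unstandardized — they are presence calls)
plus any requested clinical covariates and IEL scores, compared by
in-sample Harrell C-index. No train/test split is applied; all C-indices
are in-sample and are labelled with their exact covariate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ielscore.grading import consensus_features
from ielscore.io_annotations import CohortRecord, HISTOLOGICAL_FEATURES
from ielscore.survival import SurvivalFit, cox_fit, right_censor

__all__ = [
    "TWO_POINT_FEATURES",
    "SIX_POINT_FEATURES",
    "ModelSpec",
    "build_model_frame",
    "fit_point_model",
    "comparison_grid",
]

TWO_POINT_FEATURES = (
    "bulbous_rete_pegs",
    "loss_of_epithelial_cohesion",
)

SIX_POINT_FEATURES = (
    "bulbous_rete_pegs",
    "hyperchromatism",
    "loss_of_epithelial_cohesion",
    "loss_of_stratification",
    "suprabasal_mitoses",
    "nuclear_pleomorphism",
)


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate set: consensus features + clinical/digital terms."""

    name: str
    features: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in HISTOLOGICAL_FEATURES:
                raise ValueError(f"unknown histological feature {f!r}")
        allowed = {"age", "sex", "site", "who", "binary", "iel_c", "iel_pc",
                   "iel_i", "iel_pi"}
        for c in self.covariates:
            if c not in allowed:
                raise ValueError(f"unknown covariate {c!r}")

    @property
    def terms(self) -> list[str]:
        return list(self.features) + list(self.covariates)


def build_model_frame(
    cohort: Sequence[CohortRecord], scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten cohort records (+ optional scores) into a modelling frame.

    Feature votes are resolved to 0/1 by 2-of-3 consensus; slides without
    feature ratings get NaN there. ``scores`` is a DataFrame with a
    ``slide_id`` column (or index) and score columns to merge in.
    """
    rows = []
    for r in cohort:
        d = {
            "slide_id": r.slide_id,
            "age": r.age,
            "sex": r.sex,
            "site": r.site,
            "scanner": r.scanner,
            "who_grade": r.who_grade,
            "binary_grade": r.binary_grade,
            "transformed": r.transformed,
            "months": r.months,
        }
        for feat in HISTOLOGICAL_FEATURES:
            if r.features and feat in r.features:
                d[feat] = consensus_features(r.features[feat])
            else:
                d[feat] = np.nan
        rows.append(d)
    frame = pd.DataFrame(rows)
    if scores is not None:
        scores = scores.reset_index() if scores.index.name == "slide_id" else scores
        frame = frame.merge(scores, on="slide_id", how="left")
    return frame


def fit_point_model(
    frame: pd.DataFrame,
    spec: ModelSpec,
    horizon_months: float = 96.0,
    ties: str = "efron",
) -> SurvivalFit:
    """Fit one point-based prognostic model on a consensus-feature frame.

    Rows lacking any required feature or covariate are excluded. A feature
    that is constant in the cohort is dropped with a warning and recorded in
    the fit's ``dropped`` list.
    """
    needed = spec.terms
    cols = [c for c in frame.columns if c != "slide_id"]
    sub = frame.dropna(subset=[t for t in needed if t in frame.columns])
    si = right_censor(sub[cols], horizon_months=horizon_months)
    features = list(spec.features)
    dropped = []
    for feat in list(features):
        if si.covariates[feat].nunique() <= 1:
            warnings.warn(f"feature {feat!r} is constant in this cohort; dropped",
                          stacklevel=2)
            features.remove(feat)
            dropped.append(feat)
    fit = cox_fit(si, features + list(spec.covariates), ties=ties)
    fit.dropped = dropped
    return fit


def comparison_grid(
    frame: pd.DataFrame, horizon_months: float = 96.0
) -> pd.DataFrame:
    """C-index grid: {2-, 6-point} x {-, clinical, WHO, binary} x {-, IEL-C, IEL-PC}.

    The 8 base specs crossed with {no score, +iel_c, +iel_pc} give 24 cells,
    each labelled with its exact covariate set. Bit-reproducible: the grid is
    a pure function of the frame.
    """
    bases = [
        ("2-point", TWO_POINT_FEATURES, ()),
        ("2-point + age + sex + site", TWO_POINT_FEATURES, ("age", "sex", "site")),
        ("2-point + who", TWO_POINT_FEATURES, ("who",)),
        ("2-point + binary", TWO_POINT_FEATURES, ("binary",)),
        ("6-point", SIX_POINT_FEATURES, ()),
        ("6-point + age + sex + site", SIX_POINT_FEATURES, ("age", "sex", "site")),
        ("6-point + who", SIX_POINT_FEATURES, ("who",)),
        ("6-point + binary", SIX_POINT_FEATURES, ("binary",)),
    ]
    rows = []
    for name, feats, covs in bases:
        for score_name, score in (("", ()), (" + iel_c", ("iel_c",)), (" + iel_pc", ("iel_pc",))):
            spec = ModelSpec(name=name + score_name, features=tuple(feats),
                             covariates=tuple(covs) + score)
            fit = fit_point_model(frame, spec, horizon_months=horizon_months)
            rows.append(
                {
                    "model": spec.name,
                    "covariates": "+".join(spec.terms),
                    "c_index": fit.c_index,
                    "n_events": fit.n_events,
                }
            )
    return pd.DataFrame(rows)
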