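"""Regression design construction: lesion-volume correction and covariates.

Atom scores and the severity outcome are both corrected for total lesion
volume by ordinary-least-squares residualization on ``log1p(volume)``, so
that inferred atom effects are not mere lesion-size effects.  Covariates
follow the severity model: z-scored age and its square, sex (female = 1),
four comorbidity indicators, and log-transformed white-matter
hyperintensity volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ModelInput", "DesignTransform", "residualize_volume",
           "build_model_input", "apply_design_transform", "COMORBIDITIES"]

COMORBIDITIES = ("hypertension", "diabetes", "atrial_fibrillation",
                 "coronary_artery_disease")


@dataclass
class ModelInput:
    """Complete-case design matrix for the hierarchical severity model."""

    outcome: np.ndarray
    atom_scores: np.ndarray = field(repr=False)
    age_z: np.ndarray = field(repr=False)
    age_z_sq: np.ndarray = field(repr=False)
    sex: np.ndarray = field(repr=False)  # female = 1
    hypertension: np.ndarray = field(repr=False)
    diabetes: np.ndarray = field(repr=False)
    atrial_fibrillation: np.ndarray = field(repr=False)
    coronary_artery_disease: np.ndarray = field(repr=False)
    log_wmhv: np.ndarray = field(repr=False)
    stratum: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.outcome)
        for name in ("outcome", "age_z", "age_z_sq", "sex", "hypertension",
                     "diabetes", "atrial_fibrillation",
                     "coronary_artery_disease", "log_wmhv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be a length-{n} vector")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        self.atom_scores = np.asarray(self.atom_scores, dtype=float)
        if self.atom_scores.ndim != 2 or self.atom_scores.shape[0] != n:
            raise ValueError("atom_scores must be (n_patients, n_atoms)")
        if not np.all(np.isfinite(self.atom_scores)):
            raise ValueError("atom_scores contains non-finite values")
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum)
            if self.stratum.shape != (n,):
                raise ValueError("stratum must match outcome length")

    @property
    def n_patients(self) -> int:
        return len(self.outcome)

    @property
    def n_atoms(self) -> int:
        return self.atom_scores.shape[1]

    def covariate_matrix(self) -> np.ndarray:
        """Covariate columns in model order (age, age^2, sex, 4 comorbidities,
        log WMH volume)."""
        return np.column_stack([
            self.age_z, self.age_z_sq, self.sex, self.hypertension,
            self.diabetes, self.atrial_fibrillation,
            self.coronary_artery_disease, self.log_wmhv,
        ])


@dataclass
class DesignTransform:
    """Every parameter of the design-building transform, serializable so
    a transform fitted on one cohort can be reapplied exactly to a
    validation cohort (same age scaling, same volume-regression
    coefficients, same score scales)."""

    age_mean: float
    age_sd: float
    outcome_volume_coef: list  # [intercept, slope] on log1p(volume)
    score_volume_coef: list    # per atom: [intercept, slope]
    score_sds: list
    residualize: bool = True
    standardize_scores: bool = True

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path) -> "DesignTransform":
        return cls(**json.loads(Path(path).read_text()))


def _fit_volume_ols(values: np.ndarray, vol: np.ndarray):
    """OLS of columns on [1, log1p(vol)]; returns (coef, residuals)."""
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    x = np.log1p(vol)
    design = np.column_stack([np.ones_like(x), x])
    if np.ptp(x) == 0:
        logger.warning("constant lesion-volume regressor; mean-centering "
                       "only")
        coef = np.vstack([values.mean(axis=0), np.zeros(values.shape[1])])
    else:
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    if squeeze:
        return coef[:, 0], resid[:, 0]
    return coef, resid


def residualize_volume(values: np.ndarray,
                       lesion_volume_ml: np.ndarray) -> np.ndarray:
    """OLS-residualize columns of ``values`` on ``[1, log1p(volume)]``.

    Returns residuals with (numerically) zero mean and zero correlation
    with the log-volume regressor.  A constant regressor carries no
    volume information; in that case the values are only mean-centered and
    a warning is logged.
    """
    values = np.asarray(values, dtype=float)
    vol = np.asarray(lesion_volume_ml, dtype=float)
    if np.any(vol < 0):
        raise ValueError("lesion volumes must be non-negative")
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    if values.shape[0] != vol.shape[0]:
        raise ValueError("values and lesion_volume_ml lengths differ")
    x = np.log1p(vol)
    if np.ptp(x) == 0:
        logger.warning("constant lesion-volume regressor; mean-centering only")
        resid = values - values.mean(axis=0)
    else:
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ coef
    return resid[:, 0] if squeeze else resid


def _check_complete(cohort: pd.DataFrame, scores: np.ndarray) -> None:
    required = ["sex", "age", "nihss", "lesion_volume_ml", "wmh_volume_ml",
                *COMORBIDITIES]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing columns {missing_cols}")
    if scores.shape[0] != len(cohort):
        raise ValueError("scores rows must match cohort rows")
    na_rows = cohort[required].isna().any(axis=1)
    if na_rows.any():
        ids = (cohort["patient_id"][na_rows].tolist()
               if "patient_id" in cohort.columns
               else cohort.index[na_rows].tolist())
        raise ValueError(
            f"complete-case analysis: missing values for patients {ids}")


def _assemble(cohort: pd.DataFrame, outcome: np.ndarray,
              scores: np.ndarray, age_z: np.ndarray) -> ModelInput:
    return ModelInput(
        outcome=outcome,
        atom_scores=scores,
        age_z=age_z,
        age_z_sq=age_z ** 2,
        sex=cohort["sex"].to_numpy(dtype=float),
        hypertension=cohort["hypertension"].to_numpy(dtype=float),
        diabetes=cohort["diabetes"].to_numpy(dtype=float),
        atrial_fibrillation=cohort["atrial_fibrillation"].to_numpy(dtype=float),
        coronary_artery_disease=cohort["coronary_artery_disease"]
            .to_numpy(dtype=float),
        log_wmhv=np.log1p(cohort["wmh_volume_ml"].to_numpy(dtype=float)),
        stratum=(cohort["stratum"].to_numpy()
                 if "stratum" in cohort.columns else None),
    )


def build_model_input(cohort: pd.DataFrame, scores: np.ndarray,
                      *, standardize_scores: bool = True,
                      residualize: bool = True,
                      return_transform: bool = False):
    """Assemble the severity-model design from a cohort table and atom scores.

    Required cohort columns: ``sex`` (female = 1), ``age``, ``nihss``,
    ``lesion_volume_ml``, ``wmh_volume_ml`` and the four comorbidity
    indicator columns.  Rows with missing values raise an error listing the
    offending patient ids (complete-case contract: nothing is dropped
    silently).

    With ``return_transform=True`` also returns the fitted
    :class:`DesignTransform` (age scaling, volume-regression coefficients,
    score scales) for exact reapplication to a validation cohort via
    :func:`apply_design_transform`.
    """
    scores = np.asarray(scores, dtype=float)
    _check_complete(cohort, scores)

    age = cohort["age"].to_numpy(dtype=float)
    age_mean, age_sd = float(age.mean()), float(age.std())
    if age_sd == 0:
        logger.warning("constant age column; age_z set to zero")
        age_z = np.zeros_like(age)
    else:
        age_z = (age - age_mean) / age_sd
    vol = cohort["lesion_volume_ml"].to_numpy(dtype=float)
    outcome = cohort["nihss"].to_numpy(dtype=float)
    out_coef = np.zeros(2)
    score_coef = np.zeros((2, scores.shape[1]))
    if residualize:
        out_coef, outcome = _fit_volume_ols(outcome, vol)
        score_coef, scores = _fit_volume_ols(scores, vol)
    sds = np.ones(scores.shape[1])
    if standardize_scores:
        sds = scores.std(axis=0)
        sds[sds == 0] = 1.0
        scores = scores / sds

    inp = _assemble(cohort, outcome, scores, age_z)
    if not return_transform:
        return inp
    transform = DesignTransform(
        age_mean=age_mean, age_sd=age_sd,
        outcome_volume_coef=np.asarray(out_coef).tolist(),
        score_volume_coef=np.asarray(score_coef).tolist(),
        score_sds=np.asarray(sds).tolist(),
        residualize=residualize, standardize_scores=standardize_scores)
    return inp, transform


def apply_design_transform(cohort: pd.DataFrame, scores: np.ndarray,
                           transform: DesignTransform) -> ModelInput:
    """Rebuild a model input using a transform fitted on another cohort.

    Applies the stored age scaling, volume-regression coefficients and
    score scales verbatim — nothing is refitted — so a validation cohort
    is processed exactly like the derivation cohort that defined the
    transform.
    """
    scores = np.asarray(scores, dtype=float)
    _check_complete(cohort, scores)

    age = cohort["age"].to_numpy(dtype=float)
    if transform.age_sd == 0:
        age_z = np.zeros_like(age)
    else:
        age_z = (age - transform.age_mean) / transform.age_sd
    vol = cohort["lesion_volume_ml"].to_numpy(dtype=float)
    outcome = cohort["nihss"].to_numpy(dtype=float)
    if transform.residualize:
        design = np.column_stack([np.ones_like(vol), np.log1p(vol)])
        outcome = outcome - design @ np.asarray(transform.outcome_volume_coef)
        scores = scores - design @ np.asarray(transform.score_volume_coef)
    if transform.standardize_scores:
        scores = scores / np.asarray(transform.score_sds)
    return _assemble(cohort, outcome, scores, age_z)
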