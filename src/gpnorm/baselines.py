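"""Reference single-case statistics and evaluation metrics.

Implements the comparison methods the GP z-scores are benchmarked
against: ordinary-least-squares (GLM) prediction, the sample z-score, the
single-case t-test

    t = (mean(controls) - patient) / (sd(controls) * sqrt(1/n + 1))

(a two-sample t with group sizes n and 1), covariate-corrected variants
that residualize both controls and patient with control-estimated
coefficients first, plus ROC/AUC and onset-locked score profiles.

Score orientation: t and z statistics above are signed so that *larger*
means more atrophy for the patient (control mean above patient). GP
deltas use the opposite convention (negative = atrophy), so detection
scores flip the sign of delta before ROC analysis; helpers here take
already-oriented scores where "larger = more diseased".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "SingleCaseResult",
    "RocResult",
    "glm_fit_predict",
    "sample_z",
    "single_case_t",
    "corrected_single_case_t",
    "roc_auc",
    "onset_profile",
]


@dataclass
class SingleCaseResult:
    statistic: float
    method_tag: str
    n_controls: int


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def glm_fit_predict(Xtrain, Ytrain, Xtest) -> np.ndarray:
    """OLS fit with intercept, B = (X'X)^-1 X'Y; predictions = Xtest B.

    Falls back to the pseudoinverse with a warning on rank deficiency.
    """
    Xtrain = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    Xtest = np.atleast_2d(np.asarray(Xtest, dtype=float))
    Y = np.asarray(Ytrain, dtype=float)
    Xa = np.column_stack([np.ones(Xtrain.shape[0]), Xtrain])
    Xb = np.column_stack([np.ones(Xtest.shape[0]), Xtest])
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        import warnings

        warnings.warn("design matrix is rank deficient; using pseudoinverse")
        B = np.linalg.pinv(Xa) @ Y
    else:
        B, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
    return Xb @ B


def sample_z(controls, patient: float) -> SingleCaseResult:
    """z-score of the patient against the control mean and SD.

    Signed so that a patient *below* the control mean gives a positive
    statistic (more atrophy = larger score).
    """
    controls = np.asarray(controls, dtype=float)
    sd = controls.std(ddof=1)
    z = (controls.mean() - float(patient)) / sd if sd > 0 else np.nan
    return SingleCaseResult(statistic=float(z), method_tag="sample_z", n_controls=controls.size)


def single_case_t(controls, patient: float) -> SingleCaseResult:
    """Single-case t comparing one patient against n controls.

    t = (mean_c - patient) / (sd_c * sqrt(1/n + 1)) with the n-1 SD
    denominator; equivalent to the pooled two-sample t with group sizes
    (n, 1). Positive t = patient below the control mean.
    """
    controls = np.asarray(controls, dtype=float)
    n = controls.size
    if n < 2:
        raise ValueError("single-case t needs at least 2 controls")
    sd = controls.std(ddof=1)
    t = (controls.mean() - float(patient)) / (sd * np.sqrt(1.0 / n + 1.0)) if sd > 0 else np.nan
    return SingleCaseResult(statistic=float(t), method_tag="t_raw", n_controls=n)


def corrected_single_case_t(
    controls_y,
    controls_X,
    patient_y: float,
    patient_x,
    columns=None,
    method_tag: str = "t_corrected",
) -> SingleCaseResult:
    """Single-case t after regressing out covariate effects.

    Covariate coefficients are estimated on the controls only (with
    intercept) and applied unchanged to the patient; the t-test is then
    run on the residuals. ``columns`` selects covariate columns (e.g. age
    only for the age-corrected variant).
    """
    controls_y = np.asarray(controls_y, dtype=float)
    controls_X = np.atleast_2d(np.asarray(controls_X, dtype=float))
    patient_x = np.atleast_2d(np.asarray(patient_x, dtype=float))
    if columns is not None:
        controls_X = controls_X[:, columns]
        patient_x = patient_x[:, columns]
    pred_controls = glm_fit_predict(controls_X, controls_y, controls_X)
    pred_patient = glm_fit_predict(controls_X, controls_y, patient_x)
    res = single_case_t(controls_y - pred_controls, float(patient_y) - float(pred_patient[0]))
    return SingleCaseResult(
        statistic=res.statistic, method_tag=method_tag, n_controls=res.n_controls
    )


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC; larger score must mean "more diseased".

    AUC equals the Mann-Whitney rank statistic with midrank tie handling.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_sk_auc(fpr, tpr)))


def onset_profile(
    years_since_onset,
    statistics: dict[str, np.ndarray],
    bin_width: float = 2.0,
    lo: float = -20.0,
    hi: float = 20.0,
) -> pd.DataFrame:
    """Mean statistic per method binned by years since disease onset.

    Bins are ``bin_width``-year intervals over [lo, hi); rows are bin
    centers, columns one per method. Subjects outside the range are
    dropped.
    """
    years = np.asarray(years_since_onset, dtype=float)
    edges = np.arange(lo, hi + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(years, edges) - 1
    rows = {"years_since_onset": centers}
    for tag, vals in statistics.items():
        vals = np.asarray(vals, dtype=float)
        means = np.full(centers.size, np.nan)
        for b in range(centers.size):
            sel = idx == b
            if np.any(sel):
                means[b] = float(np.nanmean(vals[sel]))
        rows[tag] = means
    return pd.DataFrame(rows)
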