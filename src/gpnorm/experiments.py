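"""Simulation experiments: GP-vs-GLM prediction and disease detection.

These workflows tie the trajectory simulator, the GP engine and the
baseline statistics together into the two benchmark comparisons the
toolkit is validated with:

* ``prediction_comparison`` — train on one healthy ensemble, predict an
  independent test ensemble, compare mean absolute error of the GP
  against an ordinary linear model, both using [age, x0, x1, x2].
* ``detection_comparison`` — train a normative GP on a healthy control
  ensemble, score an independent healthy test ensemble and a diseased
  ensemble (post-onset hinge decline), and compare detection AUC of the
  GP z-score delta against the raw and age-corrected single-case t.

Scores handed to ROC analysis are oriented "larger = more diseased"
(delta is sign-flipped; the t statistics are already atrophy-positive).
"""

from __future__ import annotations

import numpy as np

from .baselines import (
    corrected_single_case_t,
    glm_fit_predict,
    onset_profile,
    roc_auc,
    single_case_t,
)
from .gp import FitConfig, fit_gp, gp_predict
from .simulate import EnsembleSpec, get_preset, simulate, simulate_healthy

__all__ = ["prediction_comparison", "detection_comparison", "uncertainty_vs_sample_size"]

# offset separating train/test ensemble seeds within one experiment seed
_TEST_SEED_OFFSET = 100_003

_COVARIATE_COLS = ["age", "x0", "x1", "x2"]


def _fast_fit_config() -> FitConfig:
    # single data-driven start is reliable at the n used here and keeps the
    # many-replicate experiments responsive
    return FitConfig(n_restarts=1, max_iter=100)


def prediction_comparison(
    preset: str = "fig2_large",
    r: float = 0.75,
    n_train: int = 640,
    n_test: int = 640,
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> dict:
    """Test-set MAE of GP and GLM predictions on independent ensembles."""
    corr = np.full(3, r)
    train = simulate_healthy(
        get_preset(preset, n_subjects=n_train, covariate_corr=corr, seed=seed)
    )
    test = simulate_healthy(
        get_preset(preset, n_subjects=n_test, covariate_corr=corr, seed=seed + _TEST_SEED_OFFSET)
    )
    Xtr = train.covariates[_COVARIATE_COLS].to_numpy()
    Xte = test.covariates[_COVARIATE_COLS].to_numpy()

    gp = fit_gp(Xtr, train.observations, fit_config or _fast_fit_config(), seed=seed)
    gp_pred = gp_predict(gp, Xte).mean
    glm_pred = glm_fit_predict(Xtr, train.observations, Xte)
    return {
        "mae_gp": float(np.mean(np.abs(test.observations - gp_pred))),
        "mae_glm": float(np.mean(np.abs(test.observations - glm_pred))),
        "n_train": n_train,
        "n_test": n_test,
        "r": r,
    }


def detection_comparison(
    r: float = 0.75,
    n: int = 640,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    profile: bool = False,
) -> dict:
    """Detection of post-onset diseased subjects: GP delta vs single-case t.

    The control ensemble (GP training sample and t-test control group)
    and the healthy test ensemble share the diseased ensemble's pre-onset
    trajectory law. AUC discriminates post-onset diseased subjects from
    healthy test subjects; pre-onset diseased subjects are summarized
    separately (their mean delta should be near zero).
    """
    corr = np.full(3, r)
    disease_spec = get_preset("fig3_disease", n_subjects=n, covariate_corr=corr, seed=seed + 2 * _TEST_SEED_OFFSET)
    healthy_like = EnsembleSpec(
        n_subjects=n,
        theta2_mean=disease_spec.theta2_mean[:3],
        theta1_var=disease_spec.theta1_var[:3],
        noise_var=disease_spec.noise_var,
        covariate_corr=corr,
        seed=seed,
    )
    controls = simulate(healthy_like)
    healthy_test = simulate(
        EnsembleSpec(**{**healthy_like.to_dict(), "seed": seed + _TEST_SEED_OFFSET})
    )
    diseased = simulate(disease_spec)

    Xc = controls.covariates[_COVARIATE_COLS].to_numpy()
    gp = fit_gp(Xc, controls.observations, fit_config or _fast_fit_config(), seed=seed)

    def gp_delta(cohort):
        X = cohort.covariates[_COVARIATE_COLS].to_numpy()
        return gp_predict(gp, X, ystar=cohort.observations).z

    def t_stats(cohort, columns):
        out = np.empty(cohort.n)
        for i in range(cohort.n):
            if columns is None:
                out[i] = single_case_t(controls.observations, cohort.observations[i]).statistic
            else:
                out[i] = corrected_single_case_t(
                    controls.observations,
                    Xc,
                    cohort.observations[i],
                    cohort.covariates[_COVARIATE_COLS].to_numpy()[i],
                    columns=columns,
                ).statistic
        return out

    delta_h, delta_d = gp_delta(healthy_test), gp_delta(diseased)
    t_h, t_d = t_stats(healthy_test, None), t_stats(diseased, None)
    ta_h, ta_d = t_stats(healthy_test, [0]), t_stats(diseased, [0])

    post = diseased.years_since_onset > 0
    labels = np.concatenate([np.zeros(healthy_test.n), np.ones(int(post.sum()))])

    def auc_of(h_scores, d_scores):
        return roc_auc(np.concatenate([h_scores, d_scores[post]]), labels).auc

    from scipy.stats import ks_2samp

    # pre-onset diseased subjects follow the healthy trajectory law exactly,
    # but they are conditioned on being scanned before onset (younger); give
    # the healthy cohort pseudo-onsets drawn from the same onset law so that
    # the two groups are age-matched before comparing score distributions
    rng = np.random.default_rng(seed + 3 * _TEST_SEED_OFFSET)
    pseudo_onset = rng.normal(
        disease_spec.theta2_mean[4], np.sqrt(disease_spec.theta1_var[4]), healthy_test.n
    )
    h_pre = healthy_test.ages < pseudo_onset

    def pre_onset_p(h_scores, d_scores):
        if not np.any(~post) or not np.any(h_pre):
            return np.nan
        return float(ks_2samp(h_scores[h_pre], d_scores[~post]).pvalue)

    result = {
        "auc_delta": auc_of(-delta_h, -delta_d),
        "auc_t_raw": auc_of(t_h, t_d),
        "auc_t_age": auc_of(ta_h, ta_d),
        "mean_delta_pre_onset": float(delta_d[~post].mean()) if np.any(~post) else np.nan,
        "mean_delta_healthy": float(delta_h.mean()),
        "p_pre_delta": pre_onset_p(delta_h, delta_d),
        "p_pre_t_raw": pre_onset_p(t_h, t_d),
        "p_pre_t_age": pre_onset_p(ta_h, ta_d),
        "n_post_onset": int(post.sum()),
        "r": r,
    }
    if profile:
        result["profile"] = onset_profile(
            diseased.years_since_onset,
            {"delta": delta_d, "t_raw": t_d, "t_age": ta_d},
        )
    return result


def uncertainty_vs_sample_size(
    sizes=(40, 80, 160, 320, 640),
    n_test: int = 100,
    repeats: int = 3,
    seed: int = 0,
    fit_config: FitConfig | None = None,
):
    """Mean and across-subject std of predictive uncertainty vs train size.

    Refits the GP on random training subsamples of a healthy ensemble and
    predicts sqrt-uncertainty u for a fixed held-out test cohort; larger
    training samples should mainly shrink the subject-to-subject spread
    of u while its average changes comparatively little.
    """
    import pandas as pd

    n_full = int(max(sizes))
    train = simulate_healthy(
        get_preset("fig2_large", n_subjects=n_full, seed=seed)
    )
    test = simulate_healthy(
        get_preset("fig2_large", n_subjects=n_test, seed=seed + _TEST_SEED_OFFSET)
    )
    Xtr = train.covariates[_COVARIATE_COLS].to_numpy()
    Xte = test.covariates[_COVARIATE_COLS].to_numpy()
    fc = fit_config or _fast_fit_config()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        size = int(size)
        mean_us, std_us = [], []
        n_rep = 1 if size == n_full else repeats
        for rep in range(n_rep):
            idx = (
                np.arange(n_full)
                if size == n_full
                else rng.choice(n_full, size=size, replace=False)
            )
            gp = fit_gp(Xtr[idx], train.observations[idx], fc, seed=seed + rep)
            u = np.sqrt(gp_predict(gp, Xte).observation_variance)
            mean_us.append(float(u.mean()))
            std_us.append(float(u.std()))
        rows.append({"size": size, "mean_u": float(np.mean(mean_us)), "std_u": float(np.mean(std_us))})
    return pd.DataFrame(rows)
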