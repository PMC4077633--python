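"""Ground-truth simulator of lifespan gray-matter trajectory ensembles.

A two-level mixed-effects model generates individual quadratic volume
trajectories and samples each subject cross-sectionally once:

    level 1:  y_i = f(t_i, theta_i) + eps_i,   eps_i ~ N(0, noise_var)
              f(t, theta) = theta_0 + theta_1 t + theta_2 t^2
                            [+ theta_3 * max(0, t - theta_4)]   (disease)
    level 2:  theta_i ~ N(theta_mean, diag(theta_var))

The optional hinge term adds a linear decline with per-subject slope
theta_3 after a random per-subject onset age theta_4; before onset the
trajectory law is exactly the healthy one.

Covariates x_k supplied to the normative models are constructed to
correlate with the true change parameters at a controlled level r:

    x_k = r * standardize(theta_k) + sqrt(1 - r^2) * N(0, 1)

(with x_k = standardize(theta_k) exactly at r = 1). Age is always an
observed covariate.

Presets ``fig2_large``, ``fig2_small`` and ``fig3_disease`` carry the
canonical healthy (large/small individual differences) and diseased
ensemble parameterizations used throughout the test suite; ages are drawn
uniformly over the adult lifespan [20, 90] years, volumes are in
arbitrary modulated-volume units around 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleSpec",
    "SimulatedCohort",
    "PRESETS",
    "get_preset",
    "simulate_healthy",
    "simulate_diseased",
    "simulate",
    "correlated_covariates",
    "export_cohort_as_images",
]


@dataclass
class EnsembleSpec:
    """Full parameterization of the two-level trajectory ensemble.

    ``theta2_mean`` / ``theta1_var`` are ordered [intercept, linear,
    quadratic] and, when ``disease`` is set, extended with [disease slope,
    onset age]. ``covariate_corr`` gives the target corr(x_k, theta_k) for
    the first three parameters. The onset entry of ``theta1_var`` is a
    variance (onset SD ~ 4.47 years for the disease preset).
    """

    n_subjects: int = 640
    theta2_mean: np.ndarray = field(default_factory=lambda: np.array([0.92, 4e-3, 1e-4]))
    theta1_var: np.ndarray = field(default_factory=lambda: np.array([6e-3, 1e-6, 2e-10]))
    noise_var: float = 0.01
    age_range: tuple[float, float] = (20.0, 90.0)
    covariate_corr: np.ndarray = field(default_factory=lambda: np.array([0.75, 0.75, 0.75]))
    disease: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta2_mean = np.asarray(self.theta2_mean, dtype=float)
        self.theta1_var = np.asarray(self.theta1_var, dtype=float)
        self.covariate_corr = np.asarray(self.covariate_corr, dtype=float)
        if self.theta2_mean.shape != self.theta1_var.shape:
            raise ValueError("theta2_mean and theta1_var must have matching shapes")
        expected = 5 if self.disease else 3
        if self.theta2_mean.size != expected:
            raise ValueError(
                f"{'diseased' if self.disease else 'healthy'} ensemble needs "
                f"{expected} trajectory parameters, got {self.theta2_mean.size}"
            )
        if np.any(self.theta1_var < 0) or self.noise_var < 0:
            raise ValueError("variances must be non-negative")
        if np.any((self.covariate_corr < 0) | (self.covariate_corr > 1)):
            raise ValueError("covariate correlations must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range lower bound must be below upper bound")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "theta2_mean": self.theta2_mean.tolist(),
            "theta1_var": self.theta1_var.tolist(),
            "noise_var": self.noise_var,
            "age_range": list(self.age_range),
            "covariate_corr": self.covariate_corr.tolist(),
            "disease": self.disease,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


# Canonical ensemble parameterizations. Healthy: quadratic trajectories with
# large or small individual differences; diseased: healthy law plus a hinge
# decline (mean slope -0.02/yr, mean onset 65 yr, onset variance 20 yr^2).
PRESETS: dict[str, EnsembleSpec] = {
    "fig2_large": EnsembleSpec(
        theta2_mean=np.array([0.92, 4e-3, 1e-4]),
        theta1_var=np.array([6e-3, 1e-6, 2e-10]),
        noise_var=0.01,
    ),
    "fig2_small": EnsembleSpec(
        theta2_mean=np.array([0.92, 4e-3, 1e-4]),
        theta1_var=np.array([6e-4, 1e-7, 2e-11]),
        noise_var=6e-6,
    ),
    "fig3_disease": EnsembleSpec(
        theta2_mean=np.array([0.92, 4e-3, 1e-4, -0.02, 65.0]),
        theta1_var=np.array([6e-3, 1e-6, 2e-10, 1e-4, 20.0]),
        noise_var=2e-5,
        disease=True,
    ),
}


def get_preset(name: str, **overrides) -> EnsembleSpec:
    """Return a copy of a named preset, optionally overriding fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class SimulatedCohort:
    """One cross-sectional draw from an ensemble.

    ``covariates`` holds [age, x0, x1, x2]; ``true_theta`` the hidden
    per-subject trajectory parameters. Diseased cohorts also expose onset
    ages and (signed) years since onset at scan time.
    """

    observations: np.ndarray
    ages: np.ndarray
    covariates: pd.DataFrame
    true_theta: np.ndarray
    spec: EnsembleSpec
    onset_age: np.ndarray | None = None
    years_since_onset: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.observations.size

    def frame(self) -> pd.DataFrame:
        """Covariates plus observation in one table (subject_id indexed)."""
        df = self.covariates.copy()
        df.insert(0, "subject_id", [f"s{i:04d}" for i in range(self.n)])
        df["y"] = self.observations
        if self.onset_age is not None:
            df["onset_age"] = self.onset_age
            df["years_since_onset"] = self.years_since_onset
        return df


def correlated_covariates(true_theta: np.ndarray, target_r, rng, mean=None, sd=None) -> np.ndarray:
    """Covariate columns correlated with true change parameters.

    Each column is ``r * z(theta_k) + sqrt(1-r^2) * N(0,1)``; at r = 1 the
    standardized parameter is returned exactly (no noise path), at r = 0
    the column is independent noise. ``mean``/``sd`` give the ensemble's
    population moments used to standardize theta; the covariate is a
    property of the subject, so the theta -> x map must not depend on
    which cohort the subject was drawn in (sample moments are the
    fallback when population moments are not supplied).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    theta = np.atleast_2d(np.asarray(true_theta, dtype=float))
    target_r = np.asarray(target_r, dtype=float).ravel()
    n, k = theta.shape
    if target_r.size != k:
        raise ValueError("one target correlation per parameter column required")
    mean = theta.mean(axis=0) if mean is None else np.asarray(mean, dtype=float)
    sd = theta.std(axis=0) if sd is None else np.asarray(sd, dtype=float)
    X = np.empty((n, k))
    for j, r in enumerate(target_r):
        s = sd[j] if sd[j] > 0 else 1.0
        z = (theta[:, j] - mean[j]) / s
        if r >= 1.0:
            X[:, j] = z
        else:
            X[:, j] = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return X


def _trajectory(t: np.ndarray, theta: np.ndarray, disease: bool) -> np.ndarray:
    f = theta[:, 0] + theta[:, 1] * t + theta[:, 2] * t**2
    if disease:
        f = f + theta[:, 3] * np.maximum(0.0, t - theta[:, 4])
    return f


def simulate(spec: EnsembleSpec) -> SimulatedCohort:
    """Draw one cohort (healthy or diseased per ``spec.disease``)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    theta = spec.theta2_mean + np.sqrt(spec.theta1_var) * rng.standard_normal(
        (n, spec.theta2_mean.size)
    )
    t = rng.uniform(*spec.age_range, size=n)
    y = _trajectory(t, theta, spec.disease) + np.sqrt(spec.noise_var) * rng.standard_normal(n)
    Xc = correlated_covariates(
        theta[:, :3],
        spec.covariate_corr,
        rng,
        mean=spec.theta2_mean[:3],
        sd=np.sqrt(spec.theta1_var[:3]),
    )
    cov = pd.DataFrame({"age": t, "x0": Xc[:, 0], "x1": Xc[:, 1], "x2": Xc[:, 2]})
    onset = years = None
    if spec.disease:
        onset = theta[:, 4].copy()
        years = t - onset
    return SimulatedCohort(
        observations=y,
        ages=t,
        covariates=cov,
        true_theta=theta,
        spec=spec,
        onset_age=onset,
        years_since_onset=years,
    )


def simulate_healthy(spec: EnsembleSpec) -> SimulatedCohort:
    """Healthy quadratic ensemble (rejects disease-enabled specs)."""
    if spec.disease:
        raise ValueError("spec has disease=True; use simulate_diseased")
    return simulate(spec)


def simulate_diseased(spec: EnsembleSpec) -> SimulatedCohort:
    """Diseased ensemble with the post-onset hinge decline."""
    if not spec.disease:
        raise ValueError("spec has disease=False; use simulate_healthy")
    return simulate(spec)


def export_cohort_as_images(
    cohort: SimulatedCohort,
    out_dir,
    shape: tuple[int, int, int] = (6, 6, 6),
    n_effect_voxels: int = 8,
    voxel_noise_sd: float = 0.02,
    seed: int = 0,
):
    """Write a cohort as a tiny 4-D NIfTI phantom plus a covariate CSV.

    The scalar observation of each subject is replicated into
    ``n_effect_voxels`` voxels (plus independent voxel noise); the
    remaining background voxels carry pure noise around zero, below the
    0.05 mean-intensity mask threshold. Returns the written paths
    (image, covariates, mask).
    """
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    if n_effect_voxels > n_vox:
        raise ValueError("more effect voxels than voxels in the phantom")
    effect_idx = rng.choice(n_vox, size=n_effect_voxels, replace=False)
    effect_mask = np.zeros(n_vox, dtype=bool)
    effect_mask[effect_idx] = True

    data = rng.normal(0.0, voxel_noise_sd, size=(cohort.n, n_vox))
    data[:, effect_mask] += cohort.observations[:, None]
    vol4d = np.transpose(data.reshape((cohort.n, *shape)), (1, 2, 3, 0))

    affine = np.eye(4)
    img_path = out_dir / "phantom_4d.nii"
    nib.save(nib.Nifti1Image(vol4d.astype(np.float64), affine), img_path)
    mask_path = out_dir / "phantom_mask.nii"
    nib.save(
        nib.Nifti1Image(effect_mask.reshape(shape).astype(np.uint8), affine), mask_path
    )
    cov_path = out_dir / "covariates.csv"
    cohort.frame().to_csv(cov_path, index=False)
    return img_path, cov_path, mask_path
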