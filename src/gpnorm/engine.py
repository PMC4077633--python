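"""Mass-univariate normative modeling: one GP per masked voxel.

Training fits, independently for every in-mask voxel, a Box-Cox transform
(training data only) followed by a GP regression of the transformed volume
on the subject covariates. For a new subject the per-voxel predictive
distributions yield a Normative Probability Map (NPM): the z-score

    delta = (y* - predicted mean) / sqrt(predictive uncertainty u^2)

at each voxel, with negative delta meaning less volume than the healthy
normative prediction (atrophy). Three analogous global GPs (total gray
matter, white matter, CSF volume on [age, sex, ticv, fstr]) produce global
z-scores. Per-voxel healthy log-likelihoods can be combined with
user-supplied alternative disease models into a naive-Bayes posterior over
disease states (conditional independence across voxels).

Voxels are statistically independent: each voxel's fit is a pure function
of (X, y_j, seed_j) with seed_j derived from the master seed and the
voxel's linear grid index, so results do not depend on processing order or
chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .boxcox import BoxCoxModel, fit_lambda
from .gp import CovariateMatrix, FitConfig, TrainedGP, fit_gp, gp_predict

__all__ = [
    "EngineConfig",
    "VoxelModelSet",
    "GlobalModelSet",
    "NormativeProbabilityMap",
    "DiseasePosterior",
    "LOCAL_SCHEMA",
    "GLOBAL_SCHEMA",
    "derive_mask",
    "train_voxelwise",
    "compute_npm",
    "train_global",
    "compute_global_z",
    "naive_bayes_posterior",
    "uncertainty_profile",
]

LOCAL_SCHEMA = ["age", "sex", "tgmv", "twmv", "tcsf", "fstr"]
GLOBAL_SCHEMA = ["age", "sex", "ticv", "fstr"]

# voxelwise mask threshold on the training sample-mean volume
MASK_MEAN_THRESHOLD = 0.05


@dataclass
class EngineConfig:
    """Engine-level fit settings.

    ``boxcox`` toggles the per-voxel power transform; ``boxcox_shift`` is
    the positive offset applied when a voxel contains non-positive values
    (modulated volume data can hold zeros inside the mask).
    """

    boxcox: bool = True
    boxcox_shift: float = 1e-4
    fit: FitConfig = field(default_factory=FitConfig)


def _voxel_seed(seed: int, voxel_index: int) -> int:
    return (int(seed) ^ int(voxel_index)) & 0x7FFFFFFF


def derive_mask(Y: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Binary mask of voxels whose training sample mean exceeds 0.05."""
    mean = np.asarray(Y, dtype=float).mean(axis=0)
    return (mean > MASK_MEAN_THRESHOLD).reshape(shape)


@dataclass
class VoxelModelSet:
    """Trained per-voxel models plus the mask that orders them.

    ``models`` follows the row-major linear order of the mask's True
    voxels; each entry is a (TrainedGP, BoxCoxModel-or-None) pair, or None
    where the fit failed. ``evidence_map``/``noise_map`` hold per-voxel log
    evidence and log sigma-hat on the same ordering.
    """

    models: list
    mask: np.ndarray
    covariate_schema: list[str]
    evidence_map: np.ndarray
    noise_map: np.ndarray
    config: EngineConfig
    train_X: pd.DataFrame | None = None
    train_Y: np.ndarray | None = None
    seed: int = 0

    @property
    def n_voxels(self) -> int:
        return len(self.models)

    @property
    def failure_fraction(self) -> float:
        return float(np.mean([m is None for m in self.models])) if self.models else 0.0

    def _fill_volume(self, values: np.ndarray) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = values
        return vol

    def evidence_volume(self) -> np.ndarray:
        return self._fill_volume(self.evidence_map)

    def lambda_volume(self) -> np.ndarray:
        lam = np.array(
            [np.nan if m is None or m[1] is None else m[1].lambda_ for m in self.models]
        )
        return self._fill_volume(lam)


def _covariate_values(X, schema: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = schema if schema is not None else list(X.columns)
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ValueError(f"covariate table is missing columns: {missing}")
        return X[names].to_numpy(dtype=float), list(names)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = schema if schema is not None else [f"x{k}" for k in range(X.shape[1])]
    return X, list(names)


def _fit_one_voxel(y: np.ndarray, X: CovariateMatrix, config: EngineConfig, seed: int):
    """Pure per-voxel fit: optional Box-Cox on training data, then GP."""
    bc = None
    target = np.asarray(y, dtype=float)
    if config.boxcox:
        tmin = float(target.min())
        shift = config.boxcox_shift - tmin if tmin <= 0 else 0.0
        bc = fit_lambda(target, shift=shift)
        target = bc.transform(y)
    model = fit_gp(X, target, config.fit, seed=seed)
    return model, bc


def train_voxelwise(
    Y: np.ndarray,
    X,
    mask: np.ndarray | None = None,
    config: EngineConfig | None = None,
    seed: int = 0,
    schema: list[str] | None = None,
    grid_shape: tuple[int, ...] | None = None,
) -> VoxelModelSet:
    """Train one (Box-Cox, GP) model per in-mask voxel.

    ``Y`` is n_subjects x n_voxels, columns in row-major linear order of
    either the full grid (mask derived or full-grid mask supplied) or of
    the mask's True voxels. With ``mask=None`` the mask is derived by the
    0.05 sample-mean threshold over a grid of ``grid_shape`` (default: a
    flat 1-D grid).
    """
    config = config or EngineConfig()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    values, names = _covariate_values(X, schema)
    if values.shape[0] != Y.shape[0]:
        raise ValueError(
            f"{values.shape[0]} covariate rows but {Y.shape[0]} image rows"
        )

    if mask is None:
        shape = grid_shape if grid_shape is not None else (Y.shape[1],)
        mask = derive_mask(Y, shape)
        Y_masked = Y[:, mask.ravel()]
    else:
        mask = np.asarray(mask).astype(bool)
        if Y.shape[1] == mask.size:
            Y_masked = Y[:, mask.ravel()]
        elif Y.shape[1] == int(mask.sum()):
            Y_masked = Y
        else:
            raise ValueError(
                f"Y has {Y.shape[1]} columns; mask has {mask.size} voxels "
                f"({int(mask.sum())} in-mask)"
            )

    linear_indices = np.flatnonzero(mask.ravel())
    Xc = CovariateMatrix(values, names)
    models: list = []
    evidence = np.full(linear_indices.size, np.nan)
    noise = np.full(linear_indices.size, np.nan)
    n_fail = 0
    for j, lin_idx in enumerate(linear_indices):
        try:
            model, bc = _fit_one_voxel(
                Y_masked[:, j], Xc, config, _voxel_seed(seed, int(lin_idx))
            )
            models.append((model, bc))
            evidence[j] = model.log_evidence
            noise[j] = 0.5 * np.log(model.hyper.noise_variance)
        except Exception as exc:  # per-voxel failure must not kill the run
            models.append(None)
            n_fail += 1
            warnings.warn(f"voxel {lin_idx}: fit failed ({exc})")
    if n_fail:
        warnings.warn(f"{n_fail}/{linear_indices.size} voxel fits failed")

    return VoxelModelSet(
        models=models,
        mask=mask,
        covariate_schema=names,
        evidence_map=evidence,
        noise_map=noise,
        config=config,
        train_X=pd.DataFrame(values, columns=names),
        train_Y=Y_masked,
        seed=seed,
    )


@dataclass
class NormativeProbabilityMap:
    """Per-subject voxelwise z-map and its companion volumes.

    All volumes are NaN outside the mask (never zero, so absent models are
    not conflated with zero deviation). ``z_volume`` equals
    ``prediction_error / sqrt_uncertainty`` elementwise wherever defined.
    Predicted/observed/error values are on the transformed (Box-Cox) scale
    the voxel models were trained on.
    """

    z_volume: np.ndarray
    predicted: np.ndarray
    prediction_error: np.ndarray
    sqrt_uncertainty: np.ndarray
    subject_index: int


def compute_npm(models: VoxelModelSet, Xstar, Ystar: np.ndarray) -> list[NormativeProbabilityMap]:
    """Normative Probability Maps for each test subject.

    ``Ystar`` columns must follow the model set's voxel ordering (full
    grid or in-mask, as at training); observations are Box-Cox-transformed
    with the frozen *training* lambda per voxel.
    """
    values, _ = _covariate_values(Xstar, models.covariate_schema)
    Ystar = np.atleast_2d(np.asarray(Ystar, dtype=float))
    if Ystar.shape[1] == models.mask.size:
        Ystar = Ystar[:, models.mask.ravel()]
    elif Ystar.shape[1] != models.n_voxels:
        raise ValueError(
            f"Ystar has {Ystar.shape[1]} columns; expected {models.n_voxels} "
            f"in-mask or {models.mask.size} full-grid voxels"
        )
    n_test = values.shape[0]
    nv = models.n_voxels
    z = np.full((n_test, nv), np.nan)
    pred = np.full((n_test, nv), np.nan)
    err = np.full((n_test, nv), np.nan)
    squ = np.full((n_test, nv), np.nan)
    for j, entry in enumerate(models.models):
        if entry is None:
            continue
        model, bc = entry
        yj = bc.transform(Ystar[:, j]) if bc is not None else Ystar[:, j]
        res = gp_predict(model, values, ystar=yj)
        z[:, j] = res.z
        pred[:, j] = res.mean
        err[:, j] = yj - res.mean
        squ[:, j] = np.sqrt(res.observation_variance)
    # elementwise identity delta = error / sqrt(u^2), asserted on every output
    assert np.allclose(z[np.isfinite(z)], (err / squ)[np.isfinite(z)], rtol=1e-10)
    out = []
    for i in range(n_test):
        out.append(
            NormativeProbabilityMap(
                z_volume=models._fill_volume(z[i]),
                predicted=models._fill_volume(pred[i]),
                prediction_error=models._fill_volume(err[i]),
                sqrt_uncertainty=models._fill_volume(squ[i]),
                subject_index=i,
            )
        )
    return out


@dataclass
class GlobalModelSet:
    """GPs for the three global tissue volumes on [age, sex, ticv, fstr]."""

    models: dict[str, TrainedGP]
    covariate_schema: list[str] = field(default_factory=lambda: list(GLOBAL_SCHEMA))

    TARGETS = ("tgmv", "twmv", "tcsf")


def _check_ticv(df: pd.DataFrame, rtol: float = 1e-6) -> None:
    if all(c in df.columns for c in ("ticv", "tgmv", "twmv", "tcsf")):
        total = df["tgmv"] + df["twmv"] + df["tcsf"]
        if not np.allclose(df["ticv"], total, rtol=rtol):
            raise ValueError("ticv is inconsistent with tgmv + twmv + tcsf")


def train_global(
    covariates: pd.DataFrame,
    config: FitConfig | None = None,
    seed: int = 0,
) -> GlobalModelSet:
    """Fit the three global-volume GPs from one covariate/volume table.

    The table must contain age, sex, fstr, the three tissue volumes and
    optionally ticv (derived as their sum when absent, validated when
    present). Global targets are modeled without a Box-Cox transform.
    """
    df = covariates.copy()
    if "ticv" not in df.columns:
        df["ticv"] = df["tgmv"] + df["twmv"] + df["tcsf"]
    _check_ticv(df)
    X = df[GLOBAL_SCHEMA]
    models = {}
    for k, target in enumerate(GlobalModelSet.TARGETS):
        models[target] = fit_gp(
            CovariateMatrix(X.to_numpy(dtype=float), list(GLOBAL_SCHEMA)),
            df[target].to_numpy(dtype=float),
            config,
            seed=seed + k,
        )
    return GlobalModelSet(models=models)


def compute_global_z(models: GlobalModelSet, Xstar: pd.DataFrame, global_measures=None) -> pd.DataFrame:
    """z-scores for tgmv/twmv/tcsf of each test subject.

    ``Xstar`` needs the global covariate schema (ticv derived from the
    measures when absent). ``global_measures`` may be a separate table or
    the measures may live in ``Xstar`` itself.
    """
    df = Xstar.copy()
    if global_measures is not None:
        gm = pd.DataFrame(global_measures)
        for c in gm.columns:
            df[c] = np.asarray(gm[c])
    if "ticv" not in df.columns:
        df["ticv"] = df["tgmv"] + df["twmv"] + df["tcsf"]
    _check_ticv(df)
    X = df[GLOBAL_SCHEMA].to_numpy(dtype=float)
    out = {}
    for target, model in models.models.items():
        res = gp_predict(model, X, ystar=df[target].to_numpy(dtype=float))
        out[f"z_{target}"] = res.z
    return pd.DataFrame(out, index=df.index)


@dataclass
class DiseasePosterior:
    """Naive-Bayes posterior over disease states given a scan."""

    priors: dict[str, float]
    log_likelihoods: dict[str, float]
    posterior: dict[str, float]


def naive_bayes_posterior(
    per_state_log_likelihood_maps: dict[str, np.ndarray],
    priors: dict[str, float],
) -> DiseasePosterior:
    """Combine per-voxel log-likelihood maps into a posterior over states.

    Each state's map holds the log-density of the observed voxel values
    under that state's generative model (conditional independence across
    voxels); for the healthy state this is the GP predictive density.
    Computed in log space with max-subtraction for stability.
    """
    states = list(per_state_log_likelihood_maps)
    if set(states) != set(priors):
        raise ValueError("states of likelihood maps and priors differ")
    p = np.array([priors[s] for s in states], dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("priors must sum to 1")
    sizes = {s: np.asarray(v).size for s, v in per_state_log_likelihood_maps.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"states supply different voxel counts: {sizes}")
    totals = {}
    for s in states:
        m = np.asarray(per_state_log_likelihood_maps[s], dtype=float).ravel()
        if not np.all(np.isfinite(m)):
            raise ValueError(f"state {s!r} is missing per-voxel likelihoods (non-finite)")
        totals[s] = float(m.sum())
    logpost = np.log(p) + np.array([totals[s] for s in states])
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    post /= post.sum()
    return DiseasePosterior(
        priors=dict(priors),
        log_likelihoods=totals,
        posterior={s: float(q) for s, q in zip(states, post)},
    )


def healthy_log_likelihood_map(models: VoxelModelSet, xstar_row, ystar_row: np.ndarray) -> np.ndarray:
    """Per-voxel log predictive density of one subject under the healthy GPs."""
    values, _ = _covariate_values(
        pd.DataFrame([xstar_row]) if isinstance(xstar_row, dict) else np.atleast_2d(xstar_row),
        models.covariate_schema,
    )
    ystar_row = np.asarray(ystar_row, dtype=float).ravel()
    if ystar_row.size == models.mask.size:
        ystar_row = ystar_row[models.mask.ravel()]
    out = np.full(models.n_voxels, np.nan)
    for j, entry in enumerate(models.models):
        if entry is None:
            continue
        model, bc = entry
        yj = bc.transform([ystar_row[j]]) if bc is not None else [ystar_row[j]]
        res = gp_predict(model, values, ystar=np.asarray(yj))
        out[j] = stats.norm.logpdf(
            np.asarray(yj)[0], loc=res.mean[0], scale=np.sqrt(res.observation_variance[0])
        )
    return out


def uncertainty_profile(
    models: VoxelModelSet,
    Xstar,
    subsample_sizes,
    repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive-uncertainty statistics versus training sample size.

    For each subsample size the voxel models are refit on a random subset
    of the stored training data and sqrt-uncertainty u is predicted for
    the test subjects; reported are the mean of u and its std across test
    subjects (per-subject u averaged over voxels), averaged over repeats.
    The full sample size is deterministic (no subsampling).
    """
    if models.train_X is None or models.train_Y is None:
        raise ValueError("model set does not carry its training data")
    values, _ = _covariate_values(Xstar, models.covariate_schema)
    n_train = models.train_Y.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for size in subsample_sizes:
        size = int(size)
        if size < 2 or size > n_train:
            raise ValueError(f"subsample size {size} outside [2, {n_train}]")
        mean_us, std_us = [], []
        n_rep = 1 if size == n_train else repeats
        for rep in range(n_rep):
            idx = (
                np.arange(n_train)
                if size == n_train
                else rng.choice(n_train, size=size, replace=False)
            )
            u_subject = np.zeros(values.shape[0])
            n_ok = 0
            for j, entry in enumerate(models.models):
                if entry is None:
                    continue
                model, bc = entry
                y = models.train_Y[idx, j]
                refit, rebc = _fit_one_voxel(
                    y,
                    CovariateMatrix(
                        models.train_X.iloc[idx].to_numpy(dtype=float),
                        models.covariate_schema,
                    ),
                    models.config,
                    _voxel_seed(seed + rep, j),
                )
                res = gp_predict(refit, values)
                u_subject += np.sqrt(res.observation_variance)
                n_ok += 1
            u_subject /= max(n_ok, 1)
            mean_us.append(float(u_subject.mean()))
            std_us.append(float(u_subject.std()))
        rows.append(
            {"size": size, "mean_u": float(np.mean(mean_us)), "std_u": float(np.mean(std_us))}
        )
    return pd.DataFrame(rows)
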