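"""epsilon-SVR regression, the metric suite (R2, RMSE, RPD, RER) and
hybrid-model construction.

Models are RBF-kernel epsilon-SVR pipelines (feature standardization +
libsvm backend) with hyperparameters either fixed or chosen by seeded
k-fold grid search minimizing RMSECV. A hybrid model augments a base-form
calibration set with a chosen number of other-form spectra (optionally
transferred), ordered by SPXY representativeness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .core import Dataset, SpectraSet
from .errors import (
    DataError,
    DegenerateDataError,
    DimensionError,
    ParameterError,
    PartitioningError,
)

__all__ = [
    "MetricsReport",
    "SVRConfig",
    "RegressionModel",
    "HybridSweepRow",
    "rmse",
    "rpd",
    "rer",
    "r2",
    "train_svr",
    "cross_validate",
    "evaluate",
    "build_hybrid",
    "hybrid_sweep",
    "compare_models",
]

RPD_RELIABLE = 2.5  # conventional reliability threshold
RER_GOOD = (3.0, 10.0)  # good practical utility band; above -> high efficiency


# ---------------------------------------------------------------------------
# Metrics


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error between measured and predicted values."""
    y = np.ravel(np.asarray(y, dtype=float))
    yhat = np.ravel(np.asarray(yhat, dtype=float))
    if y.size == 0:
        raise ParameterError("rmse of empty vectors is undefined")
    if y.size != yhat.size:
        raise DimensionError(f"length mismatch: {y.size} vs {yhat.size}")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y_ref: np.ndarray, rmsep: float) -> float:
    """Ratio of the reference-value standard deviation (n-1) to RMSEP."""
    y_ref = np.ravel(np.asarray(y_ref, dtype=float))
    if y_ref.size < 2:
        raise ParameterError("RPD needs at least 2 reference values")
    sd = float(np.std(y_ref, ddof=1))
    if rmsep == 0:
        warnings.warn("RPD with zero RMSEP reported as +inf", RuntimeWarning, stacklevel=2)
        return float("inf")
    return sd / float(rmsep)


def rer(y_ref: np.ndarray, rmsep: float) -> float:
    """Ratio of the reference-value range (max - min) to RMSEP."""
    y_ref = np.ravel(np.asarray(y_ref, dtype=float))
    if y_ref.size < 2:
        raise ParameterError("RER needs at least 2 reference values")
    rng = float(y_ref.max() - y_ref.min())
    if rmsep == 0:
        warnings.warn("RER with zero RMSEP reported as +inf", RuntimeWarning, stacklevel=2)
        return float("inf")
    return rng / float(rmsep)


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSres/SStot."""
    y = np.ravel(np.asarray(y, dtype=float))
    yhat = np.ravel(np.asarray(yhat, dtype=float))
    if y.size < 2 or y.size != yhat.size:
        raise ParameterError("r2 needs >= 2 paired values")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("r2 undefined for constant measured values")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class MetricsReport:
    """Full metric suite for one fitted model."""

    Rc2: float | None = None
    Rcv2: float | None = None
    Rp2: float | None = None
    RMSEC: float | None = None
    RMSECV: float | None = None
    RMSEP: float | None = None
    RPD: float | None = None
    RER: float | None = None
    SD: float | None = None
    Max: float | None = None
    Min: float | None = None

    @property
    def reliable(self) -> bool | None:
        """RPD above the conventional 2.5 reliability threshold."""
        return None if self.RPD is None else bool(self.RPD > RPD_RELIABLE)

    @property
    def utility(self) -> str | None:
        """RER band: 'low' (<3), 'good' (3-10), 'high' (>10)."""
        if self.RER is None:
            return None
        if self.RER < RER_GOOD[0]:
            return "low"
        return "good" if self.RER <= RER_GOOD[1] else "high"

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# SVR


#: exponent grids for the default log2 hyperparameter search
_C_EXPS = tuple(range(-5, 16, 2))
_GAMMA_EXPS = tuple(range(-15, 4, 2))
_EPSILONS = (0.01, 0.05, 0.1)


@dataclass
class SVRConfig:
    """Hyperparameter configuration for epsilon-SVR training.

    Fixed values (``C``, ``gamma``, ``epsilon`` not None) bypass the grid
    search; otherwise a seeded k-fold search over the log2 grids picks the
    RMSECV-minimizing combination.
    """

    kernel: str = "rbf"
    C: float | None = None
    gamma: float | None = None
    epsilon: float | None = None
    C_grid: tuple = tuple(2.0**e for e in _C_EXPS)
    gamma_grid: tuple = tuple(2.0**e for e in _GAMMA_EXPS)
    epsilon_grid: tuple = _EPSILONS
    n_folds: int = 10

    @classmethod
    def coarse(cls, **kwargs) -> "SVRConfig":
        """Coarser grids (log2 steps of 4) for fast sweeps."""
        return cls(
            C_grid=tuple(2.0**e for e in range(-5, 16, 4)),
            gamma_grid=tuple(2.0**e for e in range(-15, 4, 4)),
            epsilon_grid=(0.01, 0.1),
            **kwargs,
        )

    @property
    def is_fixed(self) -> bool:
        return self.C is not None and self.gamma is not None and self.epsilon is not None


@dataclass
class RegressionModel:
    """Fitted epsilon-SVR with its provenance."""

    pipeline: Pipeline
    kernel: str
    C: float
    gamma: float
    epsilon: float
    selected_wavelengths: np.ndarray | None = None
    fit_ids: list[str] | None = None
    seed: int = 0
    metrics: MetricsReport = field(default_factory=MetricsReport)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.ravel(self.pipeline.predict(np.atleast_2d(np.asarray(X, dtype=float))))

    def save_meta(self, path: str) -> None:
        payload = {
            "kernel": self.kernel, "C": self.C, "gamma": self.gamma,
            "epsilon": self.epsilon, "seed": self.seed,
            "selected_wavelengths": None
            if self.selected_wavelengths is None
            else np.asarray(self.selected_wavelengths).tolist(),
            "metrics": self.metrics.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _make_pipeline(kernel: str, C: float, gamma: float, epsilon: float) -> Pipeline:
    svr = SVR(kernel=kernel, C=C, epsilon=epsilon,
              gamma=gamma if kernel == "rbf" else "scale")
    return Pipeline([("scale", StandardScaler()), ("svr", svr)])


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    if X.shape[0] != y.size:
        raise DimensionError(f"{X.shape[0]} rows but {y.size} responses")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in training data")
    return X, y


def _grid_search(X: np.ndarray, y: np.ndarray, config: SVRConfig, seed: int) -> tuple[float, float, float]:
    n = X.shape[0]
    if n < 2 * config.n_folds:
        raise PartitioningError(
            f"{n} samples too few to tune with {config.n_folds}-fold CV"
        )
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    gamma_grid = config.gamma_grid if config.kernel == "rbf" else (1.0,)
    best = (np.inf, None)
    for C in config.C_grid:
        for gamma in gamma_grid:
            for epsilon in config.epsilon_grid:
                press = 0.0
                for train, test in folds:
                    pipe = _make_pipeline(config.kernel, C, gamma, epsilon)
                    pipe.fit(X[train], y[train])
                    resid = y[test] - np.ravel(pipe.predict(X[test]))
                    press += float(resid @ resid)
                score = np.sqrt(press / n)
                if score < best[0]:
                    best = (score, (C, gamma, epsilon))
    return best[1]


def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    config: SVRConfig | None = None,
    seed: int = 0,
    selected_wavelengths: np.ndarray | None = None,
    fit_ids=None,
) -> RegressionModel:
    """Fit an epsilon-SVR on ``X``; tunes hyperparameters unless fixed by config."""
    config = config or SVRConfig()
    X, y = _check_Xy(X, y)
    if config.is_fixed:
        C, gamma, epsilon = config.C, config.gamma, config.epsilon
    else:
        C, gamma, epsilon = _grid_search(X, y, config, seed)
    if min(C, epsilon) <= 0 or (config.kernel == "rbf" and gamma <= 0):
        raise ParameterError("SVR hyperparameters must be positive")
    pipe = _make_pipeline(config.kernel, C, gamma, epsilon)
    pipe.fit(X, y)
    model = RegressionModel(
        pipeline=pipe, kernel=config.kernel, C=float(C), gamma=float(gamma),
        epsilon=float(epsilon), selected_wavelengths=selected_wavelengths,
        fit_ids=None if fit_ids is None else list(fit_ids), seed=seed,
    )
    yc = model.predict(X)
    model.metrics = replace(model.metrics, Rc2=r2(y, yc), RMSEC=rmse(y, yc))
    return model


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_config: SVRConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """(Rcv2, RMSECV) from pooled out-of-fold predictions of a seeded k-fold."""
    config = model_config or SVRConfig()
    X, y = _check_Xy(X, y)
    if X.shape[0] < n_folds:
        raise PartitioningError(f"{X.shape[0]} samples cannot form {n_folds} folds")
    if not config.is_fixed:
        C, gamma, epsilon = _grid_search(X, y, config, seed)
        config = replace(config, C=C, gamma=gamma, epsilon=epsilon)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    yhat = np.empty_like(y)
    for train, test in kf.split(X):
        if train.size < 2:
            raise PartitioningError("cross-validation fold with fewer than 2 training samples")
        pipe = _make_pipeline(config.kernel, config.C, config.gamma, config.epsilon)
        pipe.fit(X[train], y[train])
        yhat[test] = np.ravel(pipe.predict(X[test]))
    return r2(y, yhat), rmse(y, yhat)


def evaluate(model: RegressionModel, X: np.ndarray, y_ref: np.ndarray) -> MetricsReport:
    """Prediction-set metrics (Rp2, RMSEP, RPD, RER) for a fitted model."""
    y_ref = np.ravel(np.asarray(y_ref, dtype=float))
    yhat = model.predict(X)
    rmsep = rmse(y_ref, yhat)
    return replace(
        model.metrics,
        Rp2=r2(y_ref, yhat),
        RMSEP=rmsep,
        RPD=rpd(y_ref, rmsep),
        RER=rer(y_ref, rmsep),
        SD=float(np.std(y_ref, ddof=1)),
        Max=float(y_ref.max()),
        Min=float(y_ref.min()),
    )


# ---------------------------------------------------------------------------
# Hybrid models


@dataclass
class HybridSweepRow:
    k_added: int
    transferred: bool
    metrics: MetricsReport


def _spxy_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    from .sample_selection import spxy_select

    return spxy_select(X, y, X.shape[0])


def build_hybrid(
    base: Dataset,
    added: Dataset,
    k: int,
    transferred: bool = False,
    order: str = "spxy",
    seed: int = 0,
) -> Dataset:
    """Augment the base calibration set with the first ``k`` added-pool rows.

    The added pool is ranked by SPXY representativeness (or shuffled when
    ``order="random"``); augmented sample ids are suffixed with the pool's
    provenance so ids stay unique.
    """
    n_pool = len(added.sample_ids)
    if not 0 <= k <= n_pool:
        raise ParameterError(f"k must be in [0, {n_pool}], got {k}")
    if base.spectra.wavelengths.size != added.spectra.wavelengths.size or not np.allclose(
        base.spectra.wavelengths, added.spectra.wavelengths
    ):
        raise DimensionError("base and added pools are on different band grids")
    if k == 0:
        return Dataset(base.spectra, base.y)
    if n_pool == 1:
        ranked = [0]
    elif order == "spxy":
        ranked = _spxy_order(added.spectra.X, added.y)
    elif order == "random":
        ranked = np.random.default_rng(seed).permutation(n_pool).tolist()
    else:
        raise ParameterError(f"unknown order {order!r}")
    take = ranked[:k]
    tag = "t" if transferred else "r"
    spectra = SpectraSet(
        X=np.vstack([base.spectra.X, added.spectra.X[take]]),
        wavelengths=base.spectra.wavelengths,
        sample_ids=list(base.sample_ids)
        + [f"{added.sample_ids[i]}+{tag}" for i in take],
        form=base.spectra.form,
    )
    return Dataset(spectra, np.concatenate([base.y, added.y[take]]))


def hybrid_sweep(
    base: Dataset,
    added: Dataset,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    k_grid=None,
    transferred: bool = False,
    model_config: SVRConfig | None = None,
    seed: int = 0,
) -> list[HybridSweepRow]:
    """Retrain the model for each augmentation count and report full metrics."""
    if k_grid is None:
        k_grid = list(range(5, 81, 5))
    k_grid = sorted(int(k) for k in k_grid)
    rows = []
    for k in k_grid:
        try:
            hybrid = build_hybrid(base, added, k, transferred=transferred)
            model = train_svr(hybrid.spectra.X, hybrid.y, config=model_config, seed=seed)
            metrics = evaluate(model, eval_X, eval_y)
        except Exception as exc:
            raise type(exc)(f"hybrid sweep k={k}: {exc}") from exc
        rows.append(HybridSweepRow(k_added=k, transferred=transferred, metrics=metrics))
    return rows


def compare_models(a: MetricsReport, b: MetricsReport) -> dict:
    """Percent changes from report ``a`` (before) to ``b`` (after).

    Error metrics (RMSEC/RMSECV/RMSEP) report ``100 * (a - b) / a`` so a
    positive number means the error DECREASED. Goodness metrics (R2 variants,
    RPD, RER) report ``100 * (b - a) / a`` so a positive number means they
    INCREASED. Zero denominators yield None with an 'undefined' flag.
    """
    out: dict = {"convention": "positive = improvement"}
    error_metrics = ("RMSEC", "RMSECV", "RMSEP")
    gain_metrics = ("Rc2", "Rcv2", "Rp2", "RPD", "RER")
    for name in error_metrics + gain_metrics:
        va, vb = getattr(a, name), getattr(b, name)
        if va is None or vb is None:
            continue
        if va == 0:
            out[name] = {"percent_change": None, "undefined": True}
            continue
        signed = 100.0 * (vb - va) / va
        improvement = -signed if name in error_metrics else signed
        out[name] = {
            "before": va,
            "after": vb,
            "percent_change": signed,
            "improvement_percent": improvement,
        }
    return out
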