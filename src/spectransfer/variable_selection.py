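"""Competitive adaptive reweighted sampling (CARS) wavelength screening.

CARS iteratively shrinks the wavelength set: each iteration fits a PLS model
on a Monte-Carlo subsample of the calibration samples, turns absolute
regression coefficients into sampling weights, competitively resamples the
retained variables (weighted bootstrap), and enforces an exponentially
decreasing retention schedule so the retained count shrinks from all
variables down to two. Cross-validated RMSE is tracked per iteration and the
iteration minimizing it defines the selected variable set.

The two-form union rule (`merge_variable_sets`) combines wavelength sets
screened on different physical forms of the same samples, keeping each
wavelength once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .errors import DataError, MappingError, ParameterError, PartitioningError

__all__ = [
    "CARSResult",
    "edf_schedule",
    "cars_run",
    "merge_variable_sets",
    "map_wavelengths_to_bands",
]


@dataclass
class CARSResult:
    """Outcome of one CARS run."""

    n_iterations: int
    retained_sets: list[np.ndarray]  # variable indices per iteration
    rmsecv_curve: np.ndarray
    best_iteration: int  # 0-based position in the curve
    selected: np.ndarray  # indices at best_iteration
    seed: int
    wavelengths: np.ndarray | None = None  # grid, for nm-based reporting

    @property
    def selected_wavelengths(self) -> np.ndarray:
        if self.wavelengths is None:
            raise ParameterError("CARSResult carries no wavelength grid")
        return self.wavelengths[self.selected]

    def to_json(self, path: str) -> None:
        payload = {
            "n_iterations": self.n_iterations,
            "rmsecv_curve": self.rmsecv_curve.tolist(),
            "best_iteration": int(self.best_iteration),
            "selected_indices": self.selected.tolist(),
            "seed": self.seed,
        }
        if self.wavelengths is not None:
            payload["selected_wavelengths"] = self.selected_wavelengths.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def edf_schedule(p: int, N: int) -> np.ndarray:
    """Retained-variable counts per iteration of the exponentially decreasing schedule.

    ``count_i = round(p * a * exp(-k * i))`` with ``a = (p/2)**(1/(N-1))`` and
    ``k = ln(p/2)/(N-1)``, so the first iteration keeps all ``p`` variables and
    the last keeps 2; all counts are clipped to at least 2.
    """
    if p < 2 or N < 2:
        raise ParameterError(f"need p >= 2 and N >= 2, got p={p}, N={N}")
    i = np.arange(1, N + 1, dtype=float)
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    counts = np.rint(p * a * np.exp(-k * i)).astype(int)
    return np.maximum(counts, 2)


def _pls_weights(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """|regression coefficient| per column from a mean-centred PLS fit."""
    n, p = X.shape
    ncomp = int(min(max_components, p, n - 1))
    ncomp = max(ncomp, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X, y)
    return np.abs(np.ravel(pls.coef_))


def _cv_rmse(
    X: np.ndarray, y: np.ndarray, n_folds: int, max_components: int, fold_seed: int
) -> float:
    """Minimum 10-fold RMSECV over the PLS component grid 1..max_components."""
    n, p = X.shape
    if n < n_folds or n // n_folds < 1:
        raise PartitioningError(f"{n} samples cannot form {n_folds} folds")
    min_train = n - int(np.ceil(n / n_folds))
    hi = max(1, int(min(max_components, p, min_train - 1)))
    comp_grid = range(1, hi + 1)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    folds = list(kf.split(X))
    best = np.inf
    for ncomp in comp_grid:
        press = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for train, test in folds:
                pls = PLSRegression(n_components=ncomp, scale=False)
                pls.fit(X[train], y[train])
                resid = y[test] - np.ravel(pls.predict(X[test]))
                press += float(resid @ resid)
        best = min(best, np.sqrt(press / n))
    return best


def cars_run(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 50,
    n_folds: int = 10,
    mc_ratio: float = 0.8,
    seed: int = 0,
    max_components: int = 10,
    wavelengths: np.ndarray | None = None,
) -> CARSResult:
    """Run CARS on calibration spectra ``X`` (samples x variables) against ``y``.

    Per iteration: a Monte-Carlo subsample of ``mc_ratio`` of the samples is
    drawn; PLS on the currently retained variables yields weights
    ``w = |coefficient|``; an adaptive reweighted bootstrap (``len(retained)``
    weighted draws with replacement) scores each variable by how often it is
    drawn; the enforced schedule cut keeps exactly the scheduled count of
    variables, ranked by (bootstrap score, weight). RMSECV on the full
    calibration set is recorded for the retained set of every iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.ravel(np.asarray(y, dtype=float))
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError(f"X {X.shape} and y ({y.size},) are inconsistent")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("CARS inputs must be finite")
    n, p = X.shape
    if n < n_folds or n_folds < 2:
        raise PartitioningError(f"{n} samples cannot form {n_folds} folds")
    if not 0 < mc_ratio <= 1:
        raise ParameterError("mc_ratio must be in (0, 1]")
    schedule = edf_schedule(p, n_iterations)
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31 - 1))
    n_sub = max(int(round(mc_ratio * n)), min(n, n_folds))

    retained = np.arange(p)
    retained_sets: list[np.ndarray] = []
    rmsecv = np.empty(n_iterations)
    for it in range(n_iterations):
        sub = rng.choice(n, size=n_sub, replace=False)
        w = _pls_weights(X[np.ix_(sub, retained)], y[sub], max_components)
        total = w.sum()
        prob = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
        # adaptive reweighted sampling: bootstrap draw frequencies act as
        # competitive scores; the schedule cut keeps the top `count` exactly
        draws = rng.choice(w.size, size=w.size, replace=True, p=prob)
        score = np.bincount(draws, minlength=w.size)
        count = int(min(schedule[it], retained.size))
        order = np.lexsort((np.arange(w.size), -w, -score))
        keep = np.sort(order[:count])
        retained = retained[keep]
        retained_sets.append(retained.copy())
        rmsecv[it] = _cv_rmse(X[:, retained], y, n_folds, max_components, fold_seed)

    best = int(np.argmin(rmsecv))
    return CARSResult(
        n_iterations=n_iterations,
        retained_sets=retained_sets,
        rmsecv_curve=rmsecv,
        best_iteration=best,
        selected=retained_sets[best].copy(),
        seed=seed,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


def merge_variable_sets(set_a, set_b) -> np.ndarray:
    """Union of two wavelength sets, ascending, duplicates removed."""
    return np.union1d(np.asarray(set_a, dtype=float), np.asarray(set_b, dtype=float))


def map_wavelengths_to_bands(wavelengths, grid) -> np.ndarray:
    """Nearest-grid-point band index per wavelength (ties -> lower index).

    Raises :class:`MappingError` for queries farther than one grid step
    outside the grid range. Duplicate indices are collapsed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ParameterError("grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ParameterError("grid must be strictly increasing")
    queries = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    lo_step = grid[1] - grid[0] if grid.size > 1 else np.inf
    hi_step = grid[-1] - grid[-2] if grid.size > 1 else np.inf
    out = []
    for wl in queries:
        if wl < grid[0] - lo_step or wl > grid[-1] + hi_step:
            raise MappingError(
                f"wavelength {wl} nm is more than one grid step outside [{grid[0]}, {grid[-1]}]"
            )
        out.append(int(np.argmin(np.abs(grid - wl))))
    return np.unique(np.asarray(out, dtype=int))
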