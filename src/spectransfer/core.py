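"""Core data containers: spectra matrices and reference-aligned datasets.

A :class:`SpectraSet` is the currency of the whole pipeline: a samples x
wavelengths reflectance matrix (percent reflectance) together with its
wavelength axis, unique sample ids and an optional physical-form label.
A :class:`Dataset` aligns a SpectraSet with reference values (log10 CFU/g)
and optionally carries a calibration/prediction partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DimensionError, ParameterError

CRUSHED = "crushed"
FULL = "full"
_FORMS = (CRUSHED, FULL)


@dataclass
class SpectraSet:
    """Samples x bands reflectance matrix with wavelength axis and ids.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_bands)
        Reflectance in percent (not clamped to [0, 100]).
    wavelengths : ndarray of shape (n_bands,)
        Band-centre wavelengths in nm, strictly increasing.
    sample_ids : sequence of str
        Unique sample labels, one per row.
    form : str or None
        Physical-form label, one of ``{"crushed", "full"}`` or None.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]
    form: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {self.X.shape}")
        if self.X.shape[0] != len(self.sample_ids):
            raise DimensionError(
                f"{self.X.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if self.X.shape[1] != self.wavelengths.size:
            raise DimensionError(
                f"{self.X.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("sample ids must be unique")
        if self.form is not None and self.form not in _FORMS:
            raise ParameterError(f"form must be one of {_FORMS}, got {self.form!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given sample ids (raises on unknown ids)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """New SpectraSet restricted to ``ids``, in the given order."""
        idx = self.index_of(ids)
        return SpectraSet(
            X=self.X[idx].copy(),
            wavelengths=self.wavelengths.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            form=self.form,
        )

    def select_bands(self, band_idx: Sequence[int]) -> "SpectraSet":
        """New SpectraSet restricted to the given band indices (sorted)."""
        band_idx = np.unique(np.asarray(band_idx, dtype=int))
        return SpectraSet(
            X=self.X[:, band_idx].copy(),
            wavelengths=self.wavelengths[band_idx].copy(),
            sample_ids=list(self.sample_ids),
            form=self.form,
        )

    def with_X(self, X: np.ndarray) -> "SpectraSet":
        """Same metadata, new data matrix (shape must match)."""
        X = np.asarray(X, dtype=float)
        if X.shape != self.X.shape:
            raise DimensionError(f"expected shape {self.X.shape}, got {X.shape}")
        return replace(self, X=X)


@dataclass
class Dataset:
    """A SpectraSet aligned with reference values and an optional split."""

    spectra: SpectraSet
    y: np.ndarray
    calibration_ids: list[str] = field(default_factory=list)
    prediction_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or self.y.size != self.spectra.n_samples:
            raise DimensionError(
                f"y has {self.y.size} values for {self.spectra.n_samples} samples"
            )
        known = set(self.spectra.sample_ids)
        stray = [s for s in (*self.calibration_ids, *self.prediction_ids) if s not in known]
        if stray:
            raise AlignmentError(f"partition ids not in dataset: {stray[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    def y_of(self, ids: Sequence[str]) -> np.ndarray:
        return self.y[self.spectra.index_of(ids)]

    def subset(self, ids: Sequence[str]) -> "Dataset":
        return Dataset(self.spectra.subset(ids), self.y_of(ids))

    @property
    def calibration(self) -> "Dataset":
        if not self.calibration_ids:
            raise ParameterError("dataset carries no calibration partition")
        return self.subset(self.calibration_ids)

    @property
    def prediction(self) -> "Dataset":
        if not self.prediction_ids:
            raise ParameterError("dataset carries no prediction partition")
        return self.subset(self.prediction_ids)

    def with_split(self, calibration_ids: Sequence[str], prediction_ids: Sequence[str]) -> "Dataset":
        return Dataset(self.spectra, self.y, list(calibration_ids), list(prediction_ids))
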