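"""Multiplicative scatter correction (MSC).

Each spectrum is regressed (ordinary least squares) on a standard spectrum
— the column mean of the fitting set — and corrected by inverting the fitted
affine relation: ``corrected = (x - intercept) / slope``. The standard
spectrum is frozen at fit time so prediction/transfer spectra are corrected
against the calibration reference rather than their own mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import SpectraSet
from .errors import DegenerateDataError, DimensionError, ParameterError

_SLOPE_TOL = 1e-12


@dataclass
class MSCModel:
    """Fitted MSC state: the reference spectrum and per-sample fit coefficients."""

    reference: np.ndarray
    slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    intercepts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.reference.ndim != 1:
            raise DimensionError("reference spectrum must be 1-D")
        if self.slopes.shape != self.intercepts.shape:
            raise DimensionError("slopes and intercepts must be paired")

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"reference": self.reference.tolist()}, fh)

    @classmethod
    def from_json(cls, path: str) -> "MSCModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(reference=np.asarray(payload["reference"], dtype=float))


def _regress_on_reference(X: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row OLS of x_i on the reference: returns (slopes, intercepts)."""
    ref_centered = reference - reference.mean()
    var = float(ref_centered @ ref_centered)
    if var <= _SLOPE_TOL:
        raise DegenerateDataError("reference spectrum is constant; MSC fit is degenerate")
    X_centered = X - X.mean(axis=1, keepdims=True)
    slopes = X_centered @ ref_centered / var
    intercepts = X.mean(axis=1) - slopes * reference.mean()
    return slopes, intercepts


def msc_fit(spectra: SpectraSet) -> MSCModel:
    """Fit MSC on a spectra set, using its column-mean as the standard spectrum."""
    if spectra.n_samples < 2:
        raise ParameterError("MSC needs at least 2 samples to define a mean reference")
    reference = spectra.X.mean(axis=0)
    slopes, intercepts = _regress_on_reference(spectra.X, reference)
    return MSCModel(reference=reference, slopes=slopes, intercepts=intercepts)


def msc_apply(model: MSCModel, spectra: SpectraSet) -> SpectraSet:
    """Correct spectra against the model's stored reference.

    Coefficients are regressed afresh for the given spectra (new samples are
    corrected with the calibration reference, not their own mean).
    """
    if spectra.n_bands != model.reference.size:
        raise DimensionError(
            f"spectra have {spectra.n_bands} bands, model reference {model.reference.size}"
        )
    slopes, intercepts = _regress_on_reference(spectra.X, model.reference)
    if np.any(np.abs(slopes) < _SLOPE_TOL):
        bad = [spectra.sample_ids[i] for i in np.nonzero(np.abs(slopes) < _SLOPE_TOL)[0]]
        raise DegenerateDataError(f"near-zero MSC slope for samples {bad[:5]}")
    corrected = (spectra.X - intercepts[:, None]) / slopes[:, None]
    return spectra.with_X(corrected)


def msc_fit_apply(spectra: SpectraSet) -> tuple[MSCModel, SpectraSet]:
    """Convenience: fit on ``spectra`` and return (model, corrected spectra)."""
    model = msc_fit(spectra)
    return model, msc_apply(model, spectra)
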