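"""Direct standardization (DS) calibration transfer.

Paired standard spectra measured under the master (host) and slave (target)
conditions are column-centred; the band-to-band transformation matrix is the
truncated-SVD pseudoinverse solution ``F = pinv(S_slave) @ S_master``. The
residual between the raw matrices is a rank-one per-wavelength offset, which
the application step carries via the stored column means:
``X_transferred = (X - slave_mean) @ F + master_mean``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import Dataset
from .errors import DegenerateDataError, DimensionError, ParameterError

__all__ = [
    "CenteredStandardPair",
    "TransferModel",
    "SSNCurve",
    "center_standards",
    "compute_transfer",
    "apply_transfer",
    "optimize_ssn",
]


@dataclass
class CenteredStandardPair:
    """Row-aligned master/slave standard spectra with their centred versions."""

    MS: np.ndarray  # master standards (m x n)
    SS: np.ndarray  # slave standards (m x n)
    Sms: np.ndarray  # column-centred MS
    Sss: np.ndarray  # column-centred SS
    master_mean: np.ndarray
    slave_mean: np.ndarray
    ids: list[str] | None = None


@dataclass
class TransferModel:
    """Fitted DS transformation with centering vectors and provenance."""

    F: np.ndarray  # n x n
    rank: int
    svd_tol: float
    Sss_pinv: np.ndarray
    master_mean: np.ndarray
    slave_mean: np.ndarray
    standard_ids: list[str] | None = None

    @property
    def n_bands(self) -> int:
        return self.F.shape[0]

    def to_json(self, path: str) -> None:
        payload = {
            "F": self.F.tolist(),
            "rank": self.rank,
            "svd_tol": self.svd_tol,
            "master_mean": self.master_mean.tolist(),
            "slave_mean": self.slave_mean.tolist(),
            "standard_ids": self.standard_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "TransferModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        F = np.asarray(d["F"], dtype=float)
        return cls(
            F=F,
            rank=int(d["rank"]),
            svd_tol=float(d["svd_tol"]),
            Sss_pinv=np.full((F.shape[1], 0), np.nan),  # not round-tripped
            master_mean=np.asarray(d["master_mean"], dtype=float),
            slave_mean=np.asarray(d["slave_mean"], dtype=float),
            standard_ids=d.get("standard_ids"),
        )


@dataclass
class SSNCurve:
    """RMSEP as a function of the standard-sample number."""

    candidate_ns: list[int]
    rmsep: np.ndarray
    best_n: int


def center_standards(slave: np.ndarray, master: np.ndarray, ids=None) -> CenteredStandardPair:
    """Column-centre a row-aligned slave/master standard pair."""
    MS = np.atleast_2d(np.asarray(master, dtype=float))
    SS = np.atleast_2d(np.asarray(slave, dtype=float))
    if MS.shape != SS.shape:
        raise DimensionError(f"master {MS.shape} and slave {SS.shape} shapes differ")
    if MS.shape[0] < 2:
        raise ParameterError("need at least 2 standard samples")
    if not (np.all(np.isfinite(MS)) and np.all(np.isfinite(SS))):
        raise DegenerateDataError("standard spectra must be finite")
    master_mean = MS.mean(axis=0)
    slave_mean = SS.mean(axis=0)
    return CenteredStandardPair(
        MS=MS, SS=SS, Sms=MS - master_mean, Sss=SS - slave_mean,
        master_mean=master_mean, slave_mean=slave_mean,
        ids=None if ids is None else list(ids),
    )


def compute_transfer(standards: CenteredStandardPair, svd_tol: float = 1e-6) -> TransferModel:
    """Estimate the DS transformation matrix by truncated-SVD pseudoinverse.

    Singular values below ``svd_tol`` times the largest are discarded; the
    retained rank is recorded. Raises if the centred slave matrix has rank 0
    (all standards identical).
    """
    U, s, Vt = np.linalg.svd(standards.Sss, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise DegenerateDataError("slave standards are identical: zero-rank centred matrix")
    keep = s > svd_tol * s[0]
    rank = int(np.count_nonzero(keep))
    if rank == 0:
        raise DegenerateDataError("no singular value survives the cutoff")
    pinv = Vt[keep].T @ np.diag(1.0 / s[keep]) @ U[:, keep].T
    F = pinv @ standards.Sms
    return TransferModel(
        F=F,
        rank=rank,
        svd_tol=svd_tol,
        Sss_pinv=pinv,
        master_mean=standards.master_mean,
        slave_mean=standards.slave_mean,
        standard_ids=standards.ids,
    )


def apply_transfer(model: TransferModel, X_un: np.ndarray) -> np.ndarray:
    """Transfer unknown slave spectra into the master space.

    ``X_t = (X_un - slave_mean) @ F + master_mean``; the slave standard mean
    maps exactly onto the master standard mean.
    """
    X_un = np.asarray(X_un, dtype=float)
    single = X_un.ndim == 1
    X = np.atleast_2d(X_un)
    if X.shape[1] != model.n_bands:
        raise DimensionError(
            f"spectra have {X.shape[1]} bands, transfer model {model.n_bands}"
        )
    X_t = (X - model.slave_mean) @ model.F + model.master_mean
    return X_t[0] if single else X_t


def fit_transfer(slave: np.ndarray, master: np.ndarray, svd_tol: float = 1e-6, ids=None) -> TransferModel:
    """Convenience: centre a standard pair and compute the transfer in one call."""
    return compute_transfer(center_standards(slave, master, ids=ids), svd_tol=svd_tol)


def optimize_ssn(
    cs: Dataset,
    fs: Dataset,
    scheme: str = "crushed_as_standard",
    method: str = "spxy",
    candidate_ns=None,
    predictor=None,
    svd_tol: float = 1e-6,
) -> SSNCurve:
    """Sweep the standard-sample number and pick the minimum-RMSEP count.

    For each candidate ``n``: select standards from the calibration set of
    the scheme's form, fit the DS transfer on the paired spectra, transfer
    the full-form prediction spectra into the master space, predict with the
    supplied master-model ``predictor`` (a callable mapping spectra matrix ->
    predictions) and record RMSEP on the full-form reference values.
    """
    from .modeling import rmse
    from .sample_selection import pair_standard_sets, select_standards

    if predictor is None:
        raise ParameterError("optimize_ssn requires a fitted master-model predictor")
    cs_cal, fs_cal = cs.calibration, fs.calibration
    if candidate_ns is None:
        candidate_ns = list(range(5, len(cs_cal.sample_ids) + 1, 5))
    candidate_ns = [int(n) for n in candidate_ns]
    n_cal = len(cs_cal.sample_ids)
    bad = [n for n in candidate_ns if not 2 <= n <= n_cal]
    if bad:
        raise ParameterError(f"candidate ns outside [2, {n_cal}]: {bad}")
    fs_pred = fs.prediction
    curve = np.empty(len(candidate_ns))
    for i, n in enumerate(candidate_ns):
        try:
            sel = select_standards(cs_cal, fs_cal, scheme=scheme, method=method, n=n)
            slave, master, ids = pair_standard_sets(sel, cs_cal, fs_cal)
            model = fit_transfer(slave, master, svd_tol=svd_tol, ids=ids)
            X_t = apply_transfer(model, fs_pred.spectra.X)
            curve[i] = rmse(fs_pred.y, predictor(X_t))
        except Exception as exc:
            raise type(exc)(f"SSN candidate n={n}: {exc}") from exc
    best_n = candidate_ns[int(np.argmin(curve))]
    return SSNCurve(candidate_ns=candidate_ns, rmsep=curve, best_n=best_n)
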