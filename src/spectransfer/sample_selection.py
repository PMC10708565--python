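"""Kennard-Stone and SPXY sample-subset selection, random splitting, and
pairing of standard samples across physical forms.

KS greedily picks the pair of samples with the largest Euclidean spectral
distance, then repeatedly adds the candidate whose minimum distance to the
already-selected set is largest. SPXY is the same greedy procedure on a
combined distance: spectral and response distance matrices each normalized
by their maximum and summed. Ties are broken deterministically (lowest index
/ lexicographically smallest pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import Dataset
from .errors import AlignmentError, ParameterError

__all__ = [
    "PairwiseDistanceSet",
    "SplitResult",
    "StandardSetSelection",
    "compute_distances",
    "ks_select",
    "spxy_select",
    "random_split",
    "pair_standard_sets",
]


@dataclass
class PairwiseDistanceSet:
    """Spectral (dx), response (dy) and combined (dxy) distance matrices."""

    dx: np.ndarray
    dy: np.ndarray | None
    dxy: np.ndarray
    Z: int  # number of spectral wave points


@dataclass
class SplitResult:
    calibration_ids: list[str]
    prediction_ids: list[str]
    seed: int


@dataclass
class StandardSetSelection:
    scheme: str  # {"crushed_as_standard", "full_as_standard"}
    indices: list[int]  # positions within the calibration set
    method: str  # {"ks", "spxy"}
    n: int

    def __post_init__(self) -> None:
        if self.scheme not in ("crushed_as_standard", "full_as_standard"):
            raise ParameterError(f"unknown scheme {self.scheme!r}")
        if self.method not in ("ks", "spxy"):
            raise ParameterError(f"unknown method {self.method!r}")
        if len(self.indices) != self.n:
            raise ParameterError("selection size must equal n")


def compute_distances(X: np.ndarray, y: np.ndarray | None = None) -> PairwiseDistanceSet:
    """Pairwise Euclidean spectral distances, optionally combined with
    normalized response distances (|y_p - y_q|).

    If ``max(dy) == 0`` (constant responses), the response term is defined as
    zero and the combined distance degrades to the normalized spectral one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 samples to form pairwise distances")
    dx = squareform(pdist(X, metric="euclidean"))
    max_dx = dx.max()
    if max_dx == 0:
        raise ParameterError("all samples identical: pairwise distances vanish")
    if y is None:
        return PairwiseDistanceSet(dx=dx, dy=None, dxy=dx / max_dx, Z=X.shape[1])
    y = np.ravel(np.asarray(y, dtype=float))
    if y.size != X.shape[0]:
        raise ParameterError("y must align with the rows of X")
    dy = np.abs(y[:, None] - y[None, :])
    max_dy = dy.max()
    dxy = dx / max_dx + (dy / max_dy if max_dy > 0 else 0.0)
    return PairwiseDistanceSet(dx=dx, dy=dy, dxy=dxy, Z=X.shape[1])


def _greedy_maxmin(d: np.ndarray, n: int) -> list[int]:
    """Greedy max-min selection on a distance matrix, deterministic tie-breaks."""
    m = d.shape[0]
    if not 2 <= n <= m:
        raise ParameterError(f"n must be in [2, {m}], got {n}")
    # seed pair: maximum distance; ties -> lexicographically smallest (i, j)
    best = (-1.0, -1, -1)
    for i in range(m):
        for j in range(i + 1, m):
            if d[i, j] > best[0]:
                best = (d[i, j], i, j)
    selected = [best[1], best[2]]
    remaining = [i for i in range(m) if i not in selected]
    while len(selected) < n:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax: first (lowest) index on ties
        selected.append(pick)
        remaining.remove(pick)
    return selected


def ks_select(X: np.ndarray, n: int) -> list[int]:
    """Kennard-Stone selection of ``n`` samples; returns indices in selection order."""
    return _greedy_maxmin(compute_distances(X).dx, n)


def spxy_select(X: np.ndarray, y: np.ndarray, n: int) -> list[int]:
    """SPXY selection (joint X-Y distance) of ``n`` samples, in selection order."""
    return _greedy_maxmin(compute_distances(X, y).dxy, n)


def random_split(ids, seed: int = 0, ratio: tuple[int, int] = (4, 1)) -> SplitResult:
    """Seeded uniform split of ids into calibration:prediction = ratio (default 4:1)."""
    ids = [str(s) for s in ids]
    if len(ids) < sum(ratio):
        raise ParameterError(f"need at least {sum(ratio)} samples for a {ratio[0]}:{ratio[1]} split")
    n = len(ids)
    n_cal = int(round(n * ratio[0] / sum(ratio)))
    n_cal = max(n_cal, n - n_cal)  # calibration never smaller than prediction
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = sorted(perm[:n_cal].tolist())
    pred = sorted(perm[n_cal:].tolist())
    return SplitResult(
        calibration_ids=[ids[i] for i in cal],
        prediction_ids=[ids[i] for i in pred],
        seed=seed,
    )


def select_standards(
    cs_cal: Dataset, fs_cal: Dataset, scheme: str, method: str, n: int
) -> StandardSetSelection:
    """Pick standard-sample indices from the calibration set of the scheme's form."""
    source = cs_cal if scheme == "crushed_as_standard" else fs_cal
    if method == "ks":
        idx = ks_select(source.spectra.X, n)
    elif method == "spxy":
        idx = spxy_select(source.spectra.X, source.y, n)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return StandardSetSelection(scheme=scheme, indices=idx, method=method, n=n)


def pair_standard_sets(
    selection: StandardSetSelection, cs: Dataset, fs: Dataset
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Row-aligned (slave standards, master standards, ids) for the selected samples.

    The crushed form is the master (its model is kept); the full form is the
    slave whose spectra get transferred. The ``selection`` indices refer to
    rows of whichever form the scheme designates as the distance source, but
    the SAME sample ids are extracted from both forms.
    """
    if set(cs.sample_ids) != set(fs.sample_ids):
        raise AlignmentError("crushed and full datasets carry different sample ids")
    source = cs if selection.scheme == "crushed_as_standard" else fs
    ids = [source.sample_ids[i] for i in selection.indices]
    master = cs.spectra.subset(ids).X  # crushed = master/host
    slave = fs.spectra.subset(ids).X  # full = slave/target
    return slave, master, ids
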