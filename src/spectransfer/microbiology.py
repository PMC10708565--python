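"""Plate-count total viable count (TVC) and its log transform.

The two-dilution plate-count rule divides the summed colony count by
``(n1 + 0.1 * n2) * d`` where ``n1``/``n2`` are the plate counts at the
first/second dilution and ``d`` is the first dilution factor. The national
standard uses the plus sign; a minus-sign variant is exposed for auditing
sources that typeset the formula with a minus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["PlateCountRecord", "plate_count_tvc", "log10_tvc", "tvc_from_table"]


@dataclass
class PlateCountRecord:
    """Colony counts with their dilution levels for one sample."""

    counts: list[float]  # colony count per plate
    dilutions: list[int]  # dilution level per plate: 1 = first, 2 = second
    d: float  # dilution factor of the first dilution, e.g. 0.01

    n1: int = field(init=False)
    n2: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.dilutions) or not self.counts:
            raise ParameterError("need one dilution level per plate, at least one plate")
        if any(c < 0 for c in self.counts):
            raise ParameterError("colony counts must be non-negative")
        if any(level not in (1, 2) for level in self.dilutions):
            raise ParameterError("dilution levels must be 1 or 2")
        if not 0 < self.d <= 1:
            raise ParameterError("dilution factor d must be in (0, 1]")
        self.n1 = sum(1 for level in self.dilutions if level == 1)
        self.n2 = sum(1 for level in self.dilutions if level == 2)


def plate_count_tvc(record: PlateCountRecord, sign_convention: str = "gb_plus") -> float:
    """Colonies per gram: ``sum(C) / ((n1 +/- 0.1*n2) * d)``.

    ``gb_plus`` (default) follows the national-standard plus sign;
    ``paper_minus`` applies the minus-sign variant. Both agree when n2 = 0.
    """
    if sign_convention not in ("gb_plus", "paper_minus"):
        raise ParameterError(f"unknown sign convention {sign_convention!r}")
    sign = 1.0 if sign_convention == "gb_plus" else -1.0
    denom = (record.n1 + sign * 0.1 * record.n2) * record.d
    if denom <= 0:
        raise ParameterError(f"non-positive plate-count denominator {denom}")
    return float(sum(record.counts)) / denom


def log10_tvc(N: float) -> float:
    """Base-10 logarithm of colonies per gram."""
    if N <= 0:
        raise ParameterError(f"TVC must be positive to take log10, got {N}")
    return math.log10(N)


def tvc_from_table(counts: pd.DataFrame, d: float = 0.01, sign_convention: str = "gb_plus") -> pd.DataFrame:
    """Per-sample TVC from a table with columns sample_id, plate_count, dilution_level."""
    required = {"sample_id", "plate_count", "dilution_level"}
    if not required.issubset(counts.columns):
        raise ParameterError(f"counts table must have columns {sorted(required)}")
    rows = []
    for sample_id, grp in counts.groupby("sample_id", sort=False):
        record = PlateCountRecord(
            counts=grp["plate_count"].astype(float).tolist(),
            dilutions=grp["dilution_level"].astype(int).tolist(),
            d=d,
        )
        n = plate_count_tvc(record, sign_convention)
        rows.append({"sample_id": sample_id, "tvc_cfu_per_g": n, "log10_tvc": log10_tvc(n)})
    return pd.DataFrame(rows)
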