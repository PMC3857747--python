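"""Comparison statistics for mapped isocenters.

Signed per-axis differences between each mapping method and the
reference isocenter (method - reference, in the x = lateral,
y = anterior-posterior, z = craniocaudal convention), their frequency
histograms, per-patient summary rows, the 3-sigma outlier rule, and the
two-sample variance-ratio F test used to compare method precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose import IsocenterRecord
from .errors import DomainError, ValidationError

__all__ = [
    "DeltaRecord",
    "compute_deltas",
    "delta_histogram",
    "summarize",
    "flag_outliers",
    "variance_f_test",
]

AXES = {"x": 0, "y": 1, "z": 2}
#: Histogram bin widths (mm) per axis; z is wider to keep comparable
#: counts per bin given the larger craniocaudal spread.
DEFAULT_BIN_MM = {"x": 0.5, "y": 0.5, "z": 1.0}
OUTLIER_SIGMA = 3.0


@dataclass
class DeltaRecord:
    """Signed (dx, dy, dz) between a mapped and the reference isocenter
    for one fraction."""

    method: str
    patient: str
    fraction: str
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.delta)):
            raise ValidationError("non-finite delta")


def compute_deltas(records: Sequence[IsocenterRecord],
                   reference_method: str = "reference") -> list[DeltaRecord]:
    """Per fraction and method: mapped minus reference, componentwise."""
    out: list[DeltaRecord] = []
    for rec in records:
        if reference_method not in rec.mapped:
            raise ValidationError(
                f"fraction {rec.fraction!r} lacks the reference method "
                f"{reference_method!r}")
        ref = rec.mapped[reference_method]
        for method, p in rec.mapped.items():
            if method == reference_method:
                continue
            out.append(DeltaRecord(method, rec.patient, rec.fraction, p - ref))
    return out


def _delta_array(deltas: Sequence[DeltaRecord] | np.ndarray) -> np.ndarray:
    if isinstance(deltas, np.ndarray):
        return np.atleast_2d(deltas)
    return np.array([d.delta for d in deltas])


def delta_histogram(deltas: Sequence[DeltaRecord] | np.ndarray, axis: str,
                    bin_mm: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Counts and edges of the signed-difference histogram for one axis,
    with bins centered on zero (axis defaults: 0.5 / 0.5 / 1.0 mm)."""
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {sorted(AXES)}")
    w = DEFAULT_BIN_MM[axis] if bin_mm is None else float(bin_mm)
    if w <= 0:
        raise ValidationError("bin width must be positive")
    vals = _delta_array(deltas)[:, AXES[axis]]
    nb = max(int(np.ceil((np.abs(vals).max() + w / 2) / w)), 1) if vals.size \
        else 1
    edges = w * (np.arange(-nb, nb + 1) + 0.5)
    edges = np.concatenate([[edges[0] - w], edges])
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def summarize(deltas: Sequence[DeltaRecord]) -> pd.DataFrame:
    """Per-patient rows plus a pooled ``All`` row: for each axis the
    mean unsigned difference, max, min and sample (n-1) standard
    deviation of the signed differences."""
    if not deltas:
        raise ValidationError("no delta records")
    methods = {d.method for d in deltas}
    if len(methods) != 1:
        raise ValidationError("summarize expects records of a single method; "
                              "filter by method first")
    groups: dict[str, list[np.ndarray]] = {}
    for d in deltas:
        groups.setdefault(d.patient, []).append(d.delta)
    rows = []

    def _row(name: str, arr: np.ndarray) -> dict:
        if arr.shape[0] < 2:
            raise ValidationError(
                f"group {name!r} has n < 2: standard deviation undefined")
        row: dict = {"patient": name, "n": arr.shape[0]}
        for ax, a in AXES.items():
            v = arr[:, a]
            row[f"{ax}_avg_abs"] = float(np.mean(np.abs(v)))
            row[f"{ax}_max"] = float(v.max())
            row[f"{ax}_min"] = float(v.min())
            row[f"{ax}_sd"] = float(v.std(ddof=1))
        return row

    for patient in sorted(groups):
        rows.append(_row(patient, np.array(groups[patient])))
    rows.append(_row("All", _delta_array(deltas)))
    df = pd.DataFrame(rows)
    df.loc[df.index[-1], "patient"] = "All"
    return df


def flag_outliers(deltas: Sequence[DeltaRecord] | np.ndarray,
                  sigma_clinical: Sequence[float]) -> np.ndarray:
    """True where any axis exceeds ``OUTLIER_SIGMA`` times the clinical
    method's per-axis standard deviation."""
    sig = np.asarray(sigma_clinical, dtype=float).reshape(3)
    if np.any(sig <= 0):
        raise ValidationError("sigma_clinical must be positive")
    arr = _delta_array(deltas)
    return np.any(np.abs(arr) > OUTLIER_SIGMA * sig, axis=1)


def variance_f_test(deltas_a: Sequence[DeltaRecord] | np.ndarray,
                    deltas_b: Sequence[DeltaRecord] | np.ndarray,
                    axis: str = "x") -> tuple[float, float]:
    """Two-sample variance-ratio F test on one axis.

    ``F = s_a^2 / s_b^2`` with ``(n_a - 1, n_b - 1)`` degrees of
    freedom and a two-sided p value; swapping the samples inverts F and
    leaves p unchanged.
    """
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {sorted(AXES)}")
    a = _delta_array(deltas_a)[:, AXES[axis]]
    b = _delta_array(deltas_b)[:, AXES[axis]]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 samples per group")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise DomainError("zero variance in denominator sample")
    F = float(va / vb)
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))
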