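"""Dose placement, model-relative dose mapping, accumulation and DVHs.

The scalar mapping between planning and treatment space assigns to a
point with model coordinates ``(i, j, k)`` in one prostate model the
value found at the *same* model coordinates in the other model.  Run
forward it maps the planned isocenter into the treatment image; run in
reverse it pulls each delivered dose back onto the planning grid.
Only modeled tissue (prostate plus a thin rind) is mapped; dose to
interstitial tissue is left undefined.

Delivered dose is modeled as a rigid translation of the planned dose
grid by the mapped-isocenter shift — the central simplification of this
package: no per-treatment heterogeneity recomputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import DVHCurve, Volume3D
from .errors import DomainError, ValidationError
from .mrep import MRepChain, chain_mask, correspond, surface_distance

__all__ = [
    "DoseGrid",
    "IsocenterRecord",
    "map_isocenter",
    "map_dose_to_planning",
    "place_delivered_dose",
    "accumulate",
    "error_dose",
    "dvh",
]

DEFAULT_BIN_CGY = 10.0
DEFAULT_RIND_MM = 3.0


@dataclass
class DoseGrid:
    """A dose distribution (cGy) on a 3D grid.

    ``defined`` (optional) masks voxels carrying valid dose — model-
    relative mapping leaves unmodeled tissue undefined.  ``kind`` is
    ``"dose"`` for physical dose (non-negative) or ``"error"`` for a
    signed difference distribution.
    """

    volume: Volume3D
    n_fractions: int = 1
    defined: np.ndarray | None = None
    kind: str = "dose"
    flagged_outside: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValidationError("fraction count must be >= 1")
        if self.kind == "dose":
            vals = self.volume.data if self.defined is None \
                else self.volume.data[self.defined]
            if vals.size and np.any(vals < 0):
                raise ValidationError("negative dose in a physical dose grid")
        if self.defined is not None and self.defined.shape != self.volume.shape:
            raise ValidationError("defined-mask shape mismatch")

    def defined_mask(self) -> np.ndarray:
        if self.defined is None:
            return np.ones(self.volume.shape, dtype=bool)
        return self.defined

    def same_grid(self, other: "DoseGrid") -> bool:
        return (self.volume.shape == other.volume.shape
                and np.allclose(self.volume.spacing, other.volume.spacing)
                and np.allclose(self.volume.origin, other.volume.origin))


@dataclass
class IsocenterRecord:
    """Planned isocenter plus per-method mapped isocenters for one
    treatment fraction."""

    patient: str
    fraction: str
    planned: np.ndarray
    mapped: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planned = np.asarray(self.planned, dtype=float).reshape(3)
        clean = {}
        for method, p in self.mapped.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"non-finite isocenter for {method!r}")
            clean[str(method)] = p
        self.mapped = clean


# ---------------------------------------------------------------------------
# Forward mapping: planned isocenter -> treatment space
# ---------------------------------------------------------------------------

def map_isocenter(planned_iso: np.ndarray, planning_chain: MRepChain,
                  treatment_chain: MRepChain) -> np.ndarray:
    """Point in treatment space with the same prostate-relative
    coordinates as the planned isocenter."""
    iso = np.asarray(planned_iso, dtype=float).reshape(3)
    try:
        return correspond(iso, planning_chain, treatment_chain)
    except DomainError as exc:
        d = float(surface_distance(iso, planning_chain)[0])
        raise DomainError(
            f"planned isocenter outside the planning model (+rind); "
            f"distance to surface = {d:.2f} mm") from exc


# ---------------------------------------------------------------------------
# Reverse mapping: treatment dose -> planning grid
# ---------------------------------------------------------------------------

def map_dose_to_planning(tct_dose: DoseGrid, treatment_chain: MRepChain,
                         planning_chain: MRepChain,
                         rind_mm: float = DEFAULT_RIND_MM,
                         planning_grid: Volume3D | None = None) -> DoseGrid:
    """Pull a treatment dose back onto the planning grid through the
    model-relative correspondence, restricted to prostate + rind."""
    if not 0.0 <= rind_mm <= 5.0:
        raise ValidationError("rind thickness must be in [0, 5] mm")
    grid = planning_grid if planning_grid is not None else tct_dose.volume
    pch = planning_chain.with_rind(rind_mm)
    tch = treatment_chain.with_rind(rind_mm)
    mask = chain_mask(pch, grid, include_rind=rind_mm > 0)
    data = np.zeros(grid.shape)
    defined = np.zeros(grid.shape, dtype=bool)
    flagged = 0
    if np.any(mask):
        vox = np.argwhere(mask)
        pts = grid.world(vox)
        from .mrep import correspond_batch

        mapped, ok = correspond_batch(pts, pch, tch)
        in_src = ok & tct_dose.volume.contains(mapped)
        src_def = tct_dose.defined_mask()
        if not np.all(src_def):
            frac = Volume3D(src_def.astype(float), tct_dose.volume.spacing,
                            tct_dose.volume.origin).sample(mapped)
            in_src &= frac > 0.999
        flagged = int(np.count_nonzero(~in_src))
        vals = tct_dose.volume.sample(mapped)
        ok = vox[in_src]
        data[ok[:, 0], ok[:, 1], ok[:, 2]] = vals[in_src]
        defined[ok[:, 0], ok[:, 1], ok[:, 2]] = True
    return DoseGrid(Volume3D(data, grid.spacing.copy(), grid.origin.copy()),
                    n_fractions=tct_dose.n_fractions, defined=defined,
                    kind=tct_dose.kind, flagged_outside=flagged)


# ---------------------------------------------------------------------------
# Placement, accumulation, error dose
# ---------------------------------------------------------------------------

def place_delivered_dose(planned_dose: DoseGrid, planned_iso: np.ndarray,
                         treatment_iso: np.ndarray) -> DoseGrid:
    """Delivered dose = planned dose rigidly translated so the planned
    isocenter lands on the treatment isocenter (exact grid shift)."""
    planned_iso = np.asarray(planned_iso, dtype=float).reshape(3)
    treatment_iso = np.asarray(treatment_iso, dtype=float).reshape(3)
    if not (np.all(np.isfinite(planned_iso)) and np.all(np.isfinite(treatment_iso))):
        raise ValidationError("isocenters must be finite")
    shift = treatment_iso - planned_iso
    vol = Volume3D(planned_dose.volume.data.copy(),
                   planned_dose.volume.spacing.copy(),
                   planned_dose.volume.origin + shift)
    defined = None if planned_dose.defined is None else planned_dose.defined.copy()
    return DoseGrid(vol, n_fractions=planned_dose.n_fractions,
                    defined=defined, kind=planned_dose.kind)


def _resample_to(dose: DoseGrid, grid: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    ax = grid.grid_world()
    P = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = dose.volume.sample(P).reshape(grid.shape)
    inside = dose.volume.contains(P).reshape(grid.shape)
    if dose.defined is not None:
        frac = Volume3D(dose.defined.astype(float), dose.volume.spacing,
                        dose.volume.origin).sample(P).reshape(grid.shape)
        inside &= frac > 0.999
    return vals, inside


def accumulate(mapped_doses: Sequence[DoseGrid], planning_grid: Volume3D) -> DoseGrid:
    """Voxelwise sum of dose grids after trilinear resampling onto the
    planning grid; defined only where every input is defined."""
    if len(mapped_doses) == 0:
        raise ValidationError("nothing to accumulate")
    total = np.zeros(planning_grid.shape)
    defined = np.ones(planning_grid.shape, dtype=bool)
    fractions = 0
    for d in mapped_doses:
        vals, inside = _resample_to(d, planning_grid)
        total += np.where(inside, vals, 0.0)
        defined &= inside
        fractions += d.n_fractions
    total[~defined] = 0.0
    return DoseGrid(Volume3D(total, planning_grid.spacing.copy(),
                             planning_grid.origin.copy()),
                    n_fractions=fractions, defined=defined)


def error_dose(accumulated: DoseGrid, planned: DoseGrid,
               n_fractions: int) -> DoseGrid:
    """Accumulated delivered dose minus the fraction-scaled planned dose."""
    if n_fractions < 1:
        raise ValidationError("fraction count must be >= 1")
    if not accumulated.same_grid(planned):
        raise ValidationError("accumulated and planned dose grids differ")
    data = accumulated.volume.data - n_fractions * planned.volume.data
    defined = accumulated.defined_mask() & planned.defined_mask()
    data = np.where(defined, data, 0.0)
    return DoseGrid(accumulated.volume.copy_with(data), n_fractions=n_fractions,
                    defined=defined, kind="error")


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

def dvh(dose: DoseGrid, region_chain: MRepChain,
        bin_cGy: float = DEFAULT_BIN_CGY) -> DVHCurve:
    """Differential DVH over voxel centers inside the chain surface.

    Bin edges are aligned to multiples of the bin width; the summed
    differential volume equals the region volume exactly (voxel-center
    containment, sub-voxel partial volumes ignored).
    """
    if bin_cGy <= 0:
        raise ValidationError("bin width must be positive")
    mask = chain_mask(region_chain, dose.volume) & dose.defined_mask()
    vals = dose.volume.data[mask]
    if vals.size == 0:
        raise ValidationError("region is empty (no voxel centers inside)")
    lo = np.floor(vals.min() / bin_cGy) * bin_cGy
    hi = np.ceil(vals.max() / bin_cGy) * bin_cGy
    if hi <= lo:
        hi = lo + bin_cGy
    edges = np.arange(lo, hi + 0.5 * bin_cGy, bin_cGy)
    counts, _ = np.histogram(vals, bins=edges)
    voxel_cm3 = dose.volume.voxel_volume_mm3 / 1000.0
    return DVHCurve(edges, counts * voxel_cm3)
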