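"""Translation-only multiscale rigid registration of pCT to tCT.

Three steps, coarse to fine, each feeding the next as a prior:

1. skin bounding boxes align x/y; per-slice voxel counts in a bone
   intensity window are matched along z (skipped when bright contrast
   medium is detected in the planning image);
2. gradient ascent on global mutual information (MI) from multiple
   deterministic starting points, best score wins;
3. the same ascent with MI restricted to an ROI around the atlas
   prostate model.

Rotations are excluded by construction (patient setup corrects
translations only); residual rotation is later absorbed by the
deformable segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import PointSet, Volume3D
from .errors import OverlapError, RegistrationError, ValidationError
from .mrep import MRepChain, surface_grid

__all__ = [
    "RigidTransform",
    "IntensityWindow",
    "SliceProfileResult",
    "slice_profile_align",
    "mutual_information",
    "register_global_mi",
    "register_roi_mi",
    "register_bbs",
    "apply_shift_threshold",
    "register_multiscale",
]

#: Default bone intensity window (HU-like) for the slice-profile step.
DEFAULT_BONE_WINDOW = (200.0, 1500.0)
#: Intensity above which voxels count as bright contrast medium.
CONTRAST_HU = 2000.0
#: Fraction of in-body voxels above CONTRAST_HU that triggers the
#: step-1 skip.
CONTRAST_FRACTION = 0.01
#: Body (skin) threshold for bounding boxes.
BODY_THRESHOLD_HU = -200.0

DEFAULT_N_BINS = 64
DEFAULT_MIN_OVERLAP = 0.25


@dataclass(frozen=True)
class RigidTransform:
    """A pure 3D translation in mm (no rotation component exists)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", tuple(float(v) for v in t))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.vector

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(tuple(self.vector + other.vector))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(tuple(-self.vector))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass(frozen=True)
class IntensityWindow:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError("intensity window needs low < high")

    def count(self, data: np.ndarray) -> np.ndarray:
        return (data >= self.low) & (data <= self.high)


@dataclass
class SliceProfileResult:
    """Outcome of the slice-profile step: a transform, or a skip flag
    telling the caller to start at the global-MI step."""

    transform: RigidTransform | None
    skipped: bool = False
    reason: str = ""
    score: float = float("nan")


# ---------------------------------------------------------------------------
# Step 1: skin bounding box + slice profiles
# ---------------------------------------------------------------------------

def _body_mask(vol: Volume3D) -> np.ndarray:
    return vol.data > BODY_THRESHOLD_HU


def _bbox_center_xy(vol: Volume3D) -> np.ndarray:
    mask = _body_mask(vol)
    if not mask.any():
        raise ValidationError("empty body mask")
    out = []
    for axis in (0, 1):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        c = 0.5 * (idx[0] + idx[-1])
        out.append(vol.origin[axis] + c * vol.spacing[axis])
    return np.array(out)


def slice_profile_align(pct: Volume3D, tct: Volume3D,
                        window: IntensityWindow | None = None
                        ) -> SliceProfileResult:
    """Coarse alignment: skin bounding boxes in x/y, bone-window
    voxel-count-per-slice profile match in z."""
    window = IntensityWindow(*DEFAULT_BONE_WINDOW) if window is None else window
    if pct.shape[2] < 5 or tct.shape[2] < 5:
        raise ValidationError("slice-profile alignment needs >= 5 slices")
    if not np.isclose(pct.spacing[2], tct.spacing[2]):
        raise ValidationError("slice spacings differ between images")

    body_p = _body_mask(pct)
    frac = np.count_nonzero(pct.data[body_p] > CONTRAST_HU) \
        / max(np.count_nonzero(body_p), 1)
    if frac > CONTRAST_FRACTION:
        return SliceProfileResult(None, skipped=True,
                                  reason="bright contrast medium in pCT")

    prof_p = window.count(pct.data).sum(axis=(0, 1)).astype(float)
    prof_t = window.count(tct.data).sum(axis=(0, 1)).astype(float)
    if prof_p.sum() == 0 or prof_t.sum() == 0:
        return SliceProfileResult(None, skipped=True,
                                  reason="empty bone-window profile")

    best = (-np.inf, 0)
    nz_p, nz_t = len(prof_p), len(prof_t)
    for s in range(-(nz_p - 5), nz_t - 4):
        lo_t, hi_t = max(0, s), min(nz_t, nz_p + s)
        a = prof_t[lo_t:hi_t]
        b = prof_p[lo_t - s:hi_t - s]
        if len(a) < 5 or a.std() == 0 or b.std() == 0:
            continue
        ncc = float(np.corrcoef(a, b)[0, 1])
        # ties break toward the smallest |shift|
        if ncc > best[0] + 1e-12 or (abs(ncc - best[0]) <= 1e-12
                                     and abs(s) < abs(best[1])):
            best = (ncc, s)
    if not np.isfinite(best[0]):
        return SliceProfileResult(None, skipped=True,
                                  reason="no valid profile overlap")

    txy = _bbox_center_xy(tct) - _bbox_center_xy(pct)
    tz = (tct.origin[2] + best[1] * tct.spacing[2]) - pct.origin[2]
    return SliceProfileResult(
        RigidTransform((txy[0], txy[1], tz)), score=best[0])


# ---------------------------------------------------------------------------
# Step 2/3: mutual information
# ---------------------------------------------------------------------------

class _MISampler:
    """Fixed-image samples with precomputed intensity bins; evaluates MI
    against a moving image under a candidate translation using
    partial-volume (trilinear-weight) histogram accumulation.

    Fixed samples are jittered off the voxel grid (seeded, +-0.5 voxel)
    so that no candidate translation aligns both sampling grids; without
    this the partial-volume joint histogram sharpens artificially at
    grid-aligned shifts and MI develops spurious maxima there.
    """

    def __init__(self, fixed: Volume3D, moving: Volume3D,
                 n_bins: int = DEFAULT_N_BINS,
                 stride: tuple[int, int, int] = (1, 1, 1),
                 roi_mask: np.ndarray | None = None,
                 min_overlap: float = DEFAULT_MIN_OVERLAP,
                 jitter: bool = True):
        self.moving = moving
        self.n_bins = n_bins
        self.min_overlap = min_overlap
        sl = tuple(slice(None, None, s) for s in stride)
        if roi_mask is not None:
            sub = np.zeros(fixed.shape, dtype=bool)
            sub[sl] = True
            vox = np.argwhere(roi_mask & sub)
        else:
            grid = np.meshgrid(*[np.arange(0, fixed.shape[a], stride[a])
                                 for a in range(3)], indexing="ij")
            vox = np.stack([g.ravel() for g in grid], axis=1)
        if vox.shape[0] == 0:
            raise OverlapError("no fixed-image samples in ROI")
        idx = vox.astype(float)
        if jitter:
            rng = np.random.default_rng(1812)
            idx = idx + rng.uniform(-0.5, 0.5, size=idx.shape)
            idx = np.clip(idx, 0, np.array(fixed.shape) - 1)
            fvals = fixed.sample(fixed.world(idx))
        else:
            fvals = fixed.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(float)
        self.points = fixed.world(idx)
        flo, fhi = float(fixed.data.min()), float(fixed.data.max())
        self._bf = self._bin(fvals, flo, fhi)
        self._mlo = float(moving.data.min())
        self._mhi = float(moving.data.max())

    def _bin(self, vals: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi <= lo:
            return np.zeros(vals.shape, dtype=np.int64)
        b = ((vals - lo) / (hi - lo) * self.n_bins).astype(np.int64)
        return np.clip(b, 0, self.n_bins - 1)

    def mi(self, translation: np.ndarray) -> float:
        """MI between fixed samples and moving image shifted so that a
        moving-space point p appears at p + translation in fixed space."""
        q = self.moving.index(self.points - np.asarray(translation, float))
        shape = np.array(self.moving.shape)
        valid = np.all((q >= 0) & (q <= shape - 1), axis=1)
        frac_overlap = valid.mean()
        if frac_overlap < self.min_overlap:
            raise OverlapError(
                f"image overlap {frac_overlap:.2f} below minimum "
                f"{self.min_overlap:.2f}")
        q = q[valid]
        bf = self._bf[valid]
        i0 = np.floor(q).astype(np.int64)
        i0 = np.minimum(i0, shape - 2 + (shape == 1))
        f = q - i0
        nb = self.n_bins
        joint = np.zeros(nb * nb)
        data = self.moving.data
        for cx in (0, 1):
            wx = f[:, 0] if cx else 1.0 - f[:, 0]
            ix = np.minimum(i0[:, 0] + cx, shape[0] - 1)
            for cy in (0, 1):
                wy = f[:, 1] if cy else 1.0 - f[:, 1]
                iy = np.minimum(i0[:, 1] + cy, shape[1] - 1)
                for cz in (0, 1):
                    wz = f[:, 2] if cz else 1.0 - f[:, 2]
                    iz = np.minimum(i0[:, 2] + cz, shape[2] - 1)
                    w = wx * wy * wz
                    mv = data[ix, iy, iz].astype(float)
                    bm = self._bin(mv, self._mlo, self._mhi)
                    joint += np.bincount(bf * nb + bm, weights=w,
                                         minlength=nb * nb)
        total = joint.sum()
        if total <= 0:
            raise OverlapError("empty joint histogram")
        pj = joint / total
        pf = pj.reshape(nb, nb).sum(axis=1)
        pm = pj.reshape(nb, nb).sum(axis=0)

        def H(p: np.ndarray) -> float:
            p = p[p > 0]
            return float(-(p * np.log(p)).sum())

        return H(pf) + H(pm) - H(pj)


def mutual_information(fixed: Volume3D, moving: Volume3D,
                       transform: RigidTransform | None = None,
                       n_bins: int = DEFAULT_N_BINS,
                       roi_mask: np.ndarray | None = None,
                       min_overlap: float = DEFAULT_MIN_OVERLAP) -> float:
    """MI of the joint intensity histogram over the image overlap."""
    t = np.zeros(3) if transform is None else transform.vector
    sampler = _MISampler(fixed, moving, n_bins=n_bins, roi_mask=roi_mask,
                         min_overlap=min_overlap, jitter=False)
    return sampler.mi(t)


def _ascend(sampler: _MISampler, start: np.ndarray, step_mm: np.ndarray,
            min_step: float = 0.1, max_iter: int = 200
            ) -> tuple[np.ndarray, float, int]:
    """Gradient ascent with central-difference gradients (one voxel
    step) and a backtracking line search; stops when the accepted step
    falls below ``min_step`` mm."""
    t = np.asarray(start, dtype=float).copy()
    try:
        f = sampler.mi(t)
    except OverlapError:
        raise
    alpha = 2.0
    it = 0
    for it in range(1, max_iter + 1):
        g = np.zeros(3)
        try:
            for a in range(3):
                e = np.zeros(3)
                e[a] = step_mm[a]
                g[a] = (sampler.mi(t + e) - sampler.mi(t - e)) / (2 * step_mm[a])
        except OverlapError:
            break
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        d = g / gn
        accepted = False
        a = alpha
        while a >= min_step:
            try:
                fn = sampler.mi(t + a * d)
            except OverlapError:
                fn = -np.inf
            if fn > f:
                t = t + a * d
                f = fn
                alpha = min(a * 1.5, 8.0)
                accepted = True
                break
            a *= 0.5
        if not accepted:
            break
    return t, f, it


def _star_starts(prior: np.ndarray, n_starts: int) -> list[np.ndarray]:
    starts = [prior.copy()]
    for radius in (10.0, 20.0, 30.0):
        for a in range(3):
            for s in (1.0, -1.0):
                e = np.zeros(3)
                e[a] = s * radius
                starts.append(prior + e)
    return starts[:max(1, n_starts)]


def register_global_mi(pct: Volume3D, tct: Volume3D,
                       prior: RigidTransform | None = None,
                       n_starts: int = 7, seed: int | None = None,
                       n_bins: int = DEFAULT_N_BINS,
                       stride: tuple[int, int, int] = (3, 3, 1),
                       min_overlap: float = DEFAULT_MIN_OVERLAP
                       ) -> tuple[RigidTransform, dict]:
    """Global-MI translation search from a deterministic star of
    starting points around the prior; best final score wins (ties go to
    the first start found)."""
    prior_t = np.zeros(3) if prior is None else prior.vector
    # multi-start exploration on a coarser sample grid, then one fine
    # refinement ascent from the best candidate
    coarse_stride = tuple(min(3 * s, d) for s, d in zip(stride, (6, 6, 2)))
    coarse = _MISampler(tct, pct, n_bins=n_bins, stride=coarse_stride,
                        min_overlap=min_overlap)
    step = pct.spacing.astype(float)
    results = []
    for s in _star_starts(prior_t, n_starts):
        try:
            t, f, it = _ascend(coarse, s, step)
            results.append({"start": s.tolist(), "translation": t.tolist(),
                            "score": f, "iterations": it})
        except OverlapError as exc:
            results.append({"start": s.tolist(), "error": str(exc)})
    ok = [r for r in results if "score" in r]
    if not ok:
        raise RegistrationError("all starting points violated the overlap "
                                "precondition")
    best = max(ok, key=lambda r: r["score"])
    fine = _MISampler(tct, pct, n_bins=n_bins, stride=stride,
                      min_overlap=min_overlap)
    t, f, it = _ascend(fine, np.asarray(best["translation"]), step)
    report = {"step": "global_mi", "starts": results, "best_score": f,
              "refine_iterations": it}
    return RigidTransform(tuple(t)), report


def _chain_roi_mask(chain: MRepChain, vol: Volume3D,
                    margin_mm: float) -> np.ndarray:
    """Voxels within ``margin_mm`` of the model surface or inside it
    (approximate signed test; adequate for an MI region of interest)."""
    from scipy.spatial import cKDTree

    surf = surface_grid(chain, 4).reshape(-1, 3)
    lo = np.maximum(np.floor(vol.index(surf.min(axis=0) - margin_mm - 1)), 0
                    ).astype(int)
    hi = np.minimum(np.ceil(vol.index(surf.max(axis=0) + margin_mm + 1)),
                    np.array(vol.shape) - 1).astype(int)
    mask = np.zeros(vol.shape, dtype=bool)
    if np.any(hi < lo):
        return mask
    ax = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    G = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    P = vol.world(G)
    d, _ = cKDTree(surf).query(P)
    center = chain.hubs.mean(axis=0)
    rad = np.linalg.norm(P - center, axis=1)
    rad_s = np.linalg.norm(surf - center, axis=1).max()
    near = (d <= margin_mm) | (rad <= rad_s)
    sub = near.reshape(tuple(hi - lo + 1))
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
    return mask


def register_roi_mi(pct: Volume3D, tct: Volume3D, prior: RigidTransform,
                    atlas_chain: MRepChain, margin_mm: float = 8.0,
                    n_bins: int = DEFAULT_N_BINS,
                    min_overlap: float = DEFAULT_MIN_OVERLAP
                    ) -> tuple[RigidTransform, dict]:
    """Refinement with MI restricted to an ROI around the atlas prostate
    model placed at the prior position in the treatment image."""
    moved = atlas_chain.translated(prior.vector)
    roi = _chain_roi_mask(moved, tct, margin_mm)
    if not roi.any():
        raise OverlapError("atlas ROI lies outside the treatment image")
    sampler = _MISampler(tct, pct, n_bins=n_bins, roi_mask=roi,
                         min_overlap=min_overlap)
    t, f, it = _ascend(sampler, prior.vector, pct.spacing.astype(float))
    report = {"step": "roi_mi", "score": f, "iterations": it,
              "roi_voxels": int(roi.sum())}
    return RigidTransform(tuple(t)), report


# ---------------------------------------------------------------------------
# BB-based comparator and the table-shift threshold rule
# ---------------------------------------------------------------------------

def register_bbs(imaged_bbs: PointSet, reference_marks: PointSet
                 ) -> tuple[RigidTransform, float]:
    """Translation-only least squares on labeled point pairs.

    The optimal translation is the centroid difference
    ``centroid(reference) - centroid(imaged)``; the RMS residual after
    applying it is returned (non-zero residuals flag unmodeled rotation
    or marker placement error).
    """
    common = [l for l in imaged_bbs.labels if l in reference_marks.points]
    if not common:
        raise ValidationError("point sets share no labels")
    A = imaged_bbs.array(common)
    B = reference_marks.array(common)
    t = B.mean(axis=0) - A.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((A + t - B) ** 2, axis=1))))
    return RigidTransform(tuple(t)), rms


def apply_shift_threshold(shift: RigidTransform,
                          threshold_mm: float = 3.0) -> RigidTransform:
    """Clinical table-shift rule: apply per-axis components only when
    strictly greater than the threshold in magnitude."""
    if threshold_mm < 0:
        raise ValidationError("threshold must be non-negative")
    v = shift.vector
    kept = np.where(np.abs(v) > threshold_mm, v, 0.0)
    return RigidTransform(tuple(kept))


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def register_multiscale(pct: Volume3D, tct: Volume3D,
                        atlas_chain: MRepChain | None = None,
                        window: IntensityWindow | None = None,
                        n_starts: int = 7, seed: int | None = None,
                        stride: tuple[int, int, int] = (3, 3, 1)
                        ) -> tuple[RigidTransform, dict]:
    """Run steps 1-3; step 1 may be skipped (contrast), step 3 runs only
    when an atlas model is supplied."""
    report: dict = {}
    step1 = slice_profile_align(pct, tct, window)
    report["step1"] = {"skipped": step1.skipped, "reason": step1.reason,
                       "score": step1.score,
                       "translation": None if step1.transform is None
                       else list(step1.transform.translation)}
    prior = step1.transform if not step1.skipped else None
    t2, rep2 = register_global_mi(pct, tct, prior, n_starts=n_starts,
                                  seed=seed, stride=stride)
    report["step2"] = rep2
    if atlas_chain is None:
        report["final"] = list(t2.translation)
        return t2, report
    t3, rep3 = register_roi_mi(pct, tct, t2, atlas_chain)
    report["step3"] = rep3
    report["final"] = list(t3.translation)
    return t3, report
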