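"""Bayesian model-based autosegmentation of the prostate in a
treatment image.

The segmentation maximizes a posterior made of two log terms:

* *geometric typicality* — a Gaussian prior over the trained shape
  space: ``log p(M) = -1/2 * sum_i c_i^2 / sigma_i^2`` for mode
  coefficients ``c_i`` with per-mode variances ``sigma_i^2``;
* *image match* — a similarity between reference intensity profiles
  sampled across the model boundary in the planning image and the same
  model-relative profiles sampled in the treatment image.

The optimum over (translation, shape coefficients) is sought with a
Polak-Ribiere conjugate-gradient ascent with backtracking line search;
coefficients are hard-clipped to +-3 sigma so the model never leaves
the trained space.  Rotation is not an explicit variable: rotational
organ motion is absorbed as an in-space deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Volume3D
from .errors import DomainError, QualityError, ValidationError
from .mrep import MRepChain, ShapeSpace, params_to_chain, surface_grid
from .registration import RigidTransform

__all__ = [
    "ImageMatchModel",
    "SegmentationConfig",
    "SegmentationState",
    "train_image_match",
    "geometric_typicality",
    "image_match",
    "segment",
]


# ---------------------------------------------------------------------------
# Image match model: boundary-crossing intensity profiles
# ---------------------------------------------------------------------------

@dataclass
class ImageMatchModel:
    """Per-spoke reference intensity profiles across the boundary.

    ``profiles[i, j, s]`` is the planning-image intensity at offset
    ``offsets_mm[s]`` along the (possibly interpolated) spoke at grid
    node ``(i, j)``, measured from the surface (negative = inside).
    ``valid`` flags samples inside the image; profiles with any
    out-of-image sample are marked truncated.
    """

    offsets_mm: np.ndarray
    profiles: np.ndarray
    valid: np.ndarray
    step_mm: float
    half_len_mm: float
    resolution: int = 1
    smooth_sigma_mm: float = 1.0
    window_sigma_mm: float = 2.0

    @property
    def sample_weights(self) -> np.ndarray:
        """Gaussian taper over profile offsets: the boundary crossing
        dominates the similarity while far samples (which may contain
        unrelated context such as nearby bone that moves relative to
        the prostate) are de-emphasized."""
        if self.window_sigma_mm <= 0:
            return np.ones_like(self.offsets_mm)
        return np.exp(-(self.offsets_mm / self.window_sigma_mm) ** 2)

    @property
    def truncated(self) -> np.ndarray:
        return ~self.valid.all(axis=-1)


def _smoothed(vol: Volume3D, sigma_mm: float) -> Volume3D:
    """Gaussian pre-smoothing (sigma in mm, anisotropic in voxels) used
    before profile sampling to suppress voxel noise while keeping the
    partial-volume boundary information."""
    if sigma_mm <= 0:
        return vol
    from scipy.ndimage import gaussian_filter

    return vol.copy_with(gaussian_filter(vol.data.astype(float),
                                         sigma_mm / vol.spacing))


def _profile_grid(chain: MRepChain, resolution: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    n, m = chain.n_atoms, chain.n_spokes
    ii = np.linspace(0.0, n - 1.0, (n - 1) * resolution + 1)
    jj = np.arange(m * resolution) / resolution
    return np.meshgrid(ii, jj, indexing="ij")


def _spoke_profile_points(chain: MRepChain, offsets: np.ndarray,
                          resolution: int = 1) -> np.ndarray:
    """Sample positions ``tip + offset * direction`` on the (interpolated)
    spoke grid; at resolution 1 these are exactly the atom spokes."""
    if resolution == 1:
        tips = chain.tips
        dirs = chain.directions
    else:
        from .mrep import interpolator
        I, J = _profile_grid(chain, resolution)
        interp = interpolator(chain)
        dirs = interp.direction(I, J)
        tips = interp.surface(I, J)
    return tips[:, :, None, :] + offsets[None, None, :, None] * dirs[:, :, None, :]


def train_image_match(pct: Volume3D, fitted_chain: MRepChain,
                      profile_len_mm: float = 5.0,
                      step_mm: float = 1.0,
                      resolution: int = 2,
                      smooth_sigma_mm: float = 1.0,
                      window_sigma_mm: float = 2.0) -> ImageMatchModel:
    """Record boundary-crossing profiles (inside -> outside) from the
    planning image in model-relative sampling geometry.

    ``resolution`` refines the spoke grid by interpolation (resolution 1
    = the atom spokes only); a denser grid makes weak shape modes better
    determined by the data.  Both images are pre-smoothed with the same
    Gaussian before sampling.
    """
    if profile_len_mm <= 0 or step_mm <= 0:
        raise ValidationError("profile length and step must be positive")
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")
    ns = int(round(profile_len_mm / step_mm))
    offsets = np.arange(-ns, ns + 1) * step_mm
    src = _smoothed(pct, smooth_sigma_mm)
    pts = _spoke_profile_points(fitted_chain, offsets, resolution)
    flat = pts.reshape(-1, 3)
    vals = src.sample(flat).reshape(pts.shape[:3])
    valid = src.contains(flat).reshape(pts.shape[:3])
    return ImageMatchModel(offsets, vals, valid, step_mm, profile_len_mm,
                           resolution, smooth_sigma_mm, window_sigma_mm)


def _normalize_profiles(P: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-profile weighted z-scoring (constant profiles map to zero,
    which makes uniform images a documented no-gradient case)."""
    n = np.maximum(weights.sum(axis=-1, keepdims=True), 1e-9)
    mean = (P * weights).sum(axis=-1, keepdims=True) / n
    var = ((P - mean) ** 2 * weights).sum(axis=-1, keepdims=True) / n
    sd = np.sqrt(var)
    return np.where(sd > 1e-9, (P - mean) / np.maximum(sd, 1e-9), 0.0)


# ---------------------------------------------------------------------------
# The two log-posterior terms
# ---------------------------------------------------------------------------

def geometric_typicality(coefficients: np.ndarray,
                         shape_space: ShapeSpace) -> float:
    """Unnormalized Gaussian log-prior in shape space; 0 at the mean."""
    c = np.atleast_1d(np.asarray(coefficients, dtype=float))
    if c.size > shape_space.n_modes:
        raise ValidationError("more coefficients than retained modes")
    var = shape_space.variances[:c.size]
    zero = var == 0
    if np.any(zero & (c != 0)):
        raise DomainError("non-zero coefficient on a zero-variance mode")
    safe = np.where(zero, 1.0, var)
    return float(-0.5 * np.sum(np.where(zero, 0.0, c ** 2 / safe)))


def image_match(chain: MRepChain, tct: Volume3D,
                match_model: ImageMatchModel,
                assume_smoothed: bool = False) -> float:
    """Sum over spokes of the (negative mean-squared-difference)
    similarity between locally normalized reference and target
    profiles; higher = better match.

    The target image is pre-smoothed with the model's Gaussian unless
    the caller has already done so (``assume_smoothed``).
    """
    if not assume_smoothed:
        tct = _smoothed(tct, match_model.smooth_sigma_mm)
    pts = _spoke_profile_points(chain, match_model.offsets_mm,
                                match_model.resolution)
    flat = pts.reshape(-1, 3)
    vals = tct.sample(flat).reshape(pts.shape[:3])
    valid_t = tct.contains(flat).reshape(pts.shape[:3])
    valid = valid_t & match_model.valid
    truncated = ~valid_t.all(axis=-1)
    if truncated.mean() > 0.5:
        raise QualityError(
            f"{truncated.mean():.0%} of profiles truncated at the image "
            "border")
    w = match_model.sample_weights * valid
    ref = _normalize_profiles(match_model.profiles, w)
    tgt = _normalize_profiles(vals, w)
    n = np.maximum(w.sum(axis=-1), 1e-9)
    mse = ((ref - tgt) ** 2 * w).sum(axis=-1) / n
    return float(-mse.sum())


# ---------------------------------------------------------------------------
# Conjugate-gradient segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationConfig:
    weight_geometry: float = 1.0
    weight_image: float = 1.0
    retained_variance: float = 0.95
    coeff_clip_sigma: float = 3.0
    max_iter: int = 300
    tol: float = 1e-6
    grad_step: float = 0.05   # in scaled units (mm / sigma)


@dataclass
class SegmentationState:
    """Diagnostics: regenerating ``synthesize(coefficients)`` translated
    by ``rigid_prior + extra_translation`` reproduces ``chain``."""

    coefficients: np.ndarray
    extra_translation: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True
    n_modes: int = 0
    chain: MRepChain | None = None


def _grad(f, x: np.ndarray, h: float) -> np.ndarray:
    g = np.zeros_like(x)
    for a in range(x.size):
        e = np.zeros_like(x)
        e[a] = h
        g[a] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def segment(tct: Volume3D, atlas_chain: MRepChain,
            rigid_prior: RigidTransform, shape_space: ShapeSpace,
            match_model: ImageMatchModel,
            config: SegmentationConfig | None = None
            ) -> tuple[MRepChain, SegmentationState]:
    """Deform the atlas model in the treatment image by maximizing
    geometric typicality + image match over (translation, shape
    coefficients)."""
    cfg = SegmentationConfig() if config is None else config
    prior_t = rigid_prior.vector
    tct_s = _smoothed(tct, match_model.smooth_sigma_mm)

    # precondition: the transferred atlas must lie mostly inside the tCT
    surf = surface_grid(atlas_chain.translated(prior_t), 2).reshape(-1, 3)
    if tct.contains(surf).mean() < 0.8:
        raise DomainError("atlas model transferred by the rigid prior lies "
                          "mostly outside the treatment image")

    K = shape_space.n_modes_for_variance(cfg.retained_variance)
    sig = shape_space.sigmas[:K]
    K = int(np.count_nonzero(sig > 0))
    sig = sig[:K]

    n, m = shape_space.n_atoms, shape_space.n_spokes
    per = 3 + m + 3 * m
    hub_idx = np.concatenate([np.arange(a * per, a * per + 3)
                              for a in range(n)])
    mean = shape_space.mean
    modes = shape_space.modes[:K]

    def build(x: np.ndarray) -> tuple[MRepChain, np.ndarray, np.ndarray]:
        tau = x[:3]
        c = x[3:] * sig
        params = mean + (c @ modes if K else 0.0)
        params = params.copy()
        for a in range(3):
            params[hub_idx[a::3]] += prior_t[a] + tau[a]
        return params_to_chain(params, n, m), tau, c

    def objective(x: np.ndarray) -> float:
        chain, _, c = build(x)
        obj = cfg.weight_geometry * geometric_typicality(c, shape_space)
        if cfg.weight_image != 0.0:
            obj += cfg.weight_image * image_match(chain, tct_s, match_model,
                                                  assume_smoothed=True)
        return obj

    def safe_objective(x: np.ndarray) -> float:
        # a trial step that pushes the model off the image is simply a
        # rejected step, not a failure of the whole segmentation
        try:
            return objective(x)
        except QualityError:
            return -np.inf

    lo = np.concatenate([np.full(3, -np.inf), np.full(K, -cfg.coeff_clip_sigma)])
    hi = -lo

    x = np.zeros(3 + K)
    fx = objective(x)
    hist = [fx]
    converged = False
    h = cfg.grad_step
    g = _grad(objective, x, h)
    d = g.copy()
    alpha = 1.0
    since_restart = 0
    for _ in range(cfg.max_iter):
        if np.linalg.norm(g) < 1e-12:
            converged = True
            break
        dn = d / np.linalg.norm(d)
        accepted = False
        a = alpha
        for _ls in range(30):
            xn = np.clip(x + a * dn, lo, hi)
            if np.allclose(xn, x):
                break
            fn = safe_objective(xn)
            if fn > fx:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            if since_restart > 0:
                # retry along the raw gradient before giving up
                d = g.copy()
                since_restart = 0
                continue
            converged = True
            break
        gain = fn - fx
        x, fx = xn, fn
        hist.append(fx)
        alpha = min(a * 2.0, 4.0)
        if gain < cfg.tol:
            converged = True
            break
        gn = _grad(objective, x, h)
        since_restart += 1
        if since_restart >= x.size + 1:
            d = gn.copy()
            since_restart = 0
        else:
            beta = max(0.0, float(gn @ (gn - g) / max(g @ g, 1e-300)))
            d = gn + beta * d
        g = gn

    chain, tau, c = build(x)
    state = SegmentationState(coefficients=c, extra_translation=tau,
                              objective_history=hist, converged=converged,
                              n_modes=K, chain=chain)
    return chain, state
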