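"""Synthetic planning/treatment CT pair generator with full ground truth.

The phantom emulates the imaging geometry of pelvic CT guidance series:
1 x 1 mm axial pixels with 3 mm slices, a deformable prostate-like
organ (ellipsoid plus low-order smooth radial harmonics) inside a soft-
tissue body ellipse with a pelvic bone ring, optional bladder contrast,
skin BBs on the anterior and lateral surfaces, a planned isocenter, and
an analytic planned dose (prescription plateau over prostate + margin
with a smooth falloff).

The treatment image differs from the planning image by a known rigid
patient setup translation, a known internal prostate shift relative to
the bones, and a known in-shape-space deformation — so every pipeline
stage can be scored against exact ground truth.  Deformations are
applied directly in m-rep parameter space, which makes the segmentation
ground truth exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import ContourStack, PointSet, Volume3D
from .dose import DoseGrid
from .errors import ValidationError
from .mrep import (
    MRepChain,
    chain_axial_sections,
    chain_from_radial,
    chain_mask,
    chain_to_params,
    correspond,
    params_to_chain,
    surface_grid,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_pair",
    "generate_training_chains",
    "generate_planned_dose",
    "simulate_clinical_isocenter",
]


@dataclass
class PhantomSpec:
    """All knobs of the synthetic patient; defaults are the package's
    standard study conditions.

    ``translation_mm`` (whole-patient setup shift), ``prostate_shift_mm``
    (internal prostate motion relative to bone) and
    ``shape_coefficients`` (per generative deformation mode) may be left
    ``None`` to be drawn from the seed: translation uniform in +-10 mm
    per axis, internal shift N(0, 2 mm) clipped to +-4 mm, coefficients
    N(0, sigma_m) clipped to +-2 sigma.
    """

    # imaging geometry (axial 1 x 1 mm pixels, 3 mm slices)
    shape: tuple[int, int, int] = (128, 116, 36)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    # prostate: ellipsoid semi-axes + smooth radial bumpiness (rms fraction)
    prostate_axes_mm: tuple[float, float, float] = (25.0, 20.0, 30.0)
    prostate_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bumpiness: float = 0.02
    n_atoms: int = 13
    n_spokes: int = 16
    # inter-image motion / deformation (None -> seeded draws, see above)
    translation_mm: tuple[float, float, float] | None = None
    prostate_shift_mm: tuple[float, float, float] | None = None
    rotation_deg: float = 0.0
    shape_coefficients: tuple[float, ...] | None = None
    #: physical amplitude (1 sigma) of the generative deformation modes:
    #: volume scale, anterior-posterior squash, craniocaudal elongation
    #: (all acting on log spoke lengths)
    mode_sigmas: tuple[float, ...] = (0.04, 0.04, 0.04)
    # intensity model (HU-like)
    air_hu: float = -1000.0
    soft_hu: float = 35.0
    prostate_hu: float = 70.0
    bone_hu: float = 1000.0
    bladder_contrast_hu: float | None = None
    rectal_gas: bool = False
    noise_sd: float = 15.0
    # anatomy layout (axial ellipse semi-axes, mm)
    body_axes_mm: tuple[float, float] = (46.0, 40.0)
    bone_outer_mm: tuple[float, float] = (42.0, 36.0)
    bone_inner_mm: tuple[float, float] = (34.0, 29.0)
    bone_z_mm: tuple[float, float] = (-36.0, 18.0)
    femoral_center_mm: tuple[float, float, float] = (38.0, 0.0, 30.0)
    femoral_radius_mm: float = 12.0
    bladder_center_mm: tuple[float, float, float] = (0.0, -12.0, 46.0)
    bladder_radius_mm: float = 14.0
    rectum_center_mm: tuple[float, float, float] = (0.0, 26.0, -8.0)
    rectum_radius_mm: float = 8.0
    # isocenter and BBs
    iso_offset_mm: tuple[float, float, float] = (2.0, -3.0, -6.0)
    bb_noise_sd: float = 0.3
    # planned dose model
    prescription_cGy: float = 200.0
    margin_mm: float = 5.0
    falloff_mm: float = 3.0
    planning_grid_mm: float = 5.0
    n_contour_vertices: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.prostate_axes_mm) <= 0):
            raise ValidationError("prostate axes must be positive")
        if self.noise_sd < 0 or self.bb_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.margin_mm < 0 or self.falloff_mm <= 0:
            raise ValidationError("margin must be >= 0 and falloff > 0")

    def volume_grid(self) -> Volume3D:
        """Empty image grid, world origin at the volume center."""
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing, dtype=float)
        origin = -(shape - 1) * spacing / 2.0
        return Volume3D(np.zeros(self.shape), spacing, origin)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stream])


@dataclass
class PhantomTruth:
    """Everything the generator knows: the ground truth for scoring."""

    planning_chain: MRepChain
    treatment_chain: MRepChain
    shape_coefficients: np.ndarray
    translation_mm: np.ndarray
    prostate_shift_mm: np.ndarray
    rotation_deg: float
    planned_iso: np.ndarray
    true_treatment_iso: np.ndarray
    skin_marks: PointSet
    imaged_bbs: PointSet
    prostate_mask_planning: np.ndarray
    prostate_mask_treatment: np.ndarray
    generative_modes: np.ndarray = field(repr=False)
    mode_sigmas: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Prostate surface and generative deformation modes
# ---------------------------------------------------------------------------

def _bump_function(spec: PhantomSpec):
    """Seeded low-order smooth radial perturbation, rms ~ bumpiness."""
    rng = spec._rng(1)
    terms = []
    for ell in (2, 3):
        for em in range(ell + 1):
            terms.append((ell, em, rng.normal(), rng.normal()))

    def bump(theta, phi):
        out = np.zeros(np.broadcast(theta, phi).shape)
        for ell, em, ac, as_ in terms:
            base = np.cos(theta) ** (ell - em) * np.sin(theta) ** em
            out = out + base * (ac * np.cos(em * phi) + as_ * np.sin(em * phi))
        return out

    # normalize rms over the sphere to the requested amplitude
    tg = np.linspace(0, np.pi, 48)
    pg = np.linspace(-np.pi, np.pi, 96, endpoint=False)
    TG, PG = np.meshgrid(tg, pg, indexing="ij")
    vals = bump(TG, PG)
    w = np.sin(TG)
    rms = np.sqrt(np.sum(vals ** 2 * w) / np.sum(w))
    scale = spec.bumpiness / rms if rms > 0 else 0.0
    return lambda theta, phi: scale * bump(theta, phi)


def _radial_function(spec: PhantomSpec):
    a, b, c = spec.prostate_axes_mm
    bump = _bump_function(spec)

    def radial(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        base = 1.0 / np.sqrt((st * np.cos(phi) / a) ** 2
                             + (st * np.sin(phi) / b) ** 2 + (ct / c) ** 2)
        return base * (1.0 + bump(theta, phi))

    return radial


def planning_chain(spec: PhantomSpec) -> MRepChain:
    """The phantom's ground-truth planning prostate model."""
    return chain_from_radial(np.asarray(spec.prostate_center_mm),
                             _radial_function(spec),
                             n_atoms=spec.n_atoms, n_spokes=spec.n_spokes)


def generative_modes(chain: MRepChain, spec: PhantomSpec
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal deformation modes (rows) in atom-parameter space and
    their 1-sigma coefficient scales."""
    n, m = chain.n_atoms, chain.n_spokes
    per = 3 + m + 3 * m
    D = n * per
    az = np.arctan2(chain.directions[..., 1], chain.directions[..., 0])

    raw = []
    # volume scale: uniform log-length change
    v = np.zeros(D)
    for a in range(n):
        v[a * per + 3: a * per + 3 + m] = 1.0
    raw.append(v)
    # anterior-posterior squash: log-lengths follow the spoke azimuth
    v = np.zeros(D)
    for a in range(n):
        v[a * per + 3: a * per + 3 + m] = 2.0 * (np.sin(az[a]) ** 2 - 0.5)
    raw.append(v)
    # craniocaudal elongation (prolate/oblate): traceless in elevation,
    # so it is orthogonal to both translation and the volume mode
    v = np.zeros(D)
    for a in range(n):
        v[a * per + 3: a * per + 3 + m] = chain.directions[a, :, 2] ** 2 - 1.0 / 3.0
    raw.append(v)

    sig_phys = np.asarray(spec.mode_sigmas, dtype=float)
    if len(sig_phys) != len(raw):
        raise ValidationError("mode_sigmas must have one entry per mode")
    norms = np.array([np.linalg.norm(v) for v in raw])
    Q, _ = np.linalg.qr(np.array(raw).T)
    modes = Q.T
    # keep each orthonormal mode pointing along its raw ancestor
    for r, v in enumerate(raw):
        if modes[r] @ v < 0:
            modes[r] *= -1.0
    sigmas = sig_phys * norms
    return modes, sigmas


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _grid_coords(vol: Volume3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gx, gy, gz = vol.grid_world()
    return gx[:, None, None], gy[None, :, None], gz[None, None, :]


def _ellipse_occ(X, Y, a, b, spacing):
    """Box-filter occupancy of an axial ellipse (approximate signed
    distance from the normalized radius)."""
    rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2)
    grad = np.sqrt((X / a ** 2) ** 2 + (Y / b ** 2) ** 2) \
        / np.maximum(rho, 1e-9)
    s = (rho - 1.0) / np.maximum(grad, 1e-9)
    nx = np.abs(X / a ** 2) / np.maximum(grad * np.maximum(rho, 1e-9), 1e-12)
    ny = np.abs(Y / b ** 2) / np.maximum(grad * np.maximum(rho, 1e-9), 1e-12)
    w = nx * spacing[0] + ny * spacing[1]
    return np.clip(0.5 - s / np.maximum(w, 1e-9), 0.0, 1.0)


def _slab_occ(Z, zlo, zhi, dz):
    return np.clip((np.minimum(zhi, Z + dz / 2) - np.maximum(zlo, Z - dz / 2))
                   / dz, 0.0, 1.0)


def _sphere_occ(X, Y, Z, center, radius, spacing):
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    rs = np.maximum(r, 1e-9)
    w = (np.abs(dx) * spacing[0] + np.abs(dy) * spacing[1]
         + np.abs(dz) * spacing[2]) / rs
    return np.clip(0.5 - (r - radius) / np.maximum(w, 1e-9), 0.0, 1.0)


def _render(spec: PhantomSpec, vol: Volume3D, body_offset: np.ndarray,
            prostate_occupancy: np.ndarray, rng_noise: np.random.Generator
            ) -> np.ndarray:
    """Paint the scene back-to-front with partial-volume (box-filter)
    edges on every structure, so sub-voxel positions stay encoded in the
    boundary intensities as in real CT."""
    X, Y, Z = _grid_coords(vol)
    ox, oy, oz = body_offset
    sp = vol.spacing

    def paint(img, occ, level):
        return img * (1.0 - occ) + level * occ

    img = np.full(vol.shape, float(spec.air_hu))
    bax, bay = spec.body_axes_mm
    img = paint(img, np.broadcast_to(
        _ellipse_occ(X - ox, Y - oy, bax, bay, sp), vol.shape), spec.soft_hu)

    roa, rob = spec.bone_outer_mm
    ria, rib = spec.bone_inner_mm
    zlo, zhi = spec.bone_z_mm
    ring = _ellipse_occ(X - ox, Y - oy, roa, rob, sp) \
        * (1.0 - _ellipse_occ(X - ox, Y - oy, ria, rib, sp)) \
        * _slab_occ(Z - oz, zlo, zhi, sp[2])
    img = paint(img, np.broadcast_to(ring, vol.shape), spec.bone_hu)
    fx, fy, fz = spec.femoral_center_mm
    for sx in (-1.0, 1.0):
        fem = _sphere_occ(X, Y, Z, (ox + sx * fx, oy + fy, oz + fz),
                          spec.femoral_radius_mm, sp)
        img = paint(img, fem, spec.bone_hu)

    if spec.bladder_contrast_hu is not None:
        cx, cy, cz = spec.bladder_center_mm
        img = paint(img, _sphere_occ(X, Y, Z, (ox + cx, oy + cy, oz + cz),
                                     spec.bladder_radius_mm, sp),
                    spec.bladder_contrast_hu)
    if spec.rectal_gas:
        cx, cy, cz = spec.rectum_center_mm
        img = paint(img, _sphere_occ(X, Y, Z, (ox + cx, oy + cy, oz + cz),
                                     spec.rectum_radius_mm, sp), -150.0)

    img = paint(img, prostate_occupancy, spec.prostate_hu)
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, size=vol.shape)
    return img


def _rotate_chain_z(chain: MRepChain, angle_deg: float,
                    center: np.ndarray) -> MRepChain:
    if angle_deg == 0.0:
        return chain
    a = np.deg2rad(angle_deg)
    Rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                   [np.sin(a), np.cos(a), 0.0],
                   [0.0, 0.0, 1.0]])
    from .mrep import MedialAtom
    atoms = [MedialAtom(center + Rz @ (at.hub - center),
                        at.directions @ Rz.T, at.lengths.copy())
             for at in chain.atoms]
    return MRepChain(atoms, rind_mm=chain.rind_mm)


def _skin_marks(spec: PhantomSpec, iso: np.ndarray) -> PointSet:
    bax, bay = spec.body_axes_mm
    x0, y0, z0 = iso
    ya = -bay * np.sqrt(max(1.0 - (x0 / bax) ** 2, 0.0))
    xl = bax * np.sqrt(max(1.0 - (y0 / bay) ** 2, 0.0))
    return PointSet({
        "AP": np.array([x0, ya, z0]),
        "RLAT": np.array([xl, y0, z0]),
        "LLAT": np.array([-xl, y0, z0]),
    })


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_pair(spec: PhantomSpec
                  ) -> tuple[Volume3D, Volume3D, ContourStack, PhantomTruth]:
    """Planning CT, treatment CT, planning contours and ground truth."""
    vol = spec.volume_grid()
    p_chain = planning_chain(spec)
    modes, sigmas = generative_modes(p_chain, spec)

    if spec.shape_coefficients is None:
        rng = spec._rng(2)
        coeffs = np.clip(rng.normal(0.0, sigmas), -2 * sigmas, 2 * sigmas)
    else:
        coeffs = np.asarray(spec.shape_coefficients, dtype=float)
        if coeffs.shape != sigmas.shape:
            raise ValidationError("need one shape coefficient per mode")
    if spec.translation_mm is None:
        translation = spec._rng(3).uniform(-10.0, 10.0, size=3)
    else:
        translation = np.asarray(spec.translation_mm, dtype=float)
    if spec.prostate_shift_mm is None:
        shift = np.clip(spec._rng(4).normal(0.0, 2.0, size=3), -4.0, 4.0)
    else:
        shift = np.asarray(spec.prostate_shift_mm, dtype=float)

    if np.any(coeffs != 0.0):
        params = chain_to_params(p_chain) + coeffs @ modes
        t_chain = params_to_chain(params, spec.n_atoms, spec.n_spokes)
    else:  # keep the identity case bitwise exact
        t_chain = p_chain
    t_chain = _rotate_chain_z(t_chain, spec.rotation_deg,
                              np.asarray(spec.prostate_center_mm, dtype=float))
    t_chain = t_chain.translated(translation + shift)

    surf = surface_grid(t_chain, 2).reshape(-1, 3)
    lo = vol.world(np.zeros(3))
    hi = vol.world(np.array(vol.shape) - 1.0)
    if np.any(surf.min(axis=0) < lo) or np.any(surf.max(axis=0) > hi):
        raise ValidationError("deformed prostate exits the image volume")

    mask_p, occ_p = chain_mask(p_chain, vol, return_occupancy=True)
    mask_t, occ_t = chain_mask(t_chain, vol, return_occupancy=True)
    pct = vol.copy_with(_render(spec, vol, np.zeros(3), occ_p, spec._rng(5)))
    tct = vol.copy_with(_render(spec, vol, translation, occ_t, spec._rng(6)))

    gz = vol.grid_world()[2]
    contours = chain_axial_sections(p_chain, gz, spec.n_contour_vertices)

    planned_iso = np.asarray(spec.prostate_center_mm) \
        + np.asarray(spec.iso_offset_mm)
    true_iso = correspond(planned_iso, p_chain.with_rind(3.0),
                          t_chain.with_rind(3.0))

    marks = _skin_marks(spec, planned_iso)
    rngb = spec._rng(7)
    bbs = PointSet({
        lab: marks[lab] + translation + rngb.normal(0.0, spec.bb_noise_sd, 3)
        for lab in marks.labels
    })

    truth = PhantomTruth(
        planning_chain=p_chain, treatment_chain=t_chain,
        shape_coefficients=coeffs, translation_mm=translation,
        prostate_shift_mm=shift, rotation_deg=spec.rotation_deg,
        planned_iso=planned_iso, true_treatment_iso=true_iso,
        skin_marks=marks, imaged_bbs=bbs,
        prostate_mask_planning=mask_p, prostate_mask_treatment=mask_t,
        generative_modes=modes, mode_sigmas=sigmas,
    )
    return pct, tct, contours, truth


def generate_training_chains(spec: PhantomSpec, n: int,
                             seed: int | None = None) -> list[MRepChain]:
    """Training set for the per-patient shape space: the planning chain
    perturbed by seeded draws from the generative modes."""
    if n < 2:
        raise ValidationError("need at least 2 training chains")
    base = planning_chain(spec)
    modes, sigmas = generative_modes(base, spec)
    p0 = chain_to_params(base)
    rng = np.random.default_rng(
        [int(spec.seed if seed is None else seed) % (2 ** 31), 23])
    chains = []
    for _ in range(n):
        c = rng.normal(0.0, sigmas)
        chains.append(params_to_chain(p0 + c @ modes, spec.n_atoms,
                                      spec.n_spokes))
    return chains


# ---------------------------------------------------------------------------
# Analytic planned dose
# ---------------------------------------------------------------------------

def generate_planned_dose(spec: PhantomSpec, planning_chain: MRepChain,
                          planned_iso: np.ndarray) -> DoseGrid:
    """Analytic plan: prescription plateau over prostate + margin with a
    smooth Gaussian falloff of the given scale, evaluated at 1 mm and
    resampled to the coarse planning grid."""
    planned_iso = np.asarray(planned_iso, dtype=float).reshape(3)
    vol = spec.volume_grid()
    if not vol.contains(planned_iso)[0]:
        raise ValidationError("planned isocenter outside the image volume")

    surf = surface_grid(planning_chain, 8).reshape(-1, 3)
    pad = spec.margin_mm + 3.0 * spec.falloff_mm + 6.0
    lo = surf.min(axis=0) - pad
    hi = surf.max(axis=0) + pad
    fine = Volume3D(np.zeros(tuple(np.ceil((hi - lo)).astype(int) + 1)),
                    np.ones(3), lo)
    from scipy.spatial import cKDTree
    tree = cKDTree(surf)
    ax = fine.grid_world()
    P = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d, _ = tree.query(P)
    inside = chain_mask(planning_chain, fine).reshape(-1)
    s = np.where(inside, -d, d)  # signed distance to prostate surface
    out = np.clip(s - spec.margin_mm, 0.0, None)
    dose = spec.prescription_cGy * np.exp(-(out / spec.falloff_mm) ** 2)
    dose[s <= spec.margin_mm] = spec.prescription_cGy
    dose[dose < 1e-6 * spec.prescription_cGy] = 0.0  # drop negligible tail
    fine = fine.copy_with(dose.reshape(fine.shape))

    g = spec.planning_grid_mm
    shape = tuple(np.floor((hi - lo) / g).astype(int) + 1)
    coarse = Volume3D(np.zeros(shape), np.full(3, g), lo)
    axc = coarse.grid_world()
    Pc = np.stack(np.meshgrid(*axc, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = fine.sample(Pc).reshape(shape)
    return DoseGrid(Volume3D(vals, np.full(3, g), lo.copy()), n_fractions=1)


def simulate_clinical_isocenter(truth: PhantomTruth,
                                manual_sd_mm: Sequence[float] = (1.4, 2.3, 3.5),
                                rng: np.random.Generator | None = None
                                ) -> np.ndarray:
    """Simulated user-directed (BB + visual match) isocenter.

    The human match error is modeled as seeded zero-mean Gaussian
    per-axis error around the true treatment isocenter — a simulation
    stand-in for intra/inter-user variability, not a claim about any
    particular operator.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    return truth.true_treatment_iso + rng.normal(
        0.0, np.asarray(manual_sd_mm, dtype=float))
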