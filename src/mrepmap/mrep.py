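"""Medial-representation (m-rep) chain models of the prostate.

An m-rep chain is an ordered list of *medial atoms*; each atom has a hub
on the medial curve and 16 spokes (unit direction + length) whose tips
lie on the organ surface.  The chain provides an organ-relative
coordinate system ``(i, j, k)``:

    i : fractional position along the chain (0 .. n_atoms-1),
    j : fractional angular spoke index (periodic, 0 .. n_spokes),
    k : fractional distance from the hub along the interpolated spoke,
        k = 0 on the medial curve, k = 1 on the surface, k > 1 inside
        an optional *rind* shell extrapolated beyond the surface.

Interpolation is cubic along the chain, periodic cubic around the
spokes, and linear in ``k``, which gives the surface the continuous
curvature the fitting stage enforces.  Atom 0 sits at the superior pole
of the organ and the last atom at the inferior pole, so the
interpolated surface closes at the chain ends; spoke 0 points anterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline, make_interp_spline
from scipy.spatial import cKDTree
from shapely.geometry import Polygon as _ShPolygon

from .core_io import ContourStack, PointSet, Volume3D
from .errors import DomainError, ValidationError

__all__ = [
    "MedialAtom",
    "MRepChain",
    "ModelCoordinate",
    "ShapeSpace",
    "DisplacementField",
    "FitResult",
    "spoke_azimuths",
    "chain_from_radial",
    "surface_grid",
    "surface_points",
    "model_to_image",
    "image_to_model",
    "correspond",
    "surface_distance",
    "chain_mask",
    "chain_axial_sections",
    "dice_coefficient",
    "extrapolate_rind",
    "displacement_field",
    "fit_chain_to_contours",
    "chain_to_params",
    "params_to_chain",
    "build_shape_space",
]

#: Azimuth (rad, from +x toward +y) of spoke index 0: anterior = -y.
SPOKE0_AZIMUTH = -np.pi / 2

DEFAULT_N_ATOMS = 13
DEFAULT_N_SPOKES = 16
DEFAULT_RIND_MM = 3.0       # middle of the 2-5 mm band used for dose mapping
DEFAULT_HUB_FRACTION = 0.6  # medial hub position as fraction of polar radius


def spoke_azimuths(n_spokes: int) -> np.ndarray:
    """Azimuth of each spoke index (spoke 0 anterior, counterclockwise)."""
    return SPOKE0_AZIMUTH + 2.0 * np.pi * np.arange(n_spokes) / n_spokes


# ---------------------------------------------------------------------------
# Atoms and chains
# ---------------------------------------------------------------------------

@dataclass
class MedialAtom:
    """A hub with radiating spokes whose tips lie on the organ surface."""

    hub: np.ndarray           # (3,) mm
    directions: np.ndarray    # (n_spokes, 3) unit vectors
    lengths: np.ndarray       # (n_spokes,) mm, > 0

    def __post_init__(self) -> None:
        self.hub = np.asarray(self.hub, dtype=float).reshape(3)
        self.directions = np.asarray(self.directions, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValidationError("spoke directions must have shape (n_spokes, 3)")
        if self.lengths.shape != (self.directions.shape[0],):
            raise ValidationError("spoke direction / length count mismatch")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("spoke directions must be unit vectors")
        if np.any(np.abs(norms - 1.0) > 1e-12):  # keep exact inputs bitwise
            self.directions = self.directions / norms[:, None]
        if np.any(self.lengths <= 0):
            raise ValidationError("spoke lengths must be positive")

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def tips(self) -> np.ndarray:
        return self.hub + self.lengths[:, None] * self.directions


@dataclass
class MRepChain:
    """Ordered chain of medial atoms sharing one spoke-index convention."""

    atoms: list[MedialAtom]
    rind_mm: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.atoms) < 3:
            raise ValidationError("a chain needs at least 3 atoms")
        counts = {a.n_spokes for a in self.atoms}
        if len(counts) != 1:
            raise ValidationError("all atoms must share the spoke count")
        if float(self.rind_mm) < 0:
            raise ValidationError("rind thickness must be non-negative")
        hubs = self.hubs
        if np.any(np.linalg.norm(np.diff(hubs, axis=0), axis=1) == 0):
            raise ValidationError("consecutive hubs coincide")

    # -- array views --------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_spokes(self) -> int:
        return self.atoms[0].n_spokes

    @property
    def hubs(self) -> np.ndarray:
        return np.array([a.hub for a in self.atoms])

    @property
    def directions(self) -> np.ndarray:
        return np.array([a.directions for a in self.atoms])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([a.lengths for a in self.atoms])

    @property
    def tips(self) -> np.ndarray:
        return np.array([a.tips for a in self.atoms])

    # -- transforms ---------------------------------------------------------
    def translated(self, t: np.ndarray) -> "MRepChain":
        t = np.asarray(t, dtype=float).reshape(3)
        atoms = [MedialAtom(a.hub + t, a.directions.copy(), a.lengths.copy())
                 for a in self.atoms]
        return MRepChain(atoms, rind_mm=self.rind_mm)

    def with_rind(self, rind_mm: float) -> "MRepChain":
        if not 0.0 <= float(rind_mm) <= 5.0:
            raise ValidationError("rind thickness must be in [0, 5] mm")
        return replace(self, rind_mm=float(rind_mm), _cache={})

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "n_spokes": self.n_spokes,
            "rind_mm": self.rind_mm,
            "atoms": [
                {
                    "hub": a.hub.tolist(),
                    "directions": a.directions.tolist(),
                    "lengths": a.lengths.tolist(),
                }
                for a in self.atoms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MRepChain":
        atoms = [MedialAtom(np.array(a["hub"]), np.array(a["directions"]),
                            np.array(a["lengths"])) for a in d["atoms"]]
        return cls(atoms, rind_mm=float(d.get("rind_mm", 0.0)))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "MRepChain":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ModelCoordinate:
    """Prostate-relative address of a point: (atom index ``i``, spoke
    index ``j``, fractional spoke distance ``k``)."""

    i: float
    j: float
    k: float

    def as_array(self) -> np.ndarray:
        return np.array([self.i, self.j, self.k], dtype=float)


def extrapolate_rind(chain: MRepChain, thickness_mm: float) -> MRepChain:
    """Extend the coordinate domain ``thickness_mm`` beyond the surface.

    The ``k`` domain per spoke becomes ``[0, 1 + thickness/length(i, j)]``,
    so a rind point at ``k = 1 + d/L`` lies exactly ``d`` mm beyond the
    surface along the (interpolated) spoke.
    """
    return chain.with_rind(thickness_mm)


# ---------------------------------------------------------------------------
# Interpolation: the continuous (i, j, k) -> world map
# ---------------------------------------------------------------------------

class ChainInterpolator:
    """Continuous interpolation of a chain: cubic along ``i``, periodic
    cubic around ``j`` (via generous periodic padding), linear in ``k``."""

    _PAD = 8

    def __init__(self, chain: MRepChain):
        n, m = chain.n_atoms, chain.n_spokes
        self.n_atoms, self.n_spokes = n, m
        self.rind_mm = float(chain.rind_mm)
        i_nodes = np.arange(n, dtype=float)
        j_nodes = np.arange(-self._PAD, m + self._PAD, dtype=float)
        kx = min(3, n - 1)
        self._hub = make_interp_spline(i_nodes, chain.hubs, k=kx)
        wrap = np.mod(np.arange(-self._PAD, m + self._PAD), m)
        dirs = chain.directions[:, wrap, :]
        lens = chain.lengths[:, wrap]
        self._dir = [RectBivariateSpline(i_nodes, j_nodes, dirs[..., c], kx=kx, ky=3)
                     for c in range(3)]
        self._len = RectBivariateSpline(i_nodes, j_nodes, lens, kx=kx, ky=3)

    def wrap_j(self, j: np.ndarray) -> np.ndarray:
        return np.mod(j, self.n_spokes)

    def hub(self, i: np.ndarray) -> np.ndarray:
        return self._hub(np.asarray(i, dtype=float))

    def direction(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        jw = self.wrap_j(np.asarray(j, dtype=float))
        i = np.asarray(i, dtype=float)
        d = np.stack([s.ev(i, jw) for s in self._dir], axis=-1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def length(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return self._len.ev(np.asarray(i, dtype=float),
                            self.wrap_j(np.asarray(j, dtype=float)))

    def kmax(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        if self.rind_mm == 0.0:
            return np.ones(np.broadcast(np.asarray(i), np.asarray(j)).shape)
        return 1.0 + self.rind_mm / self.length(i, j)

    def position(self, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        i = np.asarray(i, dtype=float)
        j = np.asarray(j, dtype=float)
        k = np.asarray(k, dtype=float)
        return self.hub(i) + (k * self.length(i, j))[..., None] * self.direction(i, j)

    def surface(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return self.position(i, j, np.ones(np.broadcast(np.asarray(i),
                                                        np.asarray(j)).shape))


def interpolator(chain: MRepChain) -> ChainInterpolator:
    interp = chain._cache.get("interp")
    if interp is None:
        interp = ChainInterpolator(chain)
        chain._cache["interp"] = interp
    return interp


# ---------------------------------------------------------------------------
# Surface sampling
# ---------------------------------------------------------------------------

def surface_grid(chain: MRepChain, resolution: int = 1) -> np.ndarray:
    """Surface positions on a refined (i, j) grid, shape (ni, nj, 3).

    ``resolution`` = subdivisions per atom/spoke interval; the grid
    always contains the original spoke tips at integer (i, j).
    """
    if resolution < 1 or int(resolution) != resolution:
        raise ValidationError("resolution must be an integer >= 1")
    n, m = chain.n_atoms, chain.n_spokes
    interp = interpolator(chain)
    ii = np.linspace(0.0, n - 1.0, (n - 1) * resolution + 1)
    jj = np.arange(m * resolution) / resolution
    I, J = np.meshgrid(ii, jj, indexing="ij")
    return interp.position(I, J, np.ones_like(I))


def surface_points(chain: MRepChain, resolution: int = 1) -> PointSet:
    """Interpolated closed-surface samples as a labeled point set."""
    grid = surface_grid(chain, resolution)
    labels = [f"s{a}_{b}" for a in range(grid.shape[0]) for b in range(grid.shape[1])]
    return PointSet.from_arrays(labels, grid.reshape(-1, 3))


# ---------------------------------------------------------------------------
# model -> image and image -> model coordinates
# ---------------------------------------------------------------------------

def _coord_arrays(coord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(coord, ModelCoordinate):
        return (np.atleast_1d(float(coord.i)), np.atleast_1d(float(coord.j)),
                np.atleast_1d(float(coord.k)))
    i, j, k = coord
    return np.atleast_1d(np.asarray(i, float)), np.atleast_1d(np.asarray(j, float)), \
        np.atleast_1d(np.asarray(k, float))


def model_to_image(coord, chain: MRepChain) -> np.ndarray:
    """World position(s) of model coordinate(s).

    ``position = hub(i) + k * length(i, j) * direction(i, j)`` with all
    three factors interpolated.  Raises :class:`DomainError` outside the
    coordinate domain (``i`` beyond the chain, ``k`` beyond surface+rind).
    """
    i, j, k = _coord_arrays(coord)
    interp = interpolator(chain)
    eps = 1e-9
    if np.any(i < -eps) or np.any(i > chain.n_atoms - 1 + eps):
        raise DomainError("chain coordinate i outside [0, n_atoms-1]")
    if np.any(k < -eps) or np.any(k > interp.kmax(i, j) + 1e-6):
        raise DomainError("spoke coordinate k outside [0, 1 + rind/length]")
    pos = interp.position(np.clip(i, 0, chain.n_atoms - 1), j, k)
    if isinstance(coord, ModelCoordinate):
        return pos[0]
    return pos


def _invert_batch(points: np.ndarray, chain: MRepChain, tol: float = 0.01,
                  max_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Batched inversion of the (i, j, k) -> world map.

    Returns ``(ijk, residual_mm)`` where residual is the distance between
    ``position(ijk)`` and the query point; small residual means the point
    lies in the model (+rind) domain.  Seeds come from a cached coarse
    lattice; refinement is damped Gauss-Newton with numerical Jacobians.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    interp = interpolator(chain)
    n, m = chain.n_atoms, chain.n_spokes

    key = ("lattice", round(chain.rind_mm, 9))
    cached = chain._cache.get(key)
    if cached is None:
        ii = np.linspace(0.0, n - 1.0, 4 * (n - 1) + 1)
        jj = np.arange(4 * m) / 4.0
        kf = np.linspace(0.08, 1.0, 12)
        I, J, K = np.meshgrid(ii, jj, kf, indexing="ij")
        K = K * interp.kmax(I, J)
        lat = interp.position(I, J, K)
        tree = cKDTree(lat.reshape(-1, 3))
        cached = (tree, np.stack([I, J, K], axis=-1).reshape(-1, 3))
        chain._cache[key] = cached
    tree, lat_ijk = cached

    _, idx = tree.query(pts)
    x = lat_ijk[idx].copy()

    def clamp(x: np.ndarray) -> np.ndarray:
        x[:, 0] = np.clip(x[:, 0], 0.0, n - 1.0)
        x[:, 2] = np.clip(x[:, 2], 0.0, interp.kmax(x[:, 0], x[:, 1]))
        return x

    def fval(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(interp.position(x[:, 0], x[:, 1], x[:, 2]) - pts, axis=1)

    def fsub(x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(interp.position(x[:, 0], x[:, 1], x[:, 2]) - p, axis=1)

    f = fval(x)
    active = f > tol
    steps = np.array([1e-3, 1e-3, 1e-3])
    clip = np.array([0.5, 1.0, 0.25])
    for _ in range(max_iter):
        if not np.any(active):
            break
        ia = np.flatnonzero(active)
        xa = x[ia]
        pa = pts[ia]
        fa = f[ia]
        r = interp.position(xa[:, 0], xa[:, 1], xa[:, 2]) - pa
        J = np.empty((xa.shape[0], 3, 3))
        for v in range(3):
            xp = xa.copy(); xp[:, v] += steps[v]
            xm = xa.copy(); xm[:, v] -= steps[v]
            J[:, :, v] = (interp.position(xp[:, 0], xp[:, 1], xp[:, 2])
                          - interp.position(xm[:, 0], xm[:, 1], xm[:, 2])) / (2 * steps[v])
        JtJ = np.einsum("nav,naw->nvw", J, J)
        g = np.einsum("nav,na->nv", J, r)
        lam = 1e-6 + 1e-3 * np.linalg.norm(r, axis=1)
        JtJ[:, np.arange(3), np.arange(3)] += lam[:, None]
        try:
            delta = -np.linalg.solve(JtJ, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        delta = np.clip(delta, -clip, clip)
        xn = clamp(xa + delta)
        fn = fsub(xn, pa)
        worse = fn >= fa
        if np.any(worse):
            xh = clamp(xa + 0.25 * delta)
            fh = fsub(xh, pa)
            use_h = worse & (fh < fn)
            xn[use_h] = xh[use_h]
            fn[use_h] = fh[use_h]
        improved = fn < fa
        gain = np.where(improved, fa - fn, 0.0)
        xa = np.where(improved[:, None], xn, xa)
        fa = np.where(improved, fn, fa)
        x[ia] = xa
        f[ia] = fa
        active[ia] = (fa > tol) & improved & (gain > 1e-6)
    return x, f


#: Residual above which a point is judged outside the model (+rind).
_INVERT_OK_MM = 0.05


def image_to_model(position: np.ndarray, chain: MRepChain,
                   tol: float = 0.01) -> ModelCoordinate:
    """Model coordinate of a world point inside the model (+rind).

    Round trip ``model_to_image(image_to_model(p))`` agrees with ``p``
    to well under 0.1 mm; points outside the domain raise
    :class:`DomainError`.
    """
    ijk, resid = _invert_batch(np.asarray(position, dtype=float).reshape(1, 3),
                               chain, tol=tol)
    if resid[0] > _INVERT_OK_MM:
        raise DomainError(
            f"point lies outside the model (+rind): nearest representable "
            f"position is {resid[0]:.3f} mm away")
    i, j, k = ijk[0]
    return ModelCoordinate(float(i), float(interpolator(chain).wrap_j(j)), float(k))


def image_to_model_batch(points: np.ndarray, chain: MRepChain,
                         tol: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`image_to_model`: returns ``(ijk, ok)``."""
    ijk, resid = _invert_batch(points, chain, tol=tol)
    return ijk, resid <= _INVERT_OK_MM


def correspond_batch(points: np.ndarray, ref_chain: MRepChain,
                     deformed_chain: MRepChain
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Tolerant vectorized :func:`correspond`: returns ``(mapped, ok)``
    where ``ok`` flags points whose model coordinates were resolvable in
    both chains (the rest carry undefined positions)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ijk, ok = image_to_model_batch(pts, ref_chain)
    interp = interpolator(deformed_chain)
    kmax = interp.kmax(ijk[:, 0], ijk[:, 1])
    ok = ok & (ijk[:, 2] <= kmax + 1e-6)
    mapped = interp.position(ijk[:, 0], ijk[:, 1], np.minimum(ijk[:, 2], kmax))
    return mapped, ok


def correspond(point, ref_chain: MRepChain, deformed_chain: MRepChain):
    """Map point(s) from the reference model's space to the deformed
    model's space via identical model-relative coordinates."""
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    ijk, ok = image_to_model_batch(np.atleast_2d(pts), ref_chain)
    if not np.all(ok):
        bad = int(np.count_nonzero(~ok))
        raise DomainError(f"{bad} point(s) outside the reference model (+rind)")
    interp = interpolator(deformed_chain)
    kmax = interp.kmax(ijk[:, 0], ijk[:, 1])
    mapped = interp.position(ijk[:, 0], ijk[:, 1], np.minimum(ijk[:, 2], kmax))
    if np.any(ijk[:, 2] > kmax + 1e-6):
        raise DomainError("corresponding point falls outside the deformed "
                          "model's rind domain")
    return mapped[0] if single else mapped


# ---------------------------------------------------------------------------
# Surface distance, masks, sections
# ---------------------------------------------------------------------------

def _dense_surface(chain: MRepChain, resolution: int = 8) -> tuple[np.ndarray, cKDTree, np.ndarray]:
    key = ("surf", resolution)
    cached = chain._cache.get(key)
    if cached is None:
        grid = surface_grid(chain, resolution)
        flat = grid.reshape(-1, 3)
        n, m = chain.n_atoms, chain.n_spokes
        ii = np.linspace(0.0, n - 1.0, (n - 1) * resolution + 1)
        jj = np.arange(m * resolution) / resolution
        I, J = np.meshgrid(ii, jj, indexing="ij")
        ij = np.stack([I, J], axis=-1).reshape(-1, 2)
        cached = (grid, cKDTree(flat), ij)
        chain._cache[key] = cached
    return cached


def surface_distance(points: np.ndarray, chain: MRepChain,
                     resolution: int = 8, max_iter: int = 15) -> np.ndarray:
    """Unsigned distance from world points to the interpolated surface.

    Dense-sample nearest neighbour seeding followed by local damped
    Gauss-Newton refinement over (i, j) at k = 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _, tree, ij_flat = _dense_surface(chain, resolution)
    interp = interpolator(chain)
    n = chain.n_atoms
    _, idx = tree.query(pts)
    x = ij_flat[idx].copy()

    def fv(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(interp.surface(x[:, 0], x[:, 1]) - pts, axis=1)

    f = fv(x)
    h = 1e-3
    for _ in range(max_iter):
        r = interp.surface(x[:, 0], x[:, 1]) - pts
        J = np.empty((x.shape[0], 3, 2))
        for v in range(2):
            xp = x.copy(); xp[:, v] += h
            xm = x.copy(); xm[:, v] -= h
            J[:, :, v] = (interp.surface(xp[:, 0], xp[:, 1])
                          - interp.surface(xm[:, 0], xm[:, 1])) / (2 * h)
        JtJ = np.einsum("nav,naw->nvw", J, J)
        g = np.einsum("nav,na->nv", J, r)
        JtJ[:, np.arange(2), np.arange(2)] += 1e-6 + 1e-3 * f[:, None]
        delta = -np.linalg.solve(JtJ, g[..., None])[..., 0]
        delta = np.clip(delta, -0.5, 0.5)
        xn = x + delta
        xn[:, 0] = np.clip(xn[:, 0], 0.0, n - 1.0)
        fn = fv(xn)
        better = fn < f
        x[better] = xn[better]
        f[better] = fn[better]
        if not np.any(better):
            break
    return f


def chain_mask(chain: MRepChain, volume: Volume3D,
               include_rind: bool = False,
               return_occupancy: bool = False):
    """Voxel-center containment mask of the chain surface (+rind).

    Voxels far from the boundary are classified by the sign of the
    offset along the nearest boundary sample's outward normal; voxels in
    a thin shell around the boundary are classified exactly by inverting
    the coordinate map.

    With ``return_occupancy`` a second float array is returned holding
    the approximate fraction of each voxel lying inside the surface
    (a box-filter partial-volume model along the local normal).
    """
    n, m = chain.n_atoms, chain.n_spokes
    interp = interpolator(chain)
    res = 4
    ii = np.linspace(0.0, n - 1.0, (n - 1) * res + 1)
    jj = np.arange(m * res) / res
    I, J = np.meshgrid(ii, jj, indexing="ij")
    kb = interp.kmax(I, J) if include_rind else np.ones_like(I)
    S = interp.position(I, J, kb)

    dSdi = np.gradient(S, axis=0)
    dSdj = np.gradient(S, axis=1)
    normals = np.cross(dSdi, dSdj)
    nn = np.linalg.norm(normals, axis=-1, keepdims=True)
    hub_line = interp.hub(I.reshape(-1)).reshape(S.shape)
    radial = S - hub_line
    small = nn[..., 0] < 1e-9
    normals = np.where(small[..., None],
                       radial / np.maximum(np.linalg.norm(radial, axis=-1,
                                                          keepdims=True), 1e-12),
                       normals / np.maximum(nn, 1e-12))
    flip = np.einsum("ijx,ijx->ij", normals, radial) < 0
    normals[flip] *= -1.0

    flatS = S.reshape(-1, 3)
    flatN = normals.reshape(-1, 3)
    tree = cKDTree(flatS)

    mask = np.zeros(volume.shape, dtype=bool)
    occ = np.zeros(volume.shape)
    pad = float(np.max(volume.spacing)) + 1.0
    lo = volume.index(flatS.min(axis=0) - pad)
    hi = volume.index(flatS.max(axis=0) + pad)
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int), np.array(volume.shape) - 1)
    if np.any(hi < lo):
        return (mask, occ) if return_occupancy else mask
    ax = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    G = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    P = volume.world(G)

    d, idx = tree.query(P)
    signed = np.einsum("na,na->n", P - flatS[idx], flatN[idx])
    shell_w = 0.6 * float(np.max(volume.spacing)) + 0.8
    shell = np.abs(signed) <= shell_w
    inside = signed < 0.0

    if np.any(shell):
        ijk, resid = _invert_batch(P[shell], chain, tol=0.01)
        kmax = interp.kmax(ijk[:, 0], ijk[:, 1]) if include_rind \
            else np.ones(ijk.shape[0])
        inside[shell] = (resid <= _INVERT_OK_MM) & (ijk[:, 2] <= kmax + 1e-9)

    sub = inside.reshape(tuple(hi - lo + 1))
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = sub
    if not return_occupancy:
        return mask
    width = np.abs(flatN[idx]) @ volume.spacing
    frac = np.clip(0.5 - signed / np.maximum(width, 1e-9), 0.0, 1.0)
    occ[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = \
        frac.reshape(tuple(hi - lo + 1))
    return mask, occ


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValidationError("both masks are empty")
    return 2.0 * np.count_nonzero(a & b) / float(denom)


def chain_axial_sections(chain: MRepChain, z_positions: Sequence[float],
                         n_vertices: int = 60) -> ContourStack:
    """Exact axial cross-sections of the interpolated chain surface.

    For each requested z plane, one vertex per azimuthal parameter line
    is found by bisection on the chain parameter ``i`` (surface z is
    monotone from the superior to the inferior pole along each line).
    """
    interp = interpolator(chain)
    n, m = chain.n_atoms, chain.n_spokes
    jj = np.arange(n_vertices) * m / n_vertices
    z_top = float(interp.surface(np.zeros(1), np.zeros(1))[0, 2])
    z_bot = float(interp.surface(np.full(1, n - 1.0), np.zeros(1))[0, 2])
    slices = []
    for z in z_positions:
        if not (min(z_top, z_bot) < z < max(z_top, z_bot)):
            continue
        lo = np.zeros(n_vertices)
        hi = np.full(n_vertices, n - 1.0)
        sign_top = np.sign(z_top - z)
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            zm = interp.surface(mid, jj)[:, 2]
            go_down = np.sign(zm - z) == sign_top
            lo = np.where(go_down, mid, lo)
            hi = np.where(go_down, hi, mid)
        mid = 0.5 * (lo + hi)
        pts = interp.surface(mid, jj)
        slices.append((float(z), pts[:, :2]))
    if not slices:
        raise ValidationError("no requested z plane intersects the surface")
    return ContourStack(slices)


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) on a reference grid; defined only on
    voxels inside the reference model (+rind)."""

    vectors: np.ndarray   # (nx, ny, nz, 3) mm
    defined: np.ndarray   # (nx, ny, nz) bool
    spacing: np.ndarray
    origin: np.ndarray


def displacement_field(ref_chain: MRepChain, deformed_chain: MRepChain,
                       grid: Volume3D) -> DisplacementField:
    """Vector field taking each defined reference voxel center to its
    post-deformation position (``correspond`` evaluated on the grid)."""
    mask = chain_mask(ref_chain, grid, include_rind=ref_chain.rind_mm > 0)
    vectors = np.zeros(grid.shape + (3,))
    if np.any(mask):
        vox = np.argwhere(mask)
        P = grid.world(vox)
        mapped, ok = correspond_batch(P, ref_chain, deformed_chain)
        vectors[mask] = np.where(ok[:, None], mapped - P, 0.0)
        if not np.all(ok):
            bad = vox[~ok]
            mask[bad[:, 0], bad[:, 1], bad[:, 2]] = False
    return DisplacementField(vectors, mask, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# Chain construction from a radial surface function
# ---------------------------------------------------------------------------

def chain_from_radial(center: np.ndarray,
                      radial: Callable[[np.ndarray, np.ndarray], np.ndarray],
                      n_atoms: int = DEFAULT_N_ATOMS,
                      n_spokes: int = DEFAULT_N_SPOKES,
                      hub_fraction: float = DEFAULT_HUB_FRACTION) -> MRepChain:
    """Build a chain for a star-shaped surface ``r = radial(theta, phi)``.

    ``theta`` is the polar angle from +z (superior), ``phi`` the azimuth
    from +x; hubs sit on the polar axis at ``hub_fraction`` of the local
    polar radius, atoms at uniform polar angles pole-to-pole.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if not 0.0 < hub_fraction < 1.0:
        raise ValidationError("hub_fraction must lie in (0, 1)")
    theta = np.pi * np.arange(n_atoms) / (n_atoms - 1)
    phi = spoke_azimuths(n_spokes)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    R = np.asarray(radial(T, P), dtype=float)
    if np.any(R <= 0):
        raise ValidationError("radial function must be positive")
    u = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1)
    tips = center + R[..., None] * u
    z_top = float(np.mean(radial(np.zeros(1), np.zeros(1))))
    z_bot = float(np.mean(radial(np.full(1, np.pi), np.zeros(1))))
    half = np.where(np.cos(theta) >= 0, z_top, z_bot)
    hub_z = hub_fraction * half * np.cos(theta)
    atoms = []
    for a in range(n_atoms):
        hub = center + np.array([0.0, 0.0, hub_z[a]])
        spokes = tips[a] - hub
        lengths = np.linalg.norm(spokes, axis=1)
        atoms.append(MedialAtom(hub, spokes / lengths[:, None], lengths))
    return MRepChain(atoms)


# ---------------------------------------------------------------------------
# Fitting a chain to planning contours
# ---------------------------------------------------------------------------

def _real_sh_basis(theta: np.ndarray, phi: np.ndarray,
                   degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Real spherical-harmonic design matrix and per-column degree."""
    from scipy.special import sph_harm_y

    cols = []
    degs = []
    for ell in range(degree + 1):
        for em in range(-ell, ell + 1):
            Y = sph_harm_y(ell, abs(em), theta, phi)
            if em < 0:
                col = np.sqrt(2.0) * np.imag(Y)
            elif em == 0:
                col = np.real(Y)
            else:
                col = np.sqrt(2.0) * np.real(Y)
            cols.append(col)
            degs.append(ell)
    return np.column_stack(cols), np.array(degs)


def _sh_radial(coeffs: np.ndarray, degree: int):
    def radial(theta, phi):
        B, _ = _real_sh_basis(np.asarray(theta, float).ravel(),
                              np.asarray(phi, float).ravel(), degree)
        return (B @ coeffs).reshape(np.shape(theta))
    return radial


@dataclass
class FitResult:
    """Fitted chain plus the contour-to-surface residual report."""

    chain: MRepChain
    mean_residual_mm: float          # mean over contours of per-contour means
    per_contour_residual_mm: np.ndarray
    center: np.ndarray
    converged: bool = True


def _validate_stack_for_fit(contours: ContourStack) -> None:
    if len(contours) < 3:
        raise ValidationError("need at least 3 contour slices")
    rings = contours.rings()
    prev = _ShPolygon(rings[0][1])
    for _, ring in rings[1:]:
        poly = _ShPolygon(ring)
        if not prev.intersects(poly) or prev.intersection(poly).area <= 0:
            raise ValidationError(
                "consecutive contours do not overlap: the stack does not "
                "enclose a simply connected volume")
        prev = poly


def fit_chain_to_contours(contours: ContourStack,
                          n_atoms: int = DEFAULT_N_ATOMS,
                          n_spokes: int = DEFAULT_N_SPOKES,
                          smoothness_weight: float = 1e-5,
                          sh_degree: int = 8,
                          hub_fraction: float = DEFAULT_HUB_FRACTION,
                          refine: bool = True) -> FitResult:
    """Fit an m-rep chain to a planning contour stack.

    The fit minimizes the mean contour-vertex-to-surface distance plus a
    curvature smoothness penalty in two stages: (1) a regularized real
    spherical-harmonic fit of the star-shaped radial surface about the
    stack's volume centroid (the smoothness term penalizes high angular
    frequencies, enforcing continuous curvature), then (2) a linear
    polish of the spoke-tip radii against the contour vertices with a
    discrete Laplacian curvature penalty.  The reported residual is the
    true vertex-to-surface distance averaged per contour.
    """
    _validate_stack_for_fit(contours)
    rings = contours.rings()
    areas = np.array([_ShPolygon(r).area for _, r in rings])
    cents = np.array([list(_ShPolygon(r).centroid.coords[0]) for _, r in rings])
    zs = contours.z_positions
    w = areas / areas.sum()
    center = np.array([w @ cents[:, 0], w @ cents[:, 1], w @ zs])

    verts = contours.all_vertices()
    coeffs = None
    for _ in range(3):
        rel = verts - center
        r = np.linalg.norm(rel, axis=1)
        theta = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        B, degs = _real_sh_basis(theta, phi, sh_degree)
        pen = smoothness_weight * len(r) * (degs * (degs + 1.0)) ** 2
        lhs = B.T @ B + np.diag(pen + 1e-12)
        try:
            coeffs = np.linalg.solve(lhs, B.T @ r)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("singular contour geometry") from exc
        # recenter on the numeric volume centroid of the fitted surface
        tg = np.linspace(0, np.pi, 64)
        pg = np.linspace(-np.pi, np.pi, 128, endpoint=False)
        TG, PG = np.meshgrid(tg, pg, indexing="ij")
        BG, _ = _real_sh_basis(TG.ravel(), PG.ravel(), sh_degree)
        RG = (BG @ coeffs).reshape(TG.shape)
        if np.any(RG <= 0):
            raise ValidationError("fitted surface collapsed; contours may "
                                  "cross or be too sparse")
        ug = np.stack([np.sin(TG) * np.cos(PG), np.sin(TG) * np.sin(PG),
                       np.cos(TG)], axis=-1)
        sw = np.sin(TG)
        vol = np.sum(RG ** 3 / 3.0 * sw)
        cen_off = np.einsum("ij,ijx->x", RG ** 4 / 4.0 * sw, ug) / vol
        center = center + cen_off
        if np.linalg.norm(cen_off) < 1e-3:
            break

    chain = chain_from_radial(center, _sh_radial(coeffs, sh_degree),
                              n_atoms, n_spokes, hub_fraction)

    if refine:
        chain = _polish_radii(chain, center, verts, smoothness_weight)

    per = np.array([
        float(np.mean(surface_distance(
            np.column_stack([ring, np.full(len(ring), z)]), chain)))
        for z, ring in rings
    ])
    return FitResult(chain, float(per.mean()), per, center)


def _polish_radii(chain: MRepChain, center: np.ndarray, verts: np.ndarray,
                  smoothness_weight: float) -> MRepChain:
    """One-shot linear re-solve of spoke-tip radii against the contour
    vertices with a squared discrete-Laplacian curvature penalty."""
    n, m = chain.n_atoms, chain.n_spokes
    tips = chain.tips
    R0 = np.linalg.norm(tips - center, axis=-1)

    rel = verts - center
    rv = np.linalg.norm(rel, axis=1)
    theta = np.arccos(np.clip(rel[:, 2] / rv, -1.0, 1.0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    iv = (n - 1) * theta / np.pi
    jv = np.mod((phi - SPOKE0_AZIMUTH) / (2 * np.pi) * m, m)

    wi = make_interp_spline(np.arange(n, dtype=float), np.eye(n), k=3)(iv)
    jp = np.arange(m + 1, dtype=float)
    Yp = np.vstack([np.eye(m), np.eye(m)[:1]])
    wj = CubicSpline(jp, Yp, bc_type="periodic")(jv)
    A = (wi[:, :, None] * wj[:, None, :]).reshape(len(rv), n * m)

    # discrete Laplacian (one-sided at chain ends, periodic around spokes)
    rows = []
    for a in range(n):
        for b in range(m):
            row = np.zeros((n, m))
            neigh = [(a, (b - 1) % m), (a, (b + 1) % m)]
            neigh += [(a - 1, b)] if a > 0 else [(a + 1, b)]
            neigh += [(a + 1, b)] if a < n - 1 else [(a - 1, b)]
            row[a, b] = len(neigh)
            for q in neigh:
                row[q] -= 1.0
            rows.append(row.ravel())
    L = np.array(rows)

    nv = len(rv)
    lam = smoothness_weight * nv
    anchor = 1e-4 * nv
    lhs = A.T @ A + lam * (L.T @ L) + anchor * np.eye(n * m)
    rhs = A.T @ (rv - A @ R0.ravel())
    try:
        dR = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        return chain
    R = np.clip(R0.ravel() + dR, 1e-3, None).reshape(n, m)

    theta_i = np.pi * np.arange(n) / (n - 1)
    phi_j = spoke_azimuths(m)
    T, P = np.meshgrid(theta_i, phi_j, indexing="ij")
    u = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1)
    new_tips = center + R[..., None] * u
    atoms = []
    for a in range(n):
        hub = chain.atoms[a].hub
        spokes = new_tips[a] - hub
        lengths = np.linalg.norm(spokes, axis=1)
        atoms.append(MedialAtom(hub, spokes / lengths[:, None], lengths))
    return MRepChain(atoms, rind_mm=chain.rind_mm)


# ---------------------------------------------------------------------------
# Shape space (per-patient statistical deformation model)
# ---------------------------------------------------------------------------

def chain_to_params(chain: MRepChain) -> np.ndarray:
    """Stack atom parameters: hub (3), log spoke lengths (m), spoke
    direction components (3m) per atom.  Log lengths keep synthesized
    lengths positive."""
    parts = []
    for a in chain.atoms:
        parts.append(a.hub)
        parts.append(np.log(a.lengths))
        parts.append(a.directions.ravel())
    return np.concatenate(parts)


def params_to_chain(params: np.ndarray, n_atoms: int, n_spokes: int,
                    rind_mm: float = 0.0) -> MRepChain:
    per = 3 + n_spokes + 3 * n_spokes
    params = np.asarray(params, dtype=float)
    if params.shape != (n_atoms * per,):
        raise ValidationError("parameter vector length mismatch")
    atoms = []
    for a in range(n_atoms):
        off = a * per
        hub = params[off:off + 3]
        lengths = np.exp(params[off + 3:off + 3 + n_spokes])
        dirs = params[off + 3 + n_spokes:off + per].reshape(n_spokes, 3)
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        atoms.append(MedialAtom(hub, dirs / norms, lengths))
    return MRepChain(atoms, rind_mm=rind_mm)


@dataclass
class ShapeSpace:
    """Mean chain plus orthonormal deformation modes over stacked atom
    parameters, ordered by non-increasing variance."""

    n_atoms: int
    n_spokes: int
    mean: np.ndarray        # (D,)
    modes: np.ndarray       # (M, D), orthonormal rows
    variances: np.ndarray   # (M,), non-negative, non-increasing

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if np.any(self.variances < -1e-12):
            raise ValidationError("negative mode variance")
        self.variances = np.clip(self.variances, 0.0, None)
        if np.any(np.diff(self.variances) > 1e-9):
            raise ValidationError("variances must be non-increasing")
        G = self.modes @ self.modes.T
        if not np.allclose(G, np.eye(self.modes.shape[0]), atol=1e-8):
            raise ValidationError("modes must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def mean_chain(self) -> MRepChain:
        return params_to_chain(self.mean, self.n_atoms, self.n_spokes)

    def synthesize(self, coefficients: np.ndarray | None = None) -> MRepChain:
        """Chain at the given mode coefficients (all zero -> mean chain)."""
        if coefficients is None:
            return self.mean_chain
        c = np.asarray(coefficients, dtype=float)
        if c.size > self.n_modes:
            raise ValidationError("more coefficients than modes")
        params = self.mean + c @ self.modes[:c.size]
        return params_to_chain(params, self.n_atoms, self.n_spokes)

    def n_modes_for_variance(self, fraction: float) -> int:
        total = self.variances.sum()
        if total == 0:
            return 0
        cum = np.cumsum(self.variances) / total
        return int(np.searchsorted(cum, fraction - 1e-12) + 1)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_atoms": self.n_atoms, "n_spokes": self.n_spokes,
                       "mean": self.mean.tolist(), "modes": self.modes.tolist(),
                       "variances": self.variances.tolist()}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeSpace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["n_atoms"], d["n_spokes"], np.array(d["mean"]),
                   np.array(d["modes"]), np.array(d["variances"]))


def build_shape_space(training_chains: Sequence[MRepChain]) -> ShapeSpace:
    """Principal modes of the stacked atom-parameter vectors of rigidly
    pre-aligned training chains."""
    if len(training_chains) < 2:
        raise ValidationError("need at least 2 training chains")
    n = training_chains[0].n_atoms
    m = training_chains[0].n_spokes
    for c in training_chains:
        if c.n_atoms != n or c.n_spokes != m:
            raise ValidationError("training chains have mismatched topologies")
    X = np.array([chain_to_params(c) for c in training_chains])
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nm = min(len(training_chains) - 1, Vt.shape[0])
    variances = (s[:nm] ** 2) / (len(training_chains) - 1)
    return ShapeSpace(n, m, mean, Vt[:nm], variances)
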