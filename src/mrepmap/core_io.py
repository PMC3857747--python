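"""Core containers and file I/O.

World coordinate convention used throughout the package: ``x`` is the
patient's lateral axis, ``y`` anterior--posterior (+y posterior), ``z``
craniocaudal (+z superior).  All positions, spacings and translations
are in millimetres.  Volumes are stored as ``data[ix, iy, iz]`` with

    world(v) = origin + v * spacing

for an integer voxel index ``v`` (world positions refer to voxel
centers, indices are 0-based).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon as _ShPolygon

from .errors import FormatError, ValidationError

logger = logging.getLogger("mrepmap")

__all__ = [
    "Volume3D",
    "ContourStack",
    "PointSet",
    "DVHCurve",
    "read_volume",
    "write_volume",
    "read_contours",
    "write_contours",
    "read_points",
    "write_points",
    "read_transform",
    "write_transform",
    "read_config",
    "setup_logging",
]


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """A scalar 3D grid (CT intensity in HU-like units, or dose in cGy).

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``.
    spacing:
        Voxel spacing per axis in mm, all components > 0.
    origin:
        World position (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValidationError("spacing and origin must be length-3 vectors")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world(self, index: np.ndarray) -> np.ndarray:
        """World position(s) of (possibly fractional) voxel indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index(self, world: np.ndarray) -> np.ndarray:
        """Continuous voxel index/indices of world position(s)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def grid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def sample(self, points_mm: np.ndarray, order: int = 1,
               cval: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world points of shape ``(n, 3)``.

        Trilinear by default; points outside the grid get ``cval``.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.index(pts).T  # (3, n)
        return map_coordinates(self.data.astype(float), idx, order=order,
                               mode="constant", cval=cval)

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """True where world points fall inside the voxel-center grid."""
        idx = self.index(np.atleast_2d(points_mm))
        hi = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=1)

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data, self.spacing.copy(), self.origin.copy())


def _to_sitk(vol: Volume3D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))  # -> (z,y,x)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume to NRRD / NIfTI / MetaImage, chosen by extension."""
    sitk.WriteImage(_to_sitk(vol), str(path))


def read_volume(path: str | Path) -> Volume3D:
    """Read a volume (NRRD / NIfTI / MetaImage) with spacing and origin."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps parse failures in RuntimeError
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return Volume3D(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


# ---------------------------------------------------------------------------
# Contour stacks
# ---------------------------------------------------------------------------

def _canonical_polygon(vertices: np.ndarray) -> np.ndarray:
    """Return the closed form (first vertex repeated last) of a polygon.

    Accepts either the open ring or the already-closed form; validates
    vertex count and simplicity (no self-intersection).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValidationError("polygon vertices must have shape (n, 2)")
    if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
        ring = v[:-1]
    else:
        ring = v
    if ring.shape[0] < 3:
        raise ValidationError(f"polygon needs >= 3 distinct vertices, got {ring.shape[0]}")
    if not _ShPolygon(ring).is_valid:
        raise ValidationError("polygon is self-intersecting or degenerate")
    return np.vstack([ring, ring[:1]])


@dataclass
class ContourStack:
    """Planar closed contours at increasing axial (z) positions.

    ``slices`` is a list of ``(z_mm, vertices)`` where vertices is an
    ``(n, 2)`` array of in-plane ``(x, y)`` mm coordinates stored in
    closed form (first vertex repeated as the last).
    """

    slices: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        canon = [(float(z), _canonical_polygon(v)) for z, v in self.slices]
        zs = np.array([z for z, _ in canon])
        if zs.size and np.any(np.diff(zs) <= 0):
            if np.unique(zs).size != zs.size:
                raise ValidationError("duplicate contour z positions")
            warnings.warn("contour slices out of z order; reordering", stacklevel=2)
            canon = sorted(canon, key=lambda t: t[0])
        self.slices = canon

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices])

    def rings(self) -> list[tuple[float, np.ndarray]]:
        """Slices with the duplicated closing vertex dropped."""
        return [(z, v[:-1]) for z, v in self.slices]

    def all_vertices(self) -> np.ndarray:
        """All distinct contour vertices as an (n, 3) world array."""
        out = [np.column_stack([v, np.full(len(v), z)]) for z, v in self.rings()]
        return np.vstack(out)


def write_contours(stack: ContourStack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mrepmap contours v1 units=mm\n")
        for z, verts in stack.slices:
            fh.write(f"slice z= {z:.9g}\n")
            for x, y in verts:
                fh.write(f"{x:.9g} {y:.9g}\n")
            fh.write("end\n")


def read_contours(path: str | Path) -> ContourStack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such contour file: {path}")
    slices: list[tuple[float, np.ndarray]] = []
    z: float | None = None
    verts: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("slice"):
                try:
                    z = float(line.split("=")[1])
                except (IndexError, ValueError) as exc:
                    raise FormatError(f"bad slice header: {line!r}") from exc
                verts = []
            elif line == "end":
                if z is None:
                    raise FormatError("'end' before any slice header")
                slices.append((z, np.array(verts)))
                z = None
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"bad vertex line: {line!r}")
                verts.append([float(parts[0]), float(parts[1])])
    if z is not None:
        raise FormatError("unterminated slice block")
    if not slices:
        raise FormatError("no contour slices found")
    return ContourStack(slices)


# ---------------------------------------------------------------------------
# Labeled point sets
# ---------------------------------------------------------------------------

@dataclass
class PointSet:
    """Labeled 3D points in mm (BBs, skin marks, isocenters)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for label, p in self.points.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,):
                raise ValidationError(f"point {label!r} must be a 3-vector")
            if label in clean:
                raise ValidationError(f"duplicate point label {label!r}")
            clean[str(label)] = p
        self.points = clean

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    @property
    def labels(self) -> list[str]:
        return list(self.points)

    def array(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = list(self.points) if labels is None else list(labels)
        return np.array([self.points[l] for l in labels])

    @classmethod
    def from_arrays(cls, labels: Iterable[str], points: np.ndarray) -> "PointSet":
        return cls(dict(zip(labels, np.asarray(points, dtype=float))))


def write_points(ps: PointSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mrepmap points v1 units=mm\n")
        for label, p in ps.points.items():
            fh.write(f"{label} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def read_points(path: str | Path) -> PointSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such point file: {path}")
    pts: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"bad point line: {line!r}")
            if parts[0] in pts:
                raise ValidationError(f"duplicate point label {parts[0]!r}")
            pts[parts[0]] = np.array([float(x) for x in parts[1:]])
    return PointSet(pts)


# ---------------------------------------------------------------------------
# Transforms (pure translations, mm)
# ---------------------------------------------------------------------------

def write_transform(translation_mm: np.ndarray, path: str | Path) -> None:
    t = np.asarray(translation_mm, dtype=float).reshape(3)
    with open(path, "w") as fh:
        fh.write("# mrepmap transform v1 translation mm\n")
        fh.write(f"{t[0]:.9g} {t[1]:.9g} {t[2]:.9g}\n")


def read_transform(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such transform file: {path}")
    vals: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            vals.extend(float(x) for x in line.split())
    if len(vals) != 3:
        raise FormatError(f"transform file must hold exactly 3 floats, got {len(vals)}")
    return np.array(vals)


# ---------------------------------------------------------------------------
# Dose-volume histograms
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Differential DVH (cm^3 per dose bin) with a derived cumulative curve.

    ``bin_edges`` has length ``nbins + 1`` (cGy); ``differential_cm3``
    holds the region volume falling in each bin.
    """

    bin_edges: np.ndarray
    differential_cm3: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.differential_cm3 = np.asarray(self.differential_cm3, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValidationError("need at least one dose bin")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if self.differential_cm3.shape != (self.bin_edges.size - 1,):
            raise ValidationError("differential histogram / edge count mismatch")
        if np.any(self.differential_cm3 < 0):
            raise ValidationError("negative bin volume")

    @property
    def total_volume_cm3(self) -> float:
        return float(self.differential_cm3.sum())

    @property
    def cumulative_percent(self) -> np.ndarray:
        """% of region volume receiving >= each bin's lower edge.

        Length ``nbins``; starts at 100% and is non-increasing.
        """
        total = self.total_volume_cm3
        if total == 0:
            raise ValidationError("empty region: cumulative DVH undefined")
        tail = np.cumsum(self.differential_cm3[::-1])[::-1]
        return 100.0 * tail / total

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "bin_low_cGy": self.bin_edges[:-1],
                "bin_high_cGy": self.bin_edges[1:],
                "differential_cm3": self.differential_cm3,
                "cumulative_percent": self.cumulative_percent,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DVHCurve":
        import pandas as pd

        df = pd.read_csv(path)
        edges = np.append(df["bin_low_cGy"].to_numpy(),
                          df["bin_high_cGy"].to_numpy()[-1])
        return cls(edges, df["differential_cm3"].to_numpy())


# ---------------------------------------------------------------------------
# Run configuration and logging
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a ``key = value`` configuration file (one pair per line)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"bad config line: {raw.rstrip()!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def setup_logging(log_file: str | Path | None = None,
                  level: int = logging.INFO) -> logging.Logger:
    """Configure the package logger; every stage logs its parameters."""
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(str(log_file))
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


def log_params(stage: str, params: Mapping[str, object]) -> None:
    logger.info("%s: %s", stage, " ".join(f"{k}={v}" for k, v in params.items()))
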