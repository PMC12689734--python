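"""Point-cloud containers, rigid-transform algebra and file I/O.

All coordinates are in millimetres, right-handed. Rigid transforms act on
column vectors as ``y = R x + t`` and serialize as row-major 4x4 homogeneous
matrices. Supported point-cloud formats are PLY (ascii and
binary_little_endian, only the x/y/z vertex properties are consumed),
PCD (ascii) and whitespace-separated XYZ text with ``#`` comments.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PointCloud",
    "RigidTransform",
    "EvalCase",
    "read_point_cloud",
    "write_point_cloud",
    "read_transform",
    "write_transform",
    "apply_transform",
    "voxel_downsample",
]


class PointCloudFormatError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class PointCloud:
    """An ordered set of 3-D points in mm with optional per-point weights."""

    points: np.ndarray
    weights: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be N x 3, got shape {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.points),):
                raise ValueError("weights must be one scalar per point")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Copy of this cloud with new coordinates (same weights/label)."""
        w = None if self.weights is None else self.weights.copy()
        return PointCloud(points=np.asarray(points, dtype=float), weights=w, label=self.label)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: rotation (det +1 orthonormal) plus translation in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    _TOL = 1e-9

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass
class EvalCase:
    """A fixed/moving cloud pair with optional tumor landmarks and ground truth."""

    fixed: PointCloud
    moving: PointCloud
    tumor_centers_fixed: np.ndarray | None = None
    tumor_centers_moving: np.ndarray | None = None
    tumor_masks: list | None = None
    ground_truth: RigidTransform | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tumor_centers_fixed is not None:
            self.tumor_centers_fixed = np.atleast_2d(np.asarray(self.tumor_centers_fixed, float))
        if self.tumor_centers_moving is not None:
            self.tumor_centers_moving = np.atleast_2d(np.asarray(self.tumor_centers_moving, float))
        if self.tumor_centers_fixed is not None and self.tumor_centers_moving is not None:
            if len(self.tumor_centers_fixed) != len(self.tumor_centers_moving):
                raise ValueError("tumor-center lists must have equal length")


@dataclass
class VoxelMask:
    """A boolean voxel volume with world origin and spacing (mm)."""

    data: np.ndarray
    origin: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be > 0")


# ---------------------------------------------------------------------------
# file formats


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "pcd", "xyz"):
        return suffix
    if suffix in ("txt", "pts"):
        return "xyz"
    raise PointCloudFormatError(f"cannot infer point-cloud format from '{path.name}'")


def read_point_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a point cloud from a PLY / PCD / XYZ file (coordinates in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point-cloud file not found: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "xyz":
        pts = _read_xyz(path)
    elif fmt == "ply":
        pts = _read_ply(path)
    elif fmt == "pcd":
        pts = _read_pcd(path)
    else:
        raise PointCloudFormatError(f"unsupported format '{fmt}'")
    return PointCloud(points=pts)


def write_point_cloud(
    pc: PointCloud,
    path: str | Path,
    format: str = "auto",
    *,
    binary: bool = False,
    make_parents: bool = False,
) -> None:
    """Write a point cloud; ``binary`` selects binary_little_endian for PLY."""
    path = Path(path)
    if make_parents:
        path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "xyz":
        _write_xyz(pc.points, path)
    elif fmt == "ply":
        _write_ply(pc.points, path, binary=binary)
    elif fmt == "pcd":
        _write_pcd(pc.points, path)
    else:
        raise PointCloudFormatError(f"unsupported format '{fmt}'")


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) < 3:
                raise PointCloudFormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise PointCloudFormatError(f"{path}:{lineno}: non-numeric coordinate ({exc})") from exc
    if not rows:
        raise PointCloudFormatError(f"{path}: no points found")
    return np.asarray(rows, dtype=float)


def _write_xyz(points: np.ndarray, path: Path) -> None:
    # 17 significant digits round-trips IEEE doubles exactly
    with open(path, "w") as fh:
        for x, y, z in points:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
    "char": ("b", 1), "int8": ("b", 1),
    "uchar": ("B", 1), "uint8": ("B", 1),
    "short": ("h", 2), "int16": ("h", 2),
    "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4),
    "uint": ("I", 4), "uint32": ("I", 4),
}


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise PointCloudFormatError(f"{path}: missing 'ply' magic line")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            raw = fh.readline()
            if not raw:
                raise PointCloudFormatError(f"{path}: truncated header")
            line = raw.decode("ascii", errors="replace").strip()
            if line.startswith("comment") or line.startswith("obj_info") or not line:
                continue
            parts = line.split()
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                elements.append((parts[1], int(parts[2]), []))
            elif parts[0] == "property":
                if parts[1] == "list":
                    elements[-1][2].append(("list:" + parts[2] + ":" + parts[3], parts[4]))
                else:
                    elements[-1][2].append((parts[1], parts[2]))
            elif parts[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudFormatError(f"{path}: unsupported PLY format '{fmt}'")
        for name, count, props in elements:
            if name == "vertex":
                return _read_ply_vertices(fh, path, fmt, count, props)
            _skip_ply_element(fh, path, fmt, count, props)
    raise PointCloudFormatError(f"{path}: no vertex element")


def _ply_prop_index(props: list[tuple[str, str]], path: Path) -> tuple[list[int], list[str]]:
    names = [p[1] for p in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise PointCloudFormatError(f"{path}: vertex element lacks property '{axis}'")
    return [names.index(a) for a in ("x", "y", "z")], names


def _read_ply_vertices(fh, path, fmt, count, props) -> np.ndarray:
    xyz_idx, _ = _ply_prop_index(props, path)
    if fmt == "ascii":
        pts = np.empty((count, 3))
        for i in range(count):
            parts = fh.readline().split()
            if len(parts) < len(props):
                raise PointCloudFormatError(f"{path}: vertex record {i} too short")
            pts[i] = [float(parts[j]) for j in xyz_idx]
        return pts
    codes = []
    for typ, _name in props:
        if typ.startswith("list:"):
            raise PointCloudFormatError(f"{path}: list property on vertex element unsupported")
        codes.append(_PLY_TYPES[typ])
    record = struct.Struct("<" + "".join(c for c, _ in codes))
    buf = fh.read(record.size * count)
    if len(buf) != record.size * count:
        raise PointCloudFormatError(f"{path}: truncated binary vertex data")
    rows = [record.unpack_from(buf, i * record.size) for i in range(count)]
    arr = np.asarray(rows, dtype=float)
    return arr[:, xyz_idx]


def _skip_ply_element(fh, path, fmt, count, props) -> None:
    if fmt == "ascii":
        for _ in range(count):
            fh.readline()
        return
    for _ in range(count):
        for typ, _name in props:
            if typ.startswith("list:"):
                _, count_t, item_t = typ.split(":")
                ccode, csize = _PLY_TYPES[count_t]
                n = struct.unpack("<" + ccode, fh.read(csize))[0]
                fh.read(_PLY_TYPES[item_t][1] * n)
            else:
                fh.read(_PLY_TYPES[typ][1])


def _write_ply(points: np.ndarray, path: Path, binary: bool) -> None:
    n = len(points)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\nelement vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\nend_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(points, dtype="<f8").tobytes())
        else:
            for x, y, z in points:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n".encode("ascii"))


def _read_pcd(path: Path) -> np.ndarray:
    fields: list[str] = []
    n_points = None
    data_mode = None
    with open(path, "r") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#") or not stripped:
            continue
        key, *rest = stripped.split()
        if key == "FIELDS":
            fields = rest
        elif key == "POINTS":
            n_points = int(rest[0])
        elif key == "DATA":
            data_mode = rest[0]
            body_start = i + 1
            break
    if data_mode != "ascii":
        raise PointCloudFormatError(f"{path}: only ascii PCD supported, got DATA {data_mode}")
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise PointCloudFormatError(f"{path}: PCD lacks field '{axis}'")
    idx = [fields.index(a) for a in ("x", "y", "z")]
    rows = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        try:
            rows.append([float(parts[j]) for j in idx])
        except (ValueError, IndexError) as exc:
            raise PointCloudFormatError(f"{path}:{lineno}: bad PCD record ({exc})") from exc
    if n_points is not None and len(rows) != n_points:
        raise PointCloudFormatError(f"{path}: POINTS says {n_points}, found {len(rows)}")
    return np.asarray(rows, dtype=float)


def _write_pcd(points: np.ndarray, path: Path) -> None:
    n = len(points)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\nVERSION 0.7\n"
        "FIELDS x y z\nSIZE 8 8 8\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for x, y, z in points:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def write_transform(T: RigidTransform, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": T.as_matrix().tolist(), "units": "mm"}, fh, indent=2)
        fh.write("\n")


def read_transform(path: str | Path) -> RigidTransform:
    with open(path) as fh:
        payload = json.load(fh)
    return RigidTransform.from_matrix(np.asarray(payload["matrix"], dtype=float))


# ---------------------------------------------------------------------------
# geometry


def apply_transform(pc: PointCloud, T: RigidTransform) -> PointCloud:
    """Rigidly move every point; weights, order and label are preserved."""
    return pc.with_points(T.apply(pc.points))


def voxel_downsample(pc: PointCloud, voxel_edge: float) -> PointCloud:
    """Replace each occupied voxel by the centroid of its member points.

    Binning uses the absolute grid of half-open cells [i*e, (i+1)*e) anchored
    at the origin, which makes downsampling exactly idempotent: a cell's
    centroid lies inside that same cell, so a second pass with the same edge
    changes nothing. Output order follows the first-seen input index of each
    voxel, so downsampling is deterministic.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be > 0")
    pts = pc.points
    keys = np.floor(pts / voxel_edge).astype(np.int64)
    _, first_idx, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    groups = rank[inverse]
    n_vox = len(first_idx)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, groups, pts)
    counts = np.bincount(groups, minlength=n_vox).astype(float)
    centroids = sums / counts[:, None]
    return PointCloud(points=centroids, label=pc.label)
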