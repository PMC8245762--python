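"""Volume and fiducial I/O.

All positions handled by this package live in RAS (Right-Anterior-Superior)
world millimeters; voxel indices are 0-based and appear only transiently
inside operations. Volumes are NIfTI-1/NIfTI-2 on disk; labeled landmark
points use 3D Slicer's Markups ``.fcsv`` comma-separated format.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "FiducialSet",
    "FormatError",
    "load_volume",
    "save_volume",
    "map_coordinates",
    "load_fiducials",
    "write_fiducials",
]


class FormatError(ValueError):
    """Raised for malformed volume or fiducial files."""


@dataclass
class Volume:
    """A 3D scalar image plus the affine taking 0-based voxel indices to RAS mm."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"Volume requires a 3D array, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx) -> np.ndarray:
        return map_coordinates(self, idx, "voxel_to_world")

    def world_to_voxel(self, pos) -> np.ndarray:
        return map_coordinates(self, pos, "world_to_voxel")


@dataclass
class FiducialSet:
    """Ordered labeled 3D points in RAS millimeters."""

    points: list[tuple[str, np.ndarray]] = field(default_factory=list)
    coordinate_system: str = "RAS"

    def __post_init__(self) -> None:
        if self.coordinate_system != "RAS":
            raise FormatError(
                f"FiducialSet must be RAS internally, got {self.coordinate_system!r}"
            )
        pts = []
        seen: set[str] = set()
        for label, pos in self.points:
            pos = np.asarray(pos, dtype=float).reshape(3)
            if not np.all(np.isfinite(pos)):
                raise FormatError(f"non-finite position for label {label!r}")
            if label in seen:
                raise FormatError(f"duplicate fiducial label {label!r}")
            seen.add(label)
            pts.append((str(label), pos))
        self.points = pts

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, label: str) -> np.ndarray:
        for lab, pos in self.points:
            if lab == label:
                return pos
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def positions(self) -> np.ndarray:
        """All positions as an (n, 3) array, in insertion order."""
        if not self.points:
            return np.zeros((0, 3))
        return np.stack([pos for _, pos in self.points])


def load_volume(path) -> Volume:
    """Read a NIfTI-1/NIfTI-2 file as a :class:`Volume` with an RAS affine.

    nibabel exposes NIfTI affines in RAS+ convention regardless of the
    on-disk qform/sform orientation codes, so no reorientation is needed.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"expected a 3D volume, got {data.ndim}D data with shape {data.shape} in {path}"
        )
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def save_volume(v: Volume, path) -> None:
    """Write ``v`` as NIfTI; data is passed through bit-for-bit."""
    if not np.all(np.isfinite(v.data)):
        logger.warning("volume written to %s contains non-finite voxels", path)
    img = nib.Nifti1Image(v.data, v.affine)
    nib.save(img, str(path))


def map_coordinates(v: Volume, coords, direction: str) -> np.ndarray:
    """Apply the volume affine (or its inverse) to one 3-vector.

    ``voxel_to_world`` maps a (possibly fractional) 0-based voxel index to RAS
    mm; ``world_to_voxel`` maps RAS mm to a continuous voxel index. No
    rounding or bounds checking is performed.
    """
    coords = np.asarray(coords, dtype=float).reshape(3)
    if direction == "voxel_to_world":
        return v.affine[:3, :3] @ coords + v.affine[:3, 3]
    if direction == "world_to_voxel":
        return np.linalg.solve(v.affine[:3, :3], coords - v.affine[:3, 3])
    raise ValueError(f"unknown direction {direction!r}")


_FCSV_COLUMNS = "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"


def _parse_coordinate_system(token: str) -> str:
    """Normalize both Slicer header dialects: numeric (0=RAS, 1=LPS) and textual."""
    token = token.strip()
    if token in ("0", "RAS"):
        return "RAS"
    if token in ("1", "LPS"):
        return "LPS"
    raise FormatError(f"unknown coordinate system tag {token!r} in .fcsv header")


def load_fiducials(path) -> FiducialSet:
    """Read a Slicer Markups ``.fcsv`` file; positions are returned in RAS mm.

    If the header declares LPS, x and y are negated on load. Both the
    numeric (Slicer <=4.10) and textual (>=4.11) coordinate-system header
    dialects are accepted.
    """
    system = "RAS"
    points: list[tuple[str, np.ndarray]] = []
    with open(path, newline="") as fh:
        data_lines: list[tuple[int, str]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*CoordinateSystem\s*=\s*(\S+)", line)
                if m:
                    system = _parse_coordinate_system(m.group(1))
                continue
            data_lines.append((lineno, line))
    for lineno, line in data_lines:
        row = next(csv.reader(io.StringIO(line)))
        if len(row) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected coordinate columns x,y,z after id "
                f"(fcsv layout {_FCSV_COLUMNS}), got {len(row)} fields"
            )
        try:
            pos = np.array([float(row[1]), float(row[2]), float(row[3])])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from exc
        if system == "LPS":
            pos[0] = -pos[0]
            pos[1] = -pos[1]
        label = row[11] if len(row) > 11 else row[0]
        points.append((label, pos))
    return FiducialSet(points=points)


def write_fiducials(f: FiducialSet, path) -> None:
    """Write a Slicer-compatible ``.fcsv`` with the textual RAS header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write(f"# columns = {_FCSV_COLUMNS}\n")
        writer = csv.writer(fh)
        for i, (label, pos) in enumerate(f.points):
            writer.writerow(
                [
                    f"vtkMRMLMarkupsFiducialNode_{i}",
                    f"{pos[0]:.6f}",
                    f"{pos[1]:.6f}",
                    f"{pos[2]:.6f}",
                    0, 0, 0, 1, 1, 1, 0,
                    label,
                    "",
                    "",
                ]
            )
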