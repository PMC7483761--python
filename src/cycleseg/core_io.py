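"""Volume and annotation I/O, coordinate conventions, and dataset splitting.

Conventions used throughout the package:

* Volumes are ``numpy`` arrays indexed ``[z][y][x]`` (depth, height, width).
* Point annotations are 0-based voxel coordinates ``(x, y, z, t)`` where
  ``x`` indexes the width axis, ``y`` the height axis and ``z`` the slice.
  Fractional coordinates are allowed: nucleus centers may sit between
  voxel grid points.
* Multi-page TIFF files hold one z-slice per page. RGB pages are collapsed
  to a scalar per voxel (maximum across channels by default, since the
  marker and the cell walls share one fluorescence color).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelVolume",
    "TimeSeries",
    "AnnotationTable",
    "DatasetSplit",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "split_by_sequence",
]

ANNOTATION_COLUMNS = ("x", "y", "z", "t")


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid, shape ``(depth z, height y, width x)``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x); got shape {data.shape}")
        if any(s < 1 for s in data.shape):
            raise ValueError(f"all volume dimensions must be >= 1; got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class TimeSeries:
    """Ordered volumes of one root captured over time."""

    volumes: list[VoxelVolume]
    sequence_id: str

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"all volumes in a series must share one shape; got {shapes}")

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class AnnotationTable:
    """Point records marking nucleus centers, columns ``x, y, z, t``."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(ANNOTATION_COLUMNS)))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.records = df[list(ANNOTATION_COLUMNS)].astype(float).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def at_time(self, t: int) -> "AnnotationTable":
        """Records of a single time point."""
        return AnnotationTable(self.records[self.records["t"] == t])

    def points(self) -> np.ndarray:
        """``(n, 3)`` array of ``(x, y, z)`` coordinates."""
        return self.records[["x", "y", "z"]].to_numpy(dtype=float)

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        """Check all coordinates fall inside a ``(z, y, x)`` volume shape."""
        nz, ny, nx = shape
        r = self.records
        ok = (
            (r["x"] >= 0) & (r["x"] < nx)
            & (r["y"] >= 0) & (r["y"] < ny)
            & (r["z"] >= 0) & (r["z"] < nz)
            & (r["t"] >= 0)
        )
        if not bool(ok.all()):
            bad = r[~ok].index.tolist()
            raise ValueError(f"annotations out of bounds for shape {shape}: rows {bad}")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test lists of ``(sequence_id, time index)``."""

    train: list[tuple[str, int]]
    validation: list[tuple[str, int]]
    test: list[tuple[str, int]]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError("split partitions overlap")


def read_volume(path: str | Path, channel: int | None = None) -> VoxelVolume:
    """Read a multi-page TIFF as a volume, one z-slice per page.

    Multi-channel pages are collapsed to a scalar per voxel using the
    per-voxel maximum across channels, or a single named ``channel``
    index when given.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - tifffile error path
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim == 4:  # (z, y, x, c) or (z, c, y, x)
        # tifffile yields channel-last for RGB pages
        if data.shape[-1] <= 4:
            data = data[..., channel] if channel is not None else data.max(axis=-1)
        elif data.shape[1] <= 4:
            data = data[:, channel] if channel is not None else data.max(axis=1)
        else:
            raise ValueError(f"cannot interpret TIFF axes for shape {data.shape}")
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}")
    return VoxelVolume(data)


def write_volume(volume: VoxelVolume | np.ndarray, path: str | Path) -> None:
    """Write a volume as an uncompressed multi-page TIFF (page i = slice i)."""
    if not isinstance(volume, VoxelVolume):
        volume = VoxelVolume(np.asarray(volume))  # enforce the volume invariants
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(str(path), volume.data, photometric="minisblack")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a point-annotation CSV with header columns x, y, z, t."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns: {sorted(missing)}")
    for col in ANNOTATION_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column '{col}' at line {row} of {path}")
    return AnnotationTable(df)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False, columns=list(ANNOTATION_COLUMNS))


def split_by_sequence(
    series: Sequence[TimeSeries],
    test_sequence: str,
    n_validation: int,
    seed: int = 0,
) -> DatasetSplit:
    """Split time points into train/validation/test, holding out one sequence.

    All time points of ``test_sequence`` go to the test partition;
    ``n_validation`` time points are drawn uniformly without replacement
    from the remaining sequences under ``seed``; the rest train.
    """
    ids = [s.sequence_id for s in series]
    if test_sequence not in ids:
        raise ValueError(f"unknown test sequence {test_sequence!r}; have {ids}")
    test = [(s.sequence_id, t) for s in series if s.sequence_id == test_sequence for t in range(len(s))]
    pool = [(s.sequence_id, t) for s in series if s.sequence_id != test_sequence for t in range(len(s))]
    if n_validation >= len(pool) + 1 and n_validation > 0:
        raise ValueError(f"n_validation={n_validation} exceeds available non-test points ({len(pool)})")
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(len(pool), size=n_validation, replace=False).tolist()) if n_validation else set()
    validation = [p for i, p in enumerate(pool) if i in val_idx]
    train = [p for i, p in enumerate(pool) if i not in val_idx]
    return DatasetSplit(train=train, validation=validation, test=test)
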