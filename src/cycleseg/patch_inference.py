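"""Overlapping-patch decomposition and stitching for large volumes.

Full confocal stacks are too large for a single network forward pass, so
volumes are processed as overlapping fixed-size patches (default 25%
overlap in every direction) whose predictions are merged back by
per-voxel averaging. Overlap, rather than plain tiling, keeps nuclei from
being cropped at patch borders. Per axis the patch origins advance by
stride = round(size * (1 - overlap)); the final origin is clamped so the
last patch ends exactly at the volume edge and no partial patches exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["PatchPlan", "plan_patches", "extract_patches", "stitch_patches"]


@dataclass
class PatchPlan:
    patch_size: tuple[int, int, int]
    overlap: float
    origins: list[tuple[int, int, int]]
    volume_shape: tuple[int, int, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PatchPlan":
        d = json.loads(text)
        return cls(
            patch_size=tuple(d["patch_size"]),
            overlap=d["overlap"],
            origins=[tuple(o) for o in d["origins"]],
            volume_shape=tuple(d["volume_shape"]),
        )


def _axis_origins(length: int, size: int, overlap: float) -> list[int]:
    stride = max(1, int(np.floor(size * (1.0 - overlap) + 0.5)))  # round half up
    last = length - size
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def plan_patches(
    volume_shape: tuple[int, int, int],
    patch_size: tuple[int, int, int],
    overlap: float = 0.25,
) -> PatchPlan:
    """Plan fully-inside patch origins covering every voxel."""
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    if any(p > v for p, v in zip(patch_size, volume_shape)):
        raise ValueError(f"patch {patch_size} exceeds volume {volume_shape}")
    per_axis = [_axis_origins(v, p, overlap) for v, p in zip(volume_shape, patch_size)]
    origins = [(z, y, x) for z in per_axis[0] for y in per_axis[1] for x in per_axis[2]]
    return PatchPlan(tuple(patch_size), overlap, origins, tuple(volume_shape))


def extract_patches(volume: np.ndarray, plan: PatchPlan) -> list[np.ndarray]:
    volume = np.asarray(volume)
    if volume.shape != plan.volume_shape:
        raise ValueError(f"volume shape {volume.shape} does not match plan {plan.volume_shape}")
    pz, py, px = plan.patch_size
    return [volume[z : z + pz, y : y + py, x : x + px] for z, y, x in plan.origins]


def stitch_patches(patches: list[np.ndarray], plan: PatchPlan) -> np.ndarray:
    """Merge patches back to full volume; overlaps average their values."""
    if len(patches) != len(plan.origins):
        raise ValueError(f"got {len(patches)} patches for {len(plan.origins)} origins")
    acc = np.zeros(plan.volume_shape, dtype=np.float64)
    count = np.zeros(plan.volume_shape, dtype=np.float64)
    pz, py, px = plan.patch_size
    for patch, (z, y, x) in zip(patches, plan.origins):
        if patch.shape != plan.patch_size:
            raise ValueError(f"patch shape {patch.shape} does not match plan {plan.patch_size}")
        acc[z : z + pz, y : y + py, x : x + px] += patch
        count[z : z + pz, y : y + py, x : x + px] += 1.0
    return acc / count
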