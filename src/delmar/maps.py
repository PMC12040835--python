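"""Labeled sets of voxel-wise network maps tied to a brain mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_mask import BrainMask

__all__ = ["SpatialMapSet", "sign_fix"]


def sign_fix(maps: np.ndarray, scale: bool = True) -> np.ndarray:
    """Resolve the sign/scale ambiguity of factor rows.

    Each row is flipped so its largest-magnitude entry is positive and, if
    ``scale`` is set, divided by that entry so the peak value is 1.  Factor
    rows from a bilinear decomposition are only defined up to sign and scale;
    pinning both makes overlap metrics comparable across runs.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 1:
        maps = maps[None, :]
        squeeze = True
    else:
        squeeze = False
    peaks = maps[np.arange(maps.shape[0]), np.argmax(np.abs(maps), axis=1)]
    peaks = np.where(peaks == 0, 1.0, peaks)
    fixed = maps * (1.0 / peaks if scale else np.sign(peaks))[:, None]
    return fixed[0] if squeeze else fixed


@dataclass
class SpatialMapSet:
    """``D x M`` matrix of voxel-wise network maps with one label per row."""

    maps: np.ndarray
    labels: list[str]
    mask: BrainMask

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[0] < 1:
            raise ValueError("need at least one map")
        if self.maps.shape[1] != self.mask.n_voxels:
            raise ValueError("map length does not match the mask voxel count")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map is required")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @classmethod
    def from_rows(cls, rows: np.ndarray, mask: BrainMask, prefix: str = "map") -> "SpatialMapSet":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        labels = [f"{prefix}{i:02d}" for i in range(rows.shape[0])]
        return cls(maps=rows, labels=labels, mask=mask)
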