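"""NIfTI input/output and brain-mask bookkeeping.

The decomposition operates on masked data only.  A :class:`BrainMask` fixes a
deterministic bijection between in-mask 3D voxel coordinates and flat column
indices (C-order scan of the grid), so that every matrix column can be traced
back to a voxel.  Multi-echo series are assembled into a single
``time x voxel x echo`` array (:class:`MultiEchoSignal`); the solver consumes
its 2D unfolding where echoes form the slowest-varying column blocks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import nibabel as nib
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .maps import SpatialMapSet

__all__ = [
    "BrainMask",
    "MultiEchoSignal",
    "load_multiecho",
    "flatten_echoes",
    "unflatten_echoes",
    "save_maps",
    "load_maps",
]


@dataclass(frozen=True)
class BrainMask:
    """In-brain voxel selection on a fixed 3D grid.

    Parameters
    ----------
    shape
        Spatial grid dimensions ``(nx, ny, nz)``.
    indices
        Flat (C-order) indices of in-mask voxels, strictly increasing.  Their
        order defines the column ordering of every masked matrix.
    affine
        4x4 voxel-to-world transform carried through to written volumes.
    """

    shape: tuple[int, int, int]
    indices: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("mask must contain at least one voxel")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("mask indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= int(np.prod(self.shape)):
            raise ValueError("mask indices out of grid bounds")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @classmethod
    def from_array(cls, mask: np.ndarray, affine: np.ndarray | None = None) -> "BrainMask":
        """Build from a 3D boolean (or 0/1) array; nonzero voxels are in-mask."""
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        idx = np.flatnonzero(mask > 0.5)
        if idx.size == 0:
            raise ValueError("mask is empty")
        return cls(shape=tuple(mask.shape), indices=idx,
                   affine=np.eye(4) if affine is None else affine)

    @classmethod
    def from_nifti(cls, path: str | os.PathLike) -> "BrainMask":
        img = nib.load(str(path))
        return cls.from_array(np.asarray(img.dataobj), affine=img.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask values of a 3D volume (or stack ending in the grid)."""
        volume = np.asarray(volume)
        if volume.shape[-3:] != self.shape:
            raise ValueError(f"volume grid {volume.shape[-3:]} != mask grid {self.shape}")
        return volume.reshape(volume.shape[:-3] + (-1,))[..., self.indices]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place masked values back on the 3D grid; out-of-mask voxels get ``fill``."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(f"expected {self.n_voxels} values, got {values.shape[-1]}")
        flat = np.full(values.shape[:-1] + (int(np.prod(self.shape)),), fill, dtype=float)
        flat[..., self.indices] = values
        return flat.reshape(values.shape[:-1] + self.shape)


@dataclass
class MultiEchoSignal:
    """Masked multi-echo fMRI data: ``data[t, v, e]`` with echo times in ms."""

    data: np.ndarray
    echo_times: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be T x M x nTE, got shape {self.data.shape}")
        T, M, nTE = self.data.shape
        if T < 2 or M < 2 or nTE < 1:
            raise ValueError(f"need T >= 2, M >= 2, nTE >= 1; got {self.data.shape}")
        if self.echo_times.shape != (nTE,):
            raise ValueError("echo_times length must equal the number of echoes")
        if nTE > 1 and np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing")
        if M != self.mask.n_voxels:
            raise ValueError("voxel dimension does not match the mask")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]


def load_multiecho(
    nifti_paths_per_echo: Sequence[str | os.PathLike],
    mask_path: str | os.PathLike,
    echo_times: Sequence[float],
) -> MultiEchoSignal:
    """Assemble one 4D NIfTI series per echo into a masked multi-echo signal.

    All series must share the spatial grid of the mask and a common number of
    time points; the echo axis follows the order of ``echo_times``.
    """
    if len(nifti_paths_per_echo) != len(echo_times):
        raise ValueError("one NIfTI path per echo time is required")
    mask = BrainMask.from_nifti(mask_path)
    blocks = []
    n_time = None
    for path in nifti_paths_per_echo:
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.ndim != 4:
            raise ValueError(f"{path}: expected a 4D series, got shape {vol.shape}")
        if vol.shape[:3] != mask.shape:
            raise ValueError(f"{path}: grid {vol.shape[:3]} != mask grid {mask.shape}")
        if n_time is None:
            n_time = vol.shape[3]
        elif vol.shape[3] != n_time:
            raise ValueError("echo series disagree on the number of time points")
        # (x, y, z, t) -> (t, voxels)
        blocks.append(mask.flatten(np.moveaxis(vol, -1, 0)))
    data = np.stack(blocks, axis=-1)
    return MultiEchoSignal(data=data, echo_times=np.asarray(echo_times, float), mask=mask)


def flatten_echoes(signal: MultiEchoSignal) -> np.ndarray:
    """Unfold ``T x M x nTE`` into ``T x (M * nTE)``.

    Echoes are the slowest-varying column blocks: column block ``e`` holds echo
    ``e``'s voxels in mask order, i.e. columns are
    ``[v1e1, ..., vMe1, v1e2, ...]``.
    """
    T, M, nTE = signal.data.shape
    return signal.data.transpose(0, 2, 1).reshape(T, nTE * M)


def unflatten_echoes(matrix: np.ndarray, n_voxels: int, n_echoes: int) -> np.ndarray:
    """Inverse of :func:`flatten_echoes`: ``rows x (M * nTE)`` -> ``rows x M x nTE``."""
    matrix = np.asarray(matrix)
    rows = matrix.shape[0]
    if matrix.shape[1] != n_voxels * n_echoes:
        raise ValueError("column count does not factor as n_voxels * n_echoes")
    return matrix.reshape(rows, n_echoes, n_voxels).transpose(0, 2, 1)


def save_maps(maps: "SpatialMapSet", out_dir: str | os.PathLike) -> list[str]:
    """Write one 3D NIfTI per map; out-of-mask voxels are zero.

    Returns the written file paths, in map order.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for label, row in zip(maps.labels, maps.maps):
        vol = maps.mask.unflatten(row)
        img = nib.Nifti1Image(vol.astype(np.float32), maps.mask.affine)
        path = os.path.join(str(out_dir), f"{label}.nii.gz")
        nib.save(img, path)
        paths.append(path)
    return paths


def load_maps(paths: Sequence[str | os.PathLike], mask: BrainMask,
              labels: Sequence[str] | None = None) -> "SpatialMapSet":
    """Read 3D NIfTI maps back into a :class:`~delmar.maps.SpatialMapSet`."""
    from .maps import SpatialMapSet

    rows = []
    for path in paths:
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError(f"{path}: grid {vol.shape} != mask grid {mask.shape}")
        rows.append(mask.flatten(vol))
    if labels is None:
        labels = [os.path.basename(str(p)).split(".")[0] for p in paths]
    return SpatialMapSet(maps=np.array(rows), labels=list(labels), mask=mask)
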