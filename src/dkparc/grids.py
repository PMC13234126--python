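"""Volume data model, NIfTI-1 / bval / bvec I/O, and grid resampling.

Every stage of the parcellation pipeline moves lattices between three kinds
of grids: the native acquisition grid of the diffusion data, a conformed
isotropic working grid (1 mm, 256^3, LIA by default, but configurable so that
small phantoms can run on e.g. 48^3 cubes), and back again.  All volumes carry
a :class:`VolumeGrid` describing shape, voxel spacing and the voxel-to-world
affine; the affine maps 0-based voxel indices to world millimetres at the
voxel centre (NIfTI-1 semantics).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "LabelVolume",
    "DwiSeries",
    "Namespace",
    "B0_MAX",
    "read_volume",
    "write_volume",
    "read_dwi",
    "write_dwi",
    "resample",
    "conform",
    "conformed_grid",
]

#: b-values at or below this (s/mm^2) count as baseline (b ~ 0).
B0_MAX = 50.0

_AXIS_VECTORS = {
    "R": np.array([1.0, 0.0, 0.0]),
    "L": np.array([-1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}


class Namespace(str, Enum):
    """Label namespace tag: which stage of the hierarchy a label volume encodes."""

    COARSE = "coarse"
    FINE = "fine"
    FINAL = "final"
    LUT = "lut"


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice embedded in world (scanner) millimetre space.

    Parameters
    ----------
    shape
        Lattice dimensions, three positive integers.
    affine
        4x4 voxel-to-world transform; voxel indices are 0-based and map to
        the world coordinate of the voxel centre.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def orientation(self) -> str:
        """Three-letter axis code (e.g. ``LIA``) derived from the affine."""
        return "".join(nib.orientations.aff2axcodes(self.affine))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the field-of-view centre."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.voxel_to_world(c)[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-8
        )


@dataclass
class ScalarVolume:
    """A real-valued 3-D lattice on a grid (one scalar map)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"lattice shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite voxels")


@dataclass
class LabelVolume:
    """A non-negative integer 3-D lattice; 0 is reserved for background."""

    grid: VolumeGrid
    labels: np.ndarray
    namespace: Namespace = Namespace.FINAL

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("label lattice has non-integer values")
            labels = labels.astype(np.int32)
        if labels.shape != self.grid.shape:
            raise ValueError(
                f"lattice shape {labels.shape} != grid shape {self.grid.shape}"
            )
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels
        self.namespace = Namespace(self.namespace)

    def ids(self) -> np.ndarray:
        """Sorted distinct non-background ids present."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class DwiSeries:
    """4-D diffusion signal with per-volume b-value and gradient direction.

    Invariants: at least one baseline volume (b <= ``B0_MAX``), at least six
    diffusion-weighted volumes (the tensor has six unknowns), unit-norm
    gradient directions wherever b > 0, and matching volume counts.
    """

    grid: VolumeGrid
    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[:3] != self.grid.shape:
            raise ValueError("signal spatial shape does not match grid")
        n = self.signal.shape[3]
        if self.bvecs.shape == (3, n) and n != 3:
            self.bvecs = self.bvecs.T
        if self.bvals.shape[0] != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"count mismatch: {n} volumes, {self.bvals.shape[0]} b-values, "
                f"{self.bvecs.shape} gradient table"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if not np.any(self.bvals <= B0_MAX):
            raise ValueError("no baseline (b ~ 0) volume present")
        dw = self.bvals > B0_MAX
        if dw.sum() < 6:
            raise ValueError(
                f"insufficient directions: {int(dw.sum())} diffusion-weighted "
                "volumes, need >= 6 for the six tensor unknowns"
            )
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("gradient directions must be unit vectors where b > 0")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.bvals <= B0_MAX


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_volume(
    path: str | os.PathLike,
    as_labels: bool = False,
    namespace: Namespace = Namespace.FINAL,
) -> ScalarVolume | LabelVolume:
    """Read a 3-D NIfTI-1 file as a scalar or label volume.

    The caller decides label-ness (and the namespace tag); integer-typed
    files are commonly labels but nothing in the header says so.
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    grid = VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))
    if as_labels:
        return LabelVolume(grid, data, namespace=namespace)
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64))


def write_volume(volume: ScalarVolume | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, preserving the lattice dtype for labels."""
    if isinstance(volume, LabelVolume):
        data = np.asarray(volume.labels, dtype=np.int32)
    else:
        data = np.asarray(volume.values, dtype=np.float64)
    img = nib.Nifti1Image(data, volume.grid.affine)
    img.header.set_sform(volume.grid.affine, code=1)
    img.header.set_qform(volume.grid.affine, code=1)
    nib.save(img, os.fspath(path))


def _read_table(path: str | os.PathLike) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([float(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"empty gradient table file: {path}")
    return np.array(rows, dtype=float)


def read_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> DwiSeries:
    """Read a 4-D NIfTI plus FSL-dialect ``bval``/``bvec`` text files.

    ``bvec`` may be 3 rows x N columns (FSL convention) or N x 3; the shape is
    auto-detected.  Zero rows on baseline volumes are accepted.
    """
    img = nib.load(os.fspath(image_path))
    signal = np.asarray(img.dataobj, dtype=float)
    if signal.ndim != 4:
        raise ValueError(f"expected 4-D DWI, got shape {signal.shape}")
    bvals = _read_table(bval_path).ravel()
    bvecs = _read_table(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    grid = VolumeGrid(shape=signal.shape[:3], affine=np.asarray(img.affine))
    return DwiSeries(grid, np.clip(signal, 0.0, None), bvals, bvecs)


def write_dwi(dwi: DwiSeries, image_path, bval_path, bvec_path) -> None:
    img = nib.Nifti1Image(np.asarray(dwi.signal, dtype=np.float32), dwi.grid.affine)
    nib.save(img, os.fspath(image_path))
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in dwi.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in dwi.bvecs.T:  # FSL convention: 3 rows
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample(
    volume: ScalarVolume | LabelVolume,
    target: VolumeGrid,
    mode: str = "trilinear",
):
    """Resample a volume onto ``target``, filling out-of-extent voxels with 0.

    Label volumes always use nearest-neighbour interpolation; requesting
    trilinear for labels is an error rather than a silent downgrade.
    """
    is_labels = isinstance(volume, LabelVolume)
    if is_labels:
        if mode == "trilinear":
            raise ValueError("trilinear interpolation is undefined for labels; use nearest")
        mode = "nearest"
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown mode {mode!r}")

    if target == volume.grid:
        if is_labels:
            return LabelVolume(target, volume.labels.copy(), volume.namespace)
        return ScalarVolume(target, volume.values.copy())

    # composite transform: target voxel -> world -> source voxel
    m = np.linalg.inv(volume.grid.affine) @ target.affine
    order = 0 if mode == "nearest" else 1
    if is_labels:
        data = volume.labels
        out = ndimage.affine_transform(
            data, m[:3, :3], offset=m[:3, 3], output_shape=target.shape,
            order=0, mode="constant", cval=0, output=data.dtype,
        )
        return LabelVolume(target, out, volume.namespace)
    out = ndimage.affine_transform(
        volume.values.astype(np.float64), m[:3, :3], offset=m[:3, 3],
        output_shape=target.shape, order=order, mode="constant", cval=0.0,
    )
    return ScalarVolume(target, out)


def _orientation_matrix(code: str) -> np.ndarray:
    code = code.upper()
    if len(code) != 3:
        raise ValueError(f"orientation code must have 3 letters, got {code!r}")
    cols = []
    for letter in code:
        if letter not in _AXIS_VECTORS:
            raise ValueError(f"unknown axis letter {letter!r}")
        cols.append(_AXIS_VECTORS[letter])
    m = np.stack(cols, axis=1)
    if abs(np.linalg.det(m)) < 0.5:
        raise ValueError(f"orientation code {code!r} does not span 3 axes")
    return m


def conformed_grid(
    reference: VolumeGrid,
    size: int = 256,
    spacing: float = 1.0,
    orientation: str = "LIA",
) -> VolumeGrid:
    """Isotropic cubic grid centred on the reference field of view.

    Defaults are the conformed-space constants (1 mm, 256^3, LIA); small
    cubes are used for desk-scale phantoms.
    """
    rot = _orientation_matrix(orientation) * float(spacing)
    center = reference.center_world
    half = (size - 1) / 2.0
    affine = np.eye(4)
    affine[:3, :3] = rot
    affine[:3, 3] = center - rot @ np.array([half, half, half])
    return VolumeGrid(shape=(size, size, size), affine=affine)


def conform(
    volume: ScalarVolume | LabelVolume,
    size: int = 256,
    spacing: float = 1.0,
    orientation: str = "LIA",
    mode: str | None = None,
):
    """Resample onto the conformed grid; labels use nearest automatically."""
    target = conformed_grid(volume.grid, size=size, spacing=spacing, orientation=orientation)
    if mode is None:
        mode = "nearest" if isinstance(volume, LabelVolume) else "trilinear"
    return resample(volume, target, mode=mode)
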