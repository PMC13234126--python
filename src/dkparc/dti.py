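"""Diffusion tensor estimation and the eight derived scalar maps.

The single-tensor model relates the measured signal to a symmetric 3x3
diffusion tensor D through S_i = S0 * exp(-b_i * g_i^T D g_i).  Taking logs
makes the model linear in (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), which is
fitted per voxel by ordinary least squares over all volumes (baselines
included as rows with b = 0 design entries — multiple baselines are thereby
averaged implicitly).

From the sorted eigenvalues E1 >= E2 >= E3 the scalar maps are:

    FA = sqrt( [(E1-E2)^2 + (E2-E3)^2 + (E1-E3)^2] / [2 (E1^2+E2^2+E3^2)] )
    CL = (E1-E2) / (E1+E2+E3)          (linearity)
    CP = 2 (E2-E3) / (E1+E2+E3)        (planarity)
    CS = 3 E3 / (E1+E2+E3)             (sphericity)
    T  = E1 + E2 + E3                  (trace; MD = T/3)

CL + CP + CS = 1 identically wherever the trace is positive.  The map set
{F, T, CL, CP, CS, E1, E2, E3} covers the channel-ablation design space; the
default model input is the four-channel (T, F, CS, E1) selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DwiSeries, LabelVolume, ScalarVolume, VolumeGrid

__all__ = [
    "TensorVolume",
    "ScalarMapSet",
    "MAP_NAMES",
    "DEFAULT_SELECTION",
    "fit_tensor",
    "eigensystem",
    "westin_and_fa",
    "assemble_maps",
]

MAP_NAMES = ("F", "T", "CL", "CP", "CS", "E1", "E2", "E3")

#: channel order of the default four-parameter model input
DEFAULT_SELECTION = ("T", "F", "CS", "E1")

# index pairs of the 6 unique tensor components in (x, y, z) order
_COMP_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor (6 unique components) plus S0."""

    grid: VolumeGrid
    components: np.ndarray  # (..., 6): Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
    s0: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError("components must have shape grid.shape + (6,)")
        if self.s0.shape != self.grid.shape or self.valid_mask.shape != self.grid.shape:
            raise ValueError("s0 / valid_mask shape mismatch")
        if not np.all(np.isfinite(self.components[self.valid_mask])):
            raise ValueError("non-finite tensor components inside valid mask")

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 tensors, shape grid.shape + (3, 3)."""
        d = np.zeros(self.grid.shape + (3, 3))
        for k, (i, j) in enumerate(_COMP_IDX):
            d[..., i, j] = self.components[..., k]
            d[..., j, i] = self.components[..., k]
        return d


@dataclass
class ScalarMapSet:
    """Named, co-registered scalar maps in a fixed channel order."""

    grid: VolumeGrid
    maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.maps.items():
            if name not in MAP_NAMES:
                raise KeyError(f"unknown map name {name!r}")
            if arr.shape != self.grid.shape:
                raise ValueError(f"map {name} shape mismatch")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def stack(self) -> np.ndarray:
        """Channel-first array (C, x, y, z) in insertion order."""
        return np.stack([self.maps[n] for n in self.maps], axis=0)

    def __getitem__(self, name: str) -> ScalarVolume:
        return ScalarVolume(self.grid, self.maps[name])


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of the log-linear system: ln S = X @ (ln S0, Dxx..Dzz)."""
    g = bvecs
    b = bvals[:, None]
    cross = np.stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ],
        axis=1,
    )
    return np.hstack([np.ones((len(bvals), 1)), -b * cross])


def fit_tensor(dwi: DwiSeries, mask: LabelVolume | None = None) -> TensorVolume:
    """Ordinary least-squares tensor fit on log-signal, per voxel.

    Voxels outside ``mask`` or with any non-positive signal are excluded via
    ``valid_mask`` and get zero components.
    """
    if dwi.n_volumes < 7:
        raise ValueError(
            f"need >= 7 volumes (6 directions + baseline), got {dwi.n_volumes}"
        )
    x = _design_matrix(dwi.bvals, dwi.bvecs)
    # pseudo-inverse once; the design is shared by every voxel
    pinv = np.linalg.pinv(x)

    sig = dwi.signal.reshape(-1, dwi.n_volumes)
    valid = np.all(sig > 0, axis=1)
    if mask is not None:
        if mask.grid.shape != dwi.grid.shape:
            raise ValueError("mask grid does not match DWI grid")
        valid &= mask.labels.reshape(-1) > 0

    coef = np.zeros((sig.shape[0], 7))
    if valid.any():
        coef[valid] = np.log(sig[valid]) @ pinv.T

    shape = dwi.grid.shape
    s0 = np.where(valid, np.exp(coef[:, 0]), 0.0).reshape(shape)
    comps = np.where(valid[:, None], coef[:, 1:], 0.0).reshape(shape + (6,))
    return TensorVolume(dwi.grid, comps, s0, valid.reshape(shape))


def eigensystem(tensor: TensorVolume) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume]:
    """Per-voxel eigenvalues of the symmetric tensor, sorted descending.

    Invalid voxels map to 0.  Returns (E1, E2, E3) as scalar volumes.
    """
    mats = tensor.as_matrices()[tensor.valid_mask]
    shape = tensor.grid.shape
    out = np.zeros(shape + (3,))
    if mats.size:
        ev = np.linalg.eigvalsh(mats)  # ascending
        out[tensor.valid_mask] = ev[:, ::-1]
    return tuple(ScalarVolume(tensor.grid, out[..., k]) for k in range(3))


def westin_and_fa(e1: ScalarVolume, e2: ScalarVolume, e3: ScalarVolume) -> dict[str, np.ndarray]:
    """Compute F (FA), T (trace), and the Westin shape measures CL, CP, CS.

    Requires eigenvalues sorted descending.  Voxels with non-positive trace
    or an all-zero eigenvalue vector fall back to zeros in every output.
    """
    a, b, c = e1.values, e2.values, e3.values
    if np.any(a < b - 1e-12) or np.any(b < c - 1e-12):
        raise ValueError("eigenvalues must be sorted descending (E1 >= E2 >= E3)")
    trace = a + b + c
    sq = a * a + b * b + c * c
    ok = (trace > 0) & (sq > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(((a - b) ** 2 + (b - c) ** 2 + (a - c) ** 2) / (2.0 * sq))
        cl = (a - b) / trace
        cp = 2.0 * (b - c) / trace
        cs = 3.0 * c / trace
    zero = np.zeros_like(a)
    return {
        "F": np.where(ok, fa, zero),
        "T": np.where(ok, trace, zero),
        "CL": np.where(ok, cl, zero),
        "CP": np.where(ok, cp, zero),
        "CS": np.where(ok, cs, zero),
    }


def assemble_maps(tensor: TensorVolume, selection=DEFAULT_SELECTION) -> ScalarMapSet:
    """Build the requested maps in the requested channel order.

    The channel order is part of the trained-model contract: models record
    the order they were trained with and refuse mismatched input.
    """
    selection = tuple(selection)
    if not selection:
        raise ValueError("selection must be non-empty")
    unknown = [n for n in selection if n not in MAP_NAMES]
    if unknown:
        raise KeyError(f"unknown map name(s): {unknown}")
    if len(set(selection)) != len(selection):
        raise ValueError(f"duplicate map name in selection: {selection}")

    e1, e2, e3 = eigensystem(tensor)
    derived = westin_and_fa(e1, e2, e3)
    derived.update({"E1": e1.values, "E2": e2.values, "E3": e3.values})
    return ScalarMapSet(tensor.grid, {name: derived[name] for name in selection})
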