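"""Synthetic diffusion phantoms with a full seven-group label hierarchy.

The generator produces, on a small conformed cube, a hierarchically
structured label volume — a ball split by the midsagittal plane, with a
cortical ribbon of angular parcels, a white-matter core, a deep nuclear
cluster per hemisphere, and a midline column — and forward-simulates a
diffusion-weighted series from per-group tensor archetypes:

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with one baseline volume, approximately uniform gradient directions from a
deterministic spherical spiral, and optional Gaussian (or Rician) noise.

The default acquisition emulates a single-shell protocol: one baseline plus
64 directions at b = 1000 s/mm^2.  Default tissue archetypes (eigenvalues in
mm^2/s, S0 = 100):

* cerebral white matter: (1.7, 0.3, 0.3)e-3, principal axis radial
* deep gray nuclei:      (1.0, 0.55, 0.55)e-3 — higher anisotropy than
  cortex, as for thalamus/putamen in vivo, so deep and cortical gray are
  separable in the derived maps
* cortical gray:         (0.9, 0.7, 0.7)e-3
* midline fluid:         (3.0, 3.0, 3.0)e-3, isotropic

Everything is a pure function of the :class:`PhantomSpec` (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import DwiSeries, LabelVolume, Namespace, VolumeGrid, conformed_grid
from .hierarchy import LabelHierarchy, default_hierarchy

__all__ = [
    "TissueArchetype",
    "PhantomSpec",
    "default_archetypes",
    "generate_labels",
    "simulate_dwi",
    "spiral_directions",
]

MIN_LABEL_VOXELS = 8


@dataclass(frozen=True)
class TissueArchetype:
    """Diffusion tensor eigenvalues (descending, mm^2/s) and baseline signal."""

    eigenvalues: tuple[float, float, float]
    s0: float = 100.0
    radial: bool = True  # orient the principal axis radially when anisotropic

    def __post_init__(self) -> None:
        ev = tuple(float(v) for v in self.eigenvalues)
        if any(v <= 0 for v in ev) or not (ev[0] >= ev[1] >= ev[2]):
            raise ValueError("eigenvalues must be positive and sorted descending")
        object.__setattr__(self, "eigenvalues", ev)


def default_archetypes() -> dict[int, TissueArchetype]:
    wm = TissueArchetype((1.7e-3, 0.3e-3, 0.3e-3))
    deep = TissueArchetype((1.0e-3, 0.55e-3, 0.55e-3))
    ctx = TissueArchetype((0.9e-3, 0.7e-3, 0.7e-3))
    fluid = TissueArchetype((3.0e-3, 3.0e-3, 3.0e-3))
    return {1: wm, 2: wm, 3: deep, 4: deep, 5: ctx, 6: ctx, 7: fluid}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom realisation."""

    grid_size: int = 48
    hierarchy: LabelHierarchy = field(default_factory=default_hierarchy)
    tissue_archetypes: dict[int, TissueArchetype] = field(default_factory=default_archetypes)
    bval: float = 1000.0
    n_directions: int = 64
    noise_sigma: float = 1.0
    noise_model: str = "gaussian"  # or "rician"
    skew: float = 0.0  # >0 inflates the white-matter core (imbalance knob)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise ValueError("n_directions must be >= 6 for tensor fitting")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


def _phantom_grid(n: int) -> VolumeGrid:
    ref = VolumeGrid((1, 1, 1), np.eye(4))  # FOV centred at world origin
    return conformed_grid(ref, size=n, spacing=1.0, orientation="LIA")


def spiral_directions(n: int) -> np.ndarray:
    """Deterministic, approximately uniform unit directions (Fibonacci spiral)."""
    i = np.arange(n)
    z = (2.0 * i + 1.0) / n - 1.0
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _sector_bins(angle: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin angles in (-pi, pi] into n_bins equal sectors, 0-based."""
    frac = (angle + np.pi) / (2.0 * np.pi)
    return np.minimum((frac * n_bins).astype(int), n_bins - 1)


def generate_labels(spec: PhantomSpec) -> LabelVolume:
    """Deterministic final-namespace phantom labels for the seven-group hierarchy.

    Geometry: a ball of radius ~0.44*N split by the midsagittal plane; per
    hemisphere an outer cortical ribbon split into angular sectors, a deep
    nuclear ball split into sectors, and a single white-matter core label; a
    central column carrying the midline labels as axial slabs.  Every final
    id is present with at least ``MIN_LABEL_VOXELS`` voxels.
    """
    n = int(spec.grid_size)
    if n < 24:
        raise ValueError("grid_size must be >= 24 to host all labels")
    h = spec.hierarchy
    groups = {g.coarse_id: g for g in h.groups}
    grid = _phantom_grid(n)

    c = (n - 1) / 2.0
    idx = np.indices((n, n, n), dtype=float)
    xb, yb, zb = idx[0] - c, idx[1] - c, idx[2] - c
    rho = np.sqrt(xb * xb + yb * yb + zb * zb)

    r_ball = 0.44 * n
    # skew inflates the white-matter core at the expense of the ribbon
    r_ctx = (0.78 + 0.12 * min(max(spec.skew, 0.0), 1.0)) * r_ball
    r_deep = 0.30 * r_ball
    deep_off = 0.45 * r_ball
    w_col = max(1.5, n / 32.0)

    ball = rho <= r_ball
    column = ball & (np.abs(xb) <= w_col)
    left = ball & (xb < -w_col)
    right = ball & (xb > w_col)

    labels = np.zeros((n, n, n), dtype=np.int32)
    angle = np.arctan2(zb, yb)  # longitude about the left-right axis

    # midline column: axial slabs, one per midline final id
    mid_ids = sorted(groups[7].final_ids)
    edges = np.linspace(-r_ball, r_ball, len(mid_ids) + 1)
    slab = np.clip(np.digitize(zb, edges) - 1, 0, len(mid_ids) - 1)
    for k, fid in enumerate(mid_ids):
        labels[column & (slab == k)] = fid

    for side_mask, sign, wm_gid, deep_gid, ctx_gid in (
        (left, -1.0, 1, 3, 5),
        (right, 1.0, 2, 4, 6),
    ):
        ribbon = side_mask & (rho > r_ctx)
        core = side_mask & (rho <= r_ctx)
        xd = xb - sign * deep_off
        deep = core & (np.sqrt(xd * xd + yb * yb + zb * zb) <= r_deep)

        ctx_ids = sorted(groups[ctx_gid].final_ids)
        sec = _sector_bins(angle, len(ctx_ids))
        for k, fid in enumerate(ctx_ids):
            labels[ribbon & (sec == k)] = fid

        deep_ids = sorted(groups[deep_gid].final_ids)
        sec = _sector_bins(angle, len(deep_ids))
        for k, fid in enumerate(deep_ids):
            labels[deep & (sec == k)] = fid

        (wm_id,) = groups[wm_gid].final_ids
        labels[core & ~deep] = wm_id

    present, counts = np.unique(labels[labels > 0], return_counts=True)
    count_of = dict(zip(present.tolist(), counts.tolist()))
    missing = [f for f in sorted(h.final_ids) if count_of.get(f, 0) < MIN_LABEL_VOXELS]
    if missing:
        raise ValueError(
            f"grid_size {n} too small: labels {missing} have fewer than "
            f"{MIN_LABEL_VOXELS} voxels"
        )
    return LabelVolume(grid, labels, namespace=Namespace.FINAL)


def _tensor_field(labels: LabelVolume, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel tensor components (...,6) and S0 from group archetypes."""
    h = spec.hierarchy
    f2c = h.final_to_coarse()
    lab = labels.labels
    present = np.unique(lab[lab > 0])
    for fid in present:
        gid = f2c.get(int(fid))
        if gid is None or gid not in spec.tissue_archetypes:
            raise ValueError(f"no tissue archetype for label {int(fid)} (group {gid})")

    n = lab.shape[0]
    c = (n - 1) / 2.0
    idx = np.indices(lab.shape, dtype=float)
    radial = np.stack([idx[0] - c, idx[1] - c, idx[2] - c], axis=-1)
    norm = np.linalg.norm(radial, axis=-1, keepdims=True)
    u = np.where(norm > 1e-9, radial / np.maximum(norm, 1e-9), [1.0, 0.0, 0.0])

    comps = np.zeros(lab.shape + (6,))
    s0 = np.zeros(lab.shape)
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for fid in present:
        gid = f2c[int(fid)]
        arch = spec.tissue_archetypes[gid]
        l1, l2, l3 = arch.eigenvalues
        vox = lab == fid
        s0[vox] = arch.s0
        if l1 == l2 == l3 or not arch.radial:
            d = np.diag([l1, l2, l3])
            for k, (i, j) in enumerate(pairs):
                comps[vox, k] = d[i, j]
        else:
            # axially symmetric about the radial direction when l2 == l3;
            # a general triple uses an arbitrary transverse frame
            uv = u[vox]
            helper = np.where(
                np.abs(uv[:, 0:1]) < 0.9, [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]
            )
            v2 = np.cross(uv, helper)
            v2 /= np.linalg.norm(v2, axis=1, keepdims=True)
            v3 = np.cross(uv, v2)
            d = (
                l1 * uv[:, :, None] * uv[:, None, :]
                + l2 * v2[:, :, None] * v2[:, None, :]
                + l3 * v3[:, :, None] * v3[:, None, :]
            )
            for k, (i, j) in enumerate(pairs):
                comps[vox, k] = d[:, i, j]
    return comps, s0


def simulate_dwi(labels: LabelVolume, spec: PhantomSpec) -> DwiSeries:
    """Forward-simulate the diffusion series from the label volume."""
    comps, s0 = _tensor_field(labels, spec)

    dirs = spiral_directions(spec.n_directions)
    bvals = np.concatenate([[0.0], np.full(spec.n_directions, float(spec.bval))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])

    g = bvecs
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
    flat = comps.reshape(-1, 6)
    atten = flat @ cross.T  # (V, n_volumes): g^T D g per volume
    signal = s0.reshape(-1, 1) * np.exp(-bvals[None, :] * atten)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
        else:  # rician: magnitude of a complex signal with Gaussian noise
            n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    signal = np.clip(signal, 0.0, None)

    shape = labels.grid.shape + (len(bvals),)
    return DwiSeries(labels.grid, signal.reshape(shape), bvals, bvecs)
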