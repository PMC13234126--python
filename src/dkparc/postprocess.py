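"""Post-processing: merge the two stages into one cleaned 101-label volume.

The fixed pipeline order is: restrict fine outputs to their coarse masks →
constrained majority fill (the "dilation" step) → per-label largest
26-connected component → merge with the terminal coarse labels → nearest-
neighbour resampling to the native grid → optional lookup-table remap.

"Dilation" is realised as a constrained majority fill rather than an
unconditional morphological dilation: dilating overlapping parcels
independently is ill-defined for a multi-label volume, while filling
background voxels inside the coarse mask from their labelled 26-neighbours
achieves the intended closing of small gaps without ever moving a parcel
boundary outward across another label or outside its coarse region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import LabelVolume, Namespace, VolumeGrid, resample
from .hierarchy import LabelHierarchy

__all__ = [
    "restrict_to_coarse",
    "dilate_fill",
    "keep_largest_component",
    "merge_final",
    "to_native",
    "apply_lookup",
    "postprocess_pipeline",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def restrict_to_coarse(
    fine: dict[int, LabelVolume],
    coarse: LabelVolume,
    h: LabelHierarchy,
) -> dict[int, LabelVolume]:
    """Zero out fine voxels falling outside their group's coarse mask."""
    if coarse.namespace is not Namespace.COARSE:
        raise ValueError("coarse volume must carry the coarse namespace")
    out: dict[int, LabelVolume] = {}
    for gid, vol in fine.items():
        h.group(gid)  # raises on unknown group
        labels = np.where(coarse.labels == gid, vol.labels, 0)
        out[gid] = LabelVolume(vol.grid, labels, namespace=Namespace.FINE)
    return out


def _majority_fill_once(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    """One sweep: background voxels in ``region`` adopt the majority label
    among 26-neighbours; ties break toward the lower label id."""
    fillable = region & (labels == 0)
    if not fillable.any():
        return labels
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return labels
    best_count = np.zeros(labels.shape, dtype=np.int32)
    best_label = np.zeros(labels.shape, dtype=labels.dtype)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    for lab in ids:  # ascending: strict > keeps the lowest id on ties
        cnt = ndimage.convolve(
            (labels == lab).astype(np.int32), kernel.astype(np.int32), mode="constant"
        )
        better = cnt > best_count
        best_count = np.where(better, cnt, best_count)
        best_label = np.where(better, lab, best_label)
    adopt = fillable & (best_count > 0)
    out = labels.copy()
    out[adopt] = best_label[adopt]
    return out


def dilate_fill(
    fine: dict[int, LabelVolume],
    coarse: LabelVolume,
    h: LabelHierarchy,
    max_iters: int = 3,
) -> dict[int, LabelVolume]:
    """Iteratively close gaps inside each coarse mask (majority 26-neighbour
    fill); never overwrites a labelled voxel and never crosses the mask."""
    out: dict[int, LabelVolume] = {}
    for gid, vol in fine.items():
        region = coarse.labels == gid
        labels = vol.labels
        for _ in range(max_iters):
            new = _majority_fill_once(labels, region)
            if np.array_equal(new, labels):
                labels = new
                break
            labels = new
        out[gid] = LabelVolume(vol.grid, labels, namespace=Namespace.FINE)
    return out


def keep_largest_component(volume: LabelVolume) -> LabelVolume:
    """Per non-background label, keep only the largest 26-connected component.

    No minimum-size threshold: every smaller component is removed, however
    large.  Size ties keep the component whose minimum linear voxel index in
    x-fastest scan order is smallest (deterministic).
    """
    labels = volume.labels
    out = labels.copy()
    shape = labels.shape
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        comp, n = ndimage.label(mask, structure=_STRUCT26)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones(shape, dtype=np.int64), comp, range(1, n + 1))
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if len(best) > 1:
            # x-fastest linear index: i + X*(j + Y*k)
            coords = np.argwhere(np.isin(comp, best))
            lin = coords[:, 0] + shape[0] * (coords[:, 1] + shape[1] * coords[:, 2])
            winner = comp[tuple(coords[np.argmin(lin)])]
        else:
            winner = int(best[0])
        out[mask & (comp != winner)] = 0
    return LabelVolume(volume.grid, out, namespace=volume.namespace)


def merge_final(
    coarse: LabelVolume,
    fine: dict[int, LabelVolume],
    h: LabelHierarchy,
) -> LabelVolume:
    """Combine both stages into the final label namespace.

    Terminal groups contribute their single final id wherever the coarse map
    assigns them; non-terminal voxels take the (post-processed) fine label.
    A voxel claimed by both keeps the fine label; unlabelled voxels inside a
    non-terminal mask stay background.
    """
    out = np.zeros(coarse.grid.shape, dtype=np.int32)
    for g in h.groups:
        if g.terminal:
            (fid,) = g.final_ids
            out[coarse.labels == g.coarse_id] = fid
    for gid, vol in fine.items():
        fg = vol.labels > 0
        out[fg] = vol.labels[fg]
    return LabelVolume(coarse.grid, out, namespace=Namespace.FINAL)


def to_native(labels: LabelVolume, native: VolumeGrid) -> LabelVolume:
    """Nearest-neighbour resampling back to the native acquisition grid."""
    return resample(labels, native, mode="nearest")


def apply_lookup(labels: LabelVolume, lut: dict[int, int] | None) -> LabelVolume:
    """Bijective remap of final ids to external (FreeSurfer-style) LUT ids."""
    if lut is None:
        raise ValueError("no lookup table defined")
    present = [int(i) for i in np.unique(labels.labels) if i > 0]
    missing = [i for i in present if i not in lut]
    if missing:
        raise KeyError(f"no lookup entry for label(s) {missing}")
    if len(set(lut.values())) != len(lut):
        raise ValueError("lookup table is not injective")
    max_id = max(present, default=0)
    table = np.zeros(max_id + 1, dtype=np.int32)
    for src in present:
        table[src] = lut[src]
    return LabelVolume(labels.grid, table[labels.labels], namespace=Namespace.LUT)


def postprocess_pipeline(
    coarse: LabelVolume,
    fine: dict[int, LabelVolume],
    h: LabelHierarchy,
    native: VolumeGrid | None = None,
    lut: dict[int, int] | None = None,
    max_fill_iters: int = 3,
) -> LabelVolume:
    """Full chain: restrict → fill → largest component → merge (→ native → lut)."""
    fine = restrict_to_coarse(fine, coarse, h)
    fine = dilate_fill(fine, coarse, h, max_iters=max_fill_iters)
    fine = {gid: keep_largest_component(v) for gid, v in fine.items()}
    merged = merge_final(coarse, fine, h)
    if native is not None:
        merged = to_native(merged, native)
    if lut is not None:
        merged = apply_lookup(merged, lut)
    return merged
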