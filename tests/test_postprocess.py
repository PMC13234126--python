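"""Post-processing steps against brute-force oracles on small fixtures."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from dkparc import (
    LabelVolume,
    Namespace,
    VolumeGrid,
    apply_lookup,
    default_hierarchy,
    dilate_fill,
    keep_largest_component,
    merge_final,
    postprocess_pipeline,
    restrict_to_coarse,
    to_coarse,
    to_native,
)


def _grid(shape, affine=None):
    return VolumeGrid(shape, np.eye(4) if affine is None else affine)


def _lab(arr, namespace=Namespace.FINE):
    arr = np.asarray(arr, dtype=np.int32)
    return LabelVolume(_grid(arr.shape), arr, namespace=namespace)


# -- brute-force oracles -----------------------------------------------------


def neighbors26(idx, shape):
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        q = tuple(i + o for i, o in zip(idx, d))
        if all(0 <= v < s for v, s in zip(q, shape)):
            yield q


def oracle_majority_fill(labels, region):
    """Literal per-voxel 26-neighbour majority fill, lowest id on ties."""
    out = labels.copy()
    for idx in np.ndindex(labels.shape):
        if not region[idx] or labels[idx] != 0:
            continue
        counts = {}
        for q in neighbors26(idx, labels.shape):
            lab = labels[q]
            if lab > 0:
                counts[lab] = counts.get(lab, 0) + 1
        if counts:
            best = max(counts.values())
            out[idx] = min(l for l, c in counts.items() if c == best)
    return out


def oracle_components(mask):
    """Flood-fill 26-connected components; returns list of voxel-index sets."""
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for idx in np.ndindex(mask.shape):
        if not mask[idx] or seen[idx]:
            continue
        comp, queue = set(), deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for q in neighbors26(cur, mask.shape):
                if mask[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
        comps.append(comp)
    return comps


def oracle_keep_largest(labels):
    shape = labels.shape
    out = labels.copy()

    def lin(idx):  # x-fastest linear index
        return idx[0] + shape[0] * (idx[1] + shape[1] * idx[2])

    for lab in np.unique(labels[labels > 0]):
        comps = oracle_components(labels == lab)
        if len(comps) <= 1:
            continue
        winner = min(comps, key=lambda c: (-len(c), min(lin(i) for i in c)))
        for comp in comps:
            if comp is not winner:
                for idx in comp:
                    out[idx] = 0
    return out


# -- restrict ----------------------------------------------------------------


def test_restrict_zeroes_voxels_outside_coarse_mask():
    fine = np.zeros((5, 5, 5), dtype=np.int32)
    fine[1:4, 1:4, 1:4] = 7
    coarse = np.zeros((5, 5, 5), dtype=np.int32)
    coarse[2:5, 2:5, 2:5] = 3
    out = restrict_to_coarse(
        {3: _lab(fine)}, _lab(coarse, Namespace.COARSE), default_hierarchy()
    )[3]
    expect = np.where(coarse == 3, fine, 0)
    np.testing.assert_array_equal(out.labels, expect)
    assert out.namespace is Namespace.FINE


def test_restrict_validates_namespace_and_group():
    fine = _lab(np.zeros((3, 3, 3)))
    wrong_ns = _lab(np.zeros((3, 3, 3)), Namespace.FINAL)
    with pytest.raises(ValueError):
        restrict_to_coarse({3: fine}, wrong_ns, default_hierarchy())
    coarse = _lab(np.zeros((3, 3, 3)), Namespace.COARSE)
    with pytest.raises(KeyError):
        restrict_to_coarse({42: fine}, coarse, default_hierarchy())


# -- dilate / majority fill --------------------------------------------------


def test_dilate_fill_closes_single_voxel_gap_lowest_id_tie():
    labels = np.zeros((3, 3, 3), dtype=np.int32)
    labels[0, 1, 1] = 9
    labels[2, 1, 1] = 5
    region = np.zeros((3, 3, 3), dtype=bool)
    region[:, 1, 1] = True
    coarse = _lab(region.astype(np.int32) * 3, Namespace.COARSE)
    out = dilate_fill({3: _lab(labels)}, coarse, default_hierarchy())[3]
    # both candidates touch the gap with one 26-neighbour each: tie -> 5
    assert out.labels[1, 1, 1] == 5
    assert out.labels[0, 1, 1] == 9 and out.labels[2, 1, 1] == 5  # untouched


def test_dilate_fill_never_crosses_mask_or_overwrites():
    labels = np.zeros((5, 5, 5), dtype=np.int32)
    labels[2, 2, 2] = 4
    region = np.zeros((5, 5, 5), dtype=bool)
    region[1:4, 1:4, 1:4] = True
    coarse = _lab(region.astype(np.int32) * 5, Namespace.COARSE)
    out = dilate_fill({5: _lab(labels)}, coarse, default_hierarchy(), max_iters=10)[5]
    assert (out.labels[~region] == 0).all()
    assert out.labels[2, 2, 2] == 4
    assert (out.labels[region] == 4).all()  # fill converges to the whole mask


def test_dilate_fill_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for trial in range(5):
        labels = rng.integers(0, 4, (6, 6, 6)).astype(np.int32)
        labels[rng.random((6, 6, 6)) < 0.5] = 0
        region = rng.random((6, 6, 6)) < 0.7
        labels[~region] = 0
        coarse = _lab(region.astype(np.int32) * 3, Namespace.COARSE)
        got = dilate_fill({3: _lab(labels)}, coarse, default_hierarchy(),
                          max_iters=1)[3]
        np.testing.assert_array_equal(
            got.labels, oracle_majority_fill(labels, region),
            err_msg=f"trial {trial}",
        )


# -- largest component -------------------------------------------------------


def test_keep_largest_component_basic():
    labels = np.zeros((9, 3, 3), dtype=np.int32)
    labels[0:5, 0, 0] = 2  # size-5 component
    labels[7:9, 0, 0] = 2  # size-2 component, removed
    out = keep_largest_component(_lab(labels))
    assert (out.labels[0:5, 0, 0] == 2).all()
    assert (out.labels[7:9, 0, 0] == 0).all()


def test_keep_largest_component_diagonal_is_connected():
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    for i in range(4):
        labels[i, i, i] = 1  # corner-adjacent chain: one 26-component
    labels[0, 3, 0] = 1  # isolated voxel, removed
    out = keep_largest_component(_lab(labels))
    assert out.labels[0, 3, 0] == 0
    assert sum(out.labels[i, i, i] == 1 for i in range(4)) == 4


def test_keep_largest_component_tie_break_scan_order():
    labels = np.zeros((7, 3, 3), dtype=np.int32)
    labels[0:2, 0, 0] = 1  # first in x-fastest scan order
    labels[5:7, 0, 0] = 1  # equally sized
    out = keep_largest_component(_lab(labels))
    assert (out.labels[0:2, 0, 0] == 1).all()
    assert (out.labels[5:7, 0, 0] == 0).all()


def test_keep_largest_component_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    for trial in range(5):
        labels = rng.integers(0, 3, (7, 7, 7)).astype(np.int32)
        labels[rng.random((7, 7, 7)) < 0.6] = 0
        got = keep_largest_component(_lab(labels))
        np.testing.assert_array_equal(
            got.labels, oracle_keep_largest(labels), err_msg=f"trial {trial}"
        )


# -- merge, native, lookup ---------------------------------------------------


def test_merge_final_terminal_plus_fine_priority():
    h = default_hierarchy()
    coarse = np.zeros((4, 4, 4), dtype=np.int32)
    coarse[0] = 1  # terminal left WM -> final id 1
    coarse[1] = 2  # terminal right WM -> final id 2
    coarse[2] = 3  # non-terminal
    fine3 = np.zeros((4, 4, 4), dtype=np.int32)
    fine3[2, :, :2] = 5  # a deep-group final id
    fine3[0, 0, 0] = 6  # overlaps terminal claim: fine wins
    out = merge_final(_lab(coarse, Namespace.COARSE), {3: _lab(fine3)}, h)
    assert out.namespace is Namespace.FINAL
    assert (out.labels[1] == 2).all()
    assert out.labels[0, 0, 0] == 6
    assert (out.labels[0].ravel()[1:] == 1).all()
    assert (out.labels[2, :, :2] == 5).all()
    assert (out.labels[2, :, 2:] == 0).all()  # unlabelled fine voxels stay 0
    assert (out.labels[3] == 0).all()


def test_to_native_round_trip_on_identical_grid(phantom_labels):
    out = to_native(phantom_labels, phantom_labels.grid)
    np.testing.assert_array_equal(out.labels, phantom_labels.labels)


def test_to_native_half_resolution_preserves_dominant_labels(phantom_labels):
    half_aff = phantom_labels.grid.affine.copy()
    half_aff[:3, :3] *= 2.0
    native = VolumeGrid((16, 16, 16), half_aff)
    out = to_native(phantom_labels, native)
    assert out.grid == native
    # coarse structure survives: WM cores still dominate the down-sampled volume
    assert np.isin(out.labels, [1, 2]).sum() > 0


def test_apply_lookup_remaps_and_validates():
    labels = _lab(np.array([[[0, 1], [2, 2]], [[0, 0], [1, 2]]]), Namespace.FINAL)
    lut = {1: 1001, 2: 2041}
    out = apply_lookup(labels, lut)
    assert out.namespace is Namespace.LUT
    assert set(np.unique(out.labels)) == {0, 1001, 2041}
    # voxel counts preserved under the remap
    assert (out.labels == 1001).sum() == (labels.labels == 1).sum()
    with pytest.raises(KeyError):
        apply_lookup(labels, {1: 1001})
    with pytest.raises(ValueError):
        apply_lookup(labels, {1: 7, 2: 7})
    with pytest.raises(ValueError):
        apply_lookup(labels, None)


# -- full chain invariants ---------------------------------------------------


def test_pipeline_invariants_on_perturbed_phantom(phantom_labels, phantom_spec):
    """Hierarchical containment + single-component invariants of the chain."""
    h = phantom_spec.hierarchy
    coarse = to_coarse(phantom_labels, h)
    rng = np.random.default_rng(2)
    fine = {}
    for g in h.nonterminal_groups():
        lab = np.where(
            np.isin(phantom_labels.labels, list(g.final_ids)),
            phantom_labels.labels, 0,
        ).astype(np.int32)
        # punch holes and flip a few voxels to exercise fill + component steps
        holes = rng.random(lab.shape) < 0.05
        lab[holes] = 0
        fine[g.coarse_id] = LabelVolume(phantom_labels.grid, lab, Namespace.FINE)

    out = postprocess_pipeline(coarse, fine, h)
    assert out.namespace is Namespace.FINAL
    f2c = h.final_to_coarse()
    # containment: every final voxel sits inside its own coarse group mask
    for fid in np.unique(out.labels[out.labels > 0]):
        vox = out.labels == fid
        assert (coarse.labels[vox] == f2c[int(fid)]).all(), fid
    # single 26-component per surviving label
    from scipy import ndimage
    for fid in np.unique(out.labels[out.labels > 0]):
        _, n = ndimage.label(out.labels == fid, structure=np.ones((3, 3, 3)))
        assert n == 1, fid


def test_pipeline_on_clean_input_reduces_to_component_filter(phantom_labels, phantom_spec):
    """Perfect stage outputs leave nothing to restrict or fill, so the chain
    collapses to the per-label largest-component rule (terminal white-matter
    labels pass through from the coarse stage unfiltered)."""
    h = phantom_spec.hierarchy
    coarse = to_coarse(phantom_labels, h)
    fine = {
        g.coarse_id: LabelVolume(
            phantom_labels.grid,
            np.where(np.isin(phantom_labels.labels, list(g.final_ids)),
                     phantom_labels.labels, 0).astype(np.int32),
            Namespace.FINE,
        )
        for g in h.nonterminal_groups()
    }
    out = postprocess_pipeline(coarse, fine, h)

    expect = keep_largest_component(phantom_labels).labels.copy()
    for g in h.groups:
        if g.terminal:
            (fid,) = g.final_ids
            expect[phantom_labels.labels == fid] = fid
    np.testing.assert_array_equal(out.labels, expect)
    # the filter is mild on this geometry: >= 99% of voxels are untouched
    same = (out.labels == phantom_labels.labels).mean()
    assert same >= 0.99
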