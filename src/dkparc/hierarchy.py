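"""The DK label hierarchy: coarse groups, imbalance statistics, class weights.

The 101 final labels of the parcellation are organised into seven coarse
groups: left/right cerebral white matter (terminal, one final label each),
left/right deep/periventricular non-cortical structures (13 labels each),
left/right cortical parcels (34 each), and midline/central structures (5) —
1 + 1 + 13 + 13 + 34 + 34 + 5 = 101.  The first-stage model predicts the
seven groups; five fine models refine the non-terminal ones.

The default configuration uses a synthetic final-id namespace 1..101 with
those group sizes.  A user-supplied config (YAML/JSON) can carry FreeSurfer
ids instead, plus an optional lookup table mapping final ids to external
(FreeSurfer colour-table) ids.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grids import LabelVolume, Namespace, ScalarVolume

__all__ = [
    "HierarchyGroup",
    "LabelHierarchy",
    "LabelStats",
    "DEFAULT_GROUP_SIZES",
    "default_hierarchy",
    "load_hierarchy",
    "save_hierarchy",
    "to_coarse",
    "imbalance_ratio",
    "inverse_frequency_weights",
    "group_channel",
]

DEFAULT_GROUP_SIZES = (1, 1, 13, 13, 34, 34, 5)

_DEFAULT_NAMES = (
    "lh-cerebral-white-matter",
    "rh-cerebral-white-matter",
    "lh-deep",
    "rh-deep",
    "lh-cortical",
    "rh-cortical",
    "midline",
)


@dataclass(frozen=True)
class HierarchyGroup:
    coarse_id: int
    name: str
    final_ids: frozenset[int]
    terminal: bool = False

    def __post_init__(self) -> None:
        if self.coarse_id < 1:
            raise ValueError("coarse_id must be >= 1")
        if not self.final_ids:
            raise ValueError(f"group {self.name!r} has no final ids")
        if any(i <= 0 for i in self.final_ids):
            raise ValueError("final ids must be positive (0 is background)")
        if self.terminal and len(self.final_ids) != 1:
            raise ValueError(
                f"terminal group {self.name!r} must contain exactly 1 final id"
            )


@dataclass(frozen=True)
class LabelHierarchy:
    """Ordered coarse groups, each owning a disjoint set of final labels."""

    groups: tuple[HierarchyGroup, ...]
    lut: dict[int, int] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            overlap = seen & g.final_ids
            if overlap:
                raise ValueError(
                    f"final ids {sorted(overlap)} appear in more than one group"
                )
            seen |= g.final_ids
        cids = [g.coarse_id for g in self.groups]
        if len(set(cids)) != len(cids):
            raise ValueError("duplicate coarse ids")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def final_ids(self) -> frozenset[int]:
        out: set[int] = set()
        for g in self.groups:
            out |= g.final_ids
        return frozenset(out)

    @property
    def n_final(self) -> int:
        return len(self.final_ids)

    def group(self, coarse_id: int) -> HierarchyGroup:
        for g in self.groups:
            if g.coarse_id == coarse_id:
                return g
        raise KeyError(f"no group with coarse id {coarse_id}")

    def nonterminal_groups(self) -> tuple[HierarchyGroup, ...]:
        return tuple(g for g in self.groups if not g.terminal)

    def final_to_coarse(self) -> dict[int, int]:
        return {f: g.coarse_id for g in self.groups for f in sorted(g.final_ids)}

    def validate_default_shape(self) -> None:
        """Check the printed group-size pattern (1,1,13,13,34,34,5)."""
        sizes = tuple(len(g.final_ids) for g in self.groups)
        if sizes != DEFAULT_GROUP_SIZES:
            raise ValueError(
                f"group sizes {sizes} do not match the default {DEFAULT_GROUP_SIZES}"
            )


def default_hierarchy() -> LabelHierarchy:
    """Synthetic-namespace hierarchy: final ids 1..101 in group order."""
    groups = []
    next_id = 1
    for cid, (name, size) in enumerate(zip(_DEFAULT_NAMES, DEFAULT_GROUP_SIZES), start=1):
        ids = frozenset(range(next_id, next_id + size))
        next_id += size
        groups.append(
            HierarchyGroup(coarse_id=cid, name=name, final_ids=ids, terminal=(size == 1))
        )
    return LabelHierarchy(tuple(groups))


def load_hierarchy(path: str | os.PathLike, strict_default: bool = False) -> LabelHierarchy:
    """Load a hierarchy config (YAML or JSON).

    Expected structure::

        groups:
          - {coarse_id: 1, name: ..., final_ids: [...], terminal: true}
        lut: {1: 2, 2: 41, ...}      # optional

    With ``strict_default`` the group sizes must match (1,1,13,13,34,34,5);
    otherwise a mismatch only warns.
    """
    text = open(os.fspath(path)).read()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError:
        cfg = json.loads(text)
    if not isinstance(cfg, dict) or "groups" not in cfg:
        raise ValueError("hierarchy config must contain a 'groups' list")
    groups = tuple(
        HierarchyGroup(
            coarse_id=int(g["coarse_id"]),
            name=str(g.get("name", f"group-{g['coarse_id']}")),
            final_ids=frozenset(int(i) for i in g["final_ids"]),
            terminal=bool(g.get("terminal", False)),
        )
        for g in cfg["groups"]
    )
    lut = None
    if cfg.get("lut"):
        lut = {int(k): int(v) for k, v in cfg["lut"].items()}
    h = LabelHierarchy(groups, lut=lut)
    sizes = tuple(len(g.final_ids) for g in h.groups)
    if sizes != DEFAULT_GROUP_SIZES:
        if strict_default:
            raise ValueError(
                f"group sizes {sizes} do not match the default {DEFAULT_GROUP_SIZES}"
            )
        warnings.warn(
            f"hierarchy group sizes {sizes} differ from the default "
            f"{DEFAULT_GROUP_SIZES}", stacklevel=2,
        )
    return h


def save_hierarchy(h: LabelHierarchy, path: str | os.PathLike) -> None:
    cfg = {
        "groups": [
            {
                "coarse_id": g.coarse_id,
                "name": g.name,
                "final_ids": sorted(g.final_ids),
                "terminal": g.terminal,
            }
            for g in h.groups
        ]
    }
    if h.lut:
        cfg["lut"] = dict(sorted(h.lut.items()))
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class LabelStats:
    """Per-label voxel counts aggregated over one or more label volumes."""

    counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_volumes(cls, volumes) -> "LabelStats":
        counts: dict[int, int] = {}
        for vol in volumes:
            labels, n = np.unique(vol.labels, return_counts=True)
            for lab, c in zip(labels.tolist(), n.tolist()):
                if lab > 0:
                    counts[lab] = counts.get(lab, 0) + c
        return cls(counts)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("label\tcount\n")
            for lab in sorted(self.counts):
                fh.write(f"{lab}\t{self.counts[lab]}\n")


def imbalance_ratio(stats: LabelStats) -> float:
    """Maximum-to-median voxel-count ratio over non-background labels.

    The median of an even-length count list is the mean of the two central
    values.  A single label (max = median) gives 1.0.
    """
    counts = np.array(
        [c for lab, c in stats.counts.items() if lab > 0 and c > 0], dtype=float
    )
    if counts.size == 0:
        raise ValueError("no non-background labels with positive counts")
    return float(counts.max() / np.median(counts))


def inverse_frequency_weights(stats: LabelStats, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/count, normalised to mean 1.

    Class ids run 0..n_classes-1 in model space.  Classes absent from the
    training counts receive the maximum weight observed among present
    classes (they are the rarest).
    """
    counts = np.zeros(n_classes)
    for lab, c in stats.counts.items():
        if 0 <= lab < n_classes:
            counts[lab] = c
    present = counts > 0
    if not present.any():
        raise ValueError("no class has a positive count")
    w = np.zeros(n_classes)
    w[present] = 1.0 / counts[present]
    w[~present] = w[present].max()
    return w / w.mean()


def group_channel(coarse: LabelVolume, n_groups: int = 7) -> ScalarVolume:
    """Coarse mask as a [0, 1] input channel: value = coarse_id / n_groups.

    One scalar channel, linear in the coarse id, background mapping to 0 —
    this keeps label magnitudes from dominating the input scale while the
    mapping stays injective and order-preserving on coarse ids.
    """
    if coarse.namespace is not Namespace.COARSE:
        raise ValueError("group_channel expects a coarse-namespace volume")
    if coarse.labels.max(initial=0) > n_groups:
        raise ValueError(f"coarse ids exceed n_groups={n_groups}")
    return ScalarVolume(coarse.grid, coarse.labels.astype(float) / float(n_groups))


def to_coarse(final: LabelVolume, h: LabelHierarchy) -> LabelVolume:
    """Collapse a final-namespace label volume onto its coarse groups."""
    mapping = h.final_to_coarse()
    present = np.unique(final.labels)
    unknown = [int(p) for p in present if p > 0 and int(p) not in mapping]
    if unknown:
        raise ValueError(f"labels not present in any hierarchy group: {unknown}")
    max_id = int(present.max(initial=0))
    table = np.zeros(max_id + 1, dtype=np.int32)
    for f, c in mapping.items():
        if f <= max_id:
            table[f] = c
    return LabelVolume(final.grid, table[final.labels], namespace=Namespace.COARSE)
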