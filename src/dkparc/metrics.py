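"""Evaluation: DSC, HD95, within-region RSD, and softmax confidence maps.

DSC and HD95 are the supervised overlap/boundary metrics; the relative
standard deviation RSD = std/mean of a diffusion-derived map inside a parcel
is the label-free homogeneity criterion (lower = more homogeneous), with MD
defined as Trace/3 for RSD reporting.  Confidence (max class score),
uncertainty (1 - confidence) and margin (top minus second score) summarise
the voxel-wise softmax output.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import LabelVolume, ScalarVolume

__all__ = [
    "MetricRecord",
    "dsc",
    "hd95",
    "rsd",
    "confidence_maps",
    "evaluate_labels",
    "report",
    "md_from_trace",
]


def md_from_trace(trace: ScalarVolume) -> ScalarVolume:
    """Mean diffusivity map: MD = Trace / 3."""
    return ScalarVolume(trace.grid, trace.values / 3.0)


def dsc(pred: LabelVolume, ref: LabelVolume, label: int) -> float:
    """Dice similarity coefficient 2|P∩R| / (|P|+|R|) for one label.

    Both masks empty → 1.0 (perfect vacuous agreement); exactly one empty → 0.
    """
    if pred.grid.shape != ref.grid.shape:
        raise ValueError("prediction and reference must share a grid")
    p = pred.labels == label
    r = ref.labels == label
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / (np_ + nr)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its 6-connectivity erosion."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def hd95(
    pred: LabelVolume,
    ref: LabelVolume,
    label: int,
    spacing: tuple[float, float, float] | None = None,
) -> float:
    """95th-percentile symmetric Hausdorff distance between boundaries, in mm.

    Directed Euclidean surface distances are computed both ways on boundary
    voxels (spacing-aware), pooled, and the 95th percentile taken with
    linear interpolation.  Either mask empty → NaN (undefined, not zero).
    """
    if pred.grid.shape != ref.grid.shape:
        raise ValueError("prediction and reference must share a grid")
    if spacing is None:
        spacing = pred.grid.spacing
    p = pred.labels == label
    r = ref.labels == label
    if not p.any() or not r.any():
        return math.nan
    sp = np.asarray(spacing, dtype=float)
    pb = np.argwhere(_boundary(p)) * sp
    rb = np.argwhere(_boundary(r)) * sp
    d_pr = cKDTree(rb).query(pb)[0]
    d_rp = cKDTree(pb).query(rb)[0]
    return float(np.percentile(np.concatenate([d_pr, d_rp]), 95))


def rsd(scalar_map: ScalarVolume, parcellation: LabelVolume, label: int) -> float:
    """Relative standard deviation (coefficient of variation) within a parcel.

    Population standard deviation divided by the mean of the map over the
    parcel's voxels; a single-voxel parcel gives 0.  A near-zero mean makes
    the ratio undefined → NaN; a negative mean yields a negative RSD, which
    is reported as-is with a warning.
    """
    if scalar_map.grid.shape != parcellation.grid.shape:
        raise ValueError("map and parcellation must share a grid")
    vals = scalar_map.values[parcellation.labels == label]
    if vals.size == 0:
        raise ValueError(f"label {label} not present in the parcellation")
    mean = float(vals.mean())
    if abs(mean) < 1e-12:
        return math.nan
    out = float(vals.std()) / mean
    if mean < 0:
        warnings.warn(f"negative region mean for label {label}; RSD is negative",
                      stacklevel=2)
    return out


def confidence_maps(scores: np.ndarray):
    """(confidence, uncertainty, margin) from a voxel-wise score simplex.

    confidence = max class score; uncertainty = 1 - confidence;
    margin = top score minus second score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim < 2:
        raise ValueError("scores must be (n_classes,) + spatial")
    part = np.sort(scores, axis=0)
    conf = part[-1]
    margin = part[-1] - part[-2] if scores.shape[0] > 1 else part[-1]
    return conf, 1.0 - conf, margin


@dataclass
class MetricRecord:
    """Per-label metrics for one (prediction, reference) pair."""

    subject: str = "subject"
    dsc_per_label: dict[int, float] = field(default_factory=dict)
    hd95_per_label: dict[int, float] = field(default_factory=dict)
    rsd_per_label: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def macro_dsc(self) -> float:
        vals = list(self.dsc_per_label.values())
        return float(np.mean(vals)) if vals else math.nan

    @property
    def macro_hd95(self) -> float:
        vals = [v for v in self.hd95_per_label.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    def macro_rsd(self, map_name: str) -> float:
        vals = [v for v in self.rsd_per_label.get(map_name, {}).values()
                if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan


def evaluate_labels(
    pred: LabelVolume,
    ref: LabelVolume,
    maps: dict[str, ScalarVolume] | None = None,
    labels: list[int] | None = None,
    subject: str = "subject",
) -> MetricRecord:
    """Compute per-label DSC/HD95 (and RSD of each supplied map on ``pred``).

    Macro averages run over labels present in the reference (plus any extra
    in ``labels``); labels absent from both volumes are skipped.
    """
    if labels is None:
        labels = sorted(set(np.unique(ref.labels)) | set(np.unique(pred.labels)))
        labels = [int(l) for l in labels if l > 0]
    rec = MetricRecord(subject=subject)
    for lab in labels:
        in_ref = bool((ref.labels == lab).any())
        in_pred = bool((pred.labels == lab).any())
        if not in_ref and not in_pred:
            continue
        rec.dsc_per_label[lab] = dsc(pred, ref, lab)
        rec.hd95_per_label[lab] = hd95(pred, ref, lab)
        if maps:
            for name, vol in maps.items():
                rec.rsd_per_label.setdefault(name, {})
                rec.rsd_per_label[name][lab] = (
                    rsd(vol, pred, lab) if in_pred else math.nan
                )
    return rec


def report(records: list[MetricRecord], out_path: str | os.PathLike) -> pd.DataFrame:
    """Write per-label and macro TSV tables; returns the per-label frame.

    Missing values are encoded as ``NA``.  Two macro orderings are emitted:
    per-subject means (subject-then-label) and the pooled label mean.
    """
    rows = []
    for rec in records:
        for lab in sorted(rec.dsc_per_label):
            row = {
                "subject": rec.subject,
                "label": lab,
                "dsc": rec.dsc_per_label[lab],
                "hd95": rec.hd95_per_label.get(lab, math.nan),
            }
            for name, per_label in sorted(rec.rsd_per_label.items()):
                row[f"rsd_{name}"] = per_label.get(lab, math.nan)
            rows.append(row)
    cols = ["subject", "label", "dsc", "hd95"]
    extra = sorted({k for r in rows for k in r} - set(cols))
    frame = pd.DataFrame(rows, columns=cols + extra)
    out_path = os.fspath(out_path)
    frame.to_csv(out_path, sep="\t", index=False, na_rep="NA", float_format="%.6f")

    macro_rows = []
    for rec in records:
        macro_rows.append(
            {"subject": rec.subject, "macro_dsc": rec.macro_dsc,
             "macro_hd95": rec.macro_hd95}
        )
    if rows:
        pooled = {"subject": "POOLED",
                  "macro_dsc": frame["dsc"].mean(),
                  "macro_hd95": frame["hd95"].mean(skipna=True)}
        macro_rows.append(pooled)
    macro = pd.DataFrame(macro_rows, columns=["subject", "macro_dsc", "macro_hd95"])
    base, ext = os.path.splitext(out_path)
    macro.to_csv(f"{base}_macro{ext or '.tsv'}", sep="\t", index=False,
                 na_rep="NA", float_format="%.6f")
    return frame
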