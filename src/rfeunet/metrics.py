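"""Evaluation metrics: dice similarity coefficient and 95th-percentile
Hausdorff distance, plus per-class test-set reports.

HD95 follows the common boundary-distance dialect: boundary pixels are the
mask minus its erosion; directed distances from one boundary to the other
are read off a Euclidean distance transform, and the symmetric HD95 is the
maximum of the two directed 95th percentiles, scaled by the pixel spacing.

Conventions for degenerate masks (per class, per sample):
- absent from both prediction and ground truth: the sample is excluded from
  that class's average;
- absent from exactly one: DSC = 0 and HD95 = the image diagonal in mm (a
  finite worst case).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "MetricsReport",
    "dsc_metric",
    "hd95_metric",
    "evaluate_report",
    "format_report_text",
    "write_report_csv",
]

#: foreground class names for ids 1..8, in standard report column order
CLASS_NAMES = ("Aorta", "Gallbladder", "Kidney (L)", "Kidney (R)",
               "Liver", "Pancreas", "Spleen", "Stomach")


def _binarize(pred_mask, gt_mask, class_id):
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"mask shapes differ: {pred_mask.shape} vs {gt_mask.shape}")
    return pred_mask == class_id, gt_mask == class_id


def dsc_metric(pred_mask, gt_mask, class_id) -> float:
    """2|X n Y| / (|X| + |Y|) in percent on the binarized class.

    Returns NaN when the class is absent from both masks (the caller decides
    how to average); 0 when absent from exactly one.
    """
    p, g = _binarize(pred_mask, gt_mask, class_id)
    total = int(p.sum()) + int(g.sum())
    if total == 0:
        return float("nan")
    return 200.0 * float(np.logical_and(p, g).sum()) / total


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    border = mask & ~eroded
    if not border.any() and mask.any():  # mask too thin to erode
        return mask
    return border


def _directed_distances(src: np.ndarray, dst: np.ndarray, spacing: float) -> np.ndarray:
    dt = ndimage.distance_transform_edt(~_boundary(dst), sampling=(spacing, spacing))
    return dt[_boundary(src)]


def hd95_metric(pred_mask, gt_mask, class_id, spacing_mm: float = 1.0) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm.

    NaN when the class is absent from both masks; the image diagonal (in mm)
    when absent from exactly one.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be strictly positive")
    p, g = _binarize(pred_mask, gt_mask, class_id)
    if not p.any() and not g.any():
        return float("nan")
    if not p.any() or not g.any():
        return float(np.hypot(*p.shape) * spacing_mm)
    d_pg = _directed_distances(p, g, spacing_mm)
    d_gp = _directed_distances(g, p, spacing_mm)
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


@dataclass
class MetricsReport:
    per_class_dsc: Dict[int, float] = field(default_factory=dict)   # percent
    mean_dsc: float = float("nan")
    per_class_hd95: Dict[int, float] = field(default_factory=dict)  # mm
    mean_hd95: float = float("nan")
    n_samples: int = 0
    class_names: Dict[int, str] = field(default_factory=dict)


def evaluate_report(pred_masks: Sequence, gt_masks: Sequence, spacing: float = 1.0,
                    n_classes: int = 8, class_names: Optional[Sequence[str]] = None) -> MetricsReport:
    """Per-class and mean DSC / HD95 over a paired test set.

    Class means average over the samples where the class occurs (in either
    mask); the headline means are arithmetic means over foreground classes.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError(f"{len(pred_masks)} predictions vs {len(gt_masks)} ground truths")
    if class_names is None:
        class_names = CLASS_NAMES[:n_classes]
    dsc_acc: Dict[int, List[float]] = {c: [] for c in range(1, n_classes + 1)}
    hd_acc: Dict[int, List[float]] = {c: [] for c in range(1, n_classes + 1)}
    for pred, gt in zip(pred_masks, gt_masks):
        for c in range(1, n_classes + 1):
            d = dsc_metric(pred, gt, c)
            if np.isnan(d):  # absent from both: excluded by convention
                continue
            dsc_acc[c].append(d)
            hd_acc[c].append(hd95_metric(pred, gt, c, spacing))
    per_dsc = {c: (float(np.mean(v)) if v else float("nan")) for c, v in dsc_acc.items()}
    per_hd = {c: (float(np.mean(v)) if v else float("nan")) for c, v in hd_acc.items()}
    dsc_vals = [v for v in per_dsc.values() if not np.isnan(v)]
    hd_vals = [v for v in per_hd.values() if not np.isnan(v)]
    return MetricsReport(
        per_class_dsc=per_dsc,
        mean_dsc=float(np.mean(dsc_vals)) if dsc_vals else float("nan"),
        per_class_hd95=per_hd,
        mean_hd95=float(np.mean(hd_vals)) if hd_vals else float("nan"),
        n_samples=len(pred_masks),
        class_names={c: n for c, n in zip(range(1, n_classes + 1), class_names)},
    )


def _report_rows(report: MetricsReport):
    header = ["DSC (%)", "HD95 (mm)"] + [report.class_names[c] for c in sorted(report.class_names)]
    dsc_row = [f"{report.mean_dsc:.2f}", f"{report.mean_hd95:.2f}"] + [
        f"{report.per_class_dsc[c]:.2f}" for c in sorted(report.per_class_dsc)
    ]
    hd_row = ["", ""] + [f"{report.per_class_hd95[c]:.2f}" for c in sorted(report.per_class_hd95)]
    return header, dsc_row, hd_row


def format_report_text(report: MetricsReport) -> str:
    header, dsc_row, hd_row = _report_rows(report)
    widths = [max(len(h), len(d), len(x)) for h, d, x in zip(header, dsc_row, hd_row)]
    def fmt(row):
        return "  ".join(cell.rjust(w) for cell, w in zip(row, widths))
    lines = [
        f"n_samples = {report.n_samples}",
        fmt(header),
        fmt(dsc_row) + "   (per-class DSC %)",
        fmt(hd_row) + "   (per-class HD95 mm)",
    ]
    return "\n".join(lines)


def write_report_csv(report: MetricsReport, path) -> None:
    header, dsc_row, hd_row = _report_rows(report)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row"] + header)
        writer.writerow(["DSC"] + dsc_row)
        writer.writerow(["HD95"] + hd_row)
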