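"""Segmentation evaluation metrics and texture diagnostics.

Overlap metrics (DSC, Jaccard) and surface-distance metrics (Hausdorff
distance, average symmetric surface distance) per structure, following the
usual organ-at-risk reporting layout: one row per structure plus a mean row
and a mean over the small-volume structures.  Distances are computed on mask
boundaries (mask pixels 4-connected to background) via Euclidean distance
transforms and reported in millimetres using the pixel spacing.

Empty-mask policy: DSC/Jaccard of two empty masks is defined as 1.0 and
flagged; HD/ASSD are undefined whenever either mask is empty and are reported
as NaN with a flag, and excluded from aggregate means.

The module also provides the eight gray-level co-occurrence (GLCM/Haralick)
texture features used to quantify heterogeneity between image collections:
sum entropy, difference entropy, sum average, correlation, contrast,
homogeneity, sum variance and variance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix


def _check_masks(pred, true):
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {true.shape}")
    return pred, true


def dsc(pred_mask, true_mask):
    """Dice similarity coefficient 2|P∩T| / (|P|+|T|), in [0, 1].

    Returns (value, both_empty_flag); two empty masks score 1.0 by convention.
    """
    pred, true = _check_masks(pred_mask, true_mask)
    p, t = pred.sum(), true.sum()
    if p + t == 0:
        return 1.0, True
    return 2.0 * np.logical_and(pred, true).sum() / (p + t), False


def jaccard(pred_mask, true_mask):
    """Jaccard coefficient |P∩T| / |P∪T|; both-empty convention 1.0, flagged."""
    pred, true = _check_masks(pred_mask, true_mask)
    union = np.logical_or(pred, true).sum()
    if union == 0:
        return 1.0, True
    return np.logical_and(pred, true).sum() / union, False


def boundary_pixels(mask):
    """Mask pixels 4-connected to background (or to the image edge)."""
    mask = np.asarray(mask).astype(bool)
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def _directed_distances(src_pts_mask, dst_pts_mask, spacing):
    """Distances from every boundary pixel of src to the nearest of dst."""
    dist_to_dst = ndimage.distance_transform_edt(~dst_pts_mask, sampling=spacing)
    return dist_to_dst[src_pts_mask]


def hausdorff(pred_mask, true_mask, spacing=1.0):
    """Classical (maximum) symmetric Hausdorff distance between boundaries, in mm.

    Undefined for empty masks: returns NaN with a flag.
    """
    pred, true = _check_masks(pred_mask, true_mask)
    if pred.sum() == 0 or true.sum() == 0:
        return float("nan"), True
    bp, bt = boundary_pixels(pred), boundary_pixels(true)
    d_pt = _directed_distances(bp, bt, spacing)
    d_tp = _directed_distances(bt, bp, spacing)
    return float(max(d_pt.max(), d_tp.max())), False


def hausdorff95(pred_mask, true_mask, spacing=1.0):
    """95th-percentile Hausdorff distance (robust variant, behind its own name)."""
    pred, true = _check_masks(pred_mask, true_mask)
    if pred.sum() == 0 or true.sum() == 0:
        return float("nan"), True
    bp, bt = boundary_pixels(pred), boundary_pixels(true)
    d_pt = _directed_distances(bp, bt, spacing)
    d_tp = _directed_distances(bt, bp, spacing)
    return float(max(np.percentile(d_pt, 95), np.percentile(d_tp, 95))), False


def assd(pred_mask, true_mask, spacing=1.0):
    """Average symmetric surface distance: mean of pooled nearest-boundary
    distances in both directions, in mm."""
    pred, true = _check_masks(pred_mask, true_mask)
    if pred.sum() == 0 or true.sum() == 0:
        return float("nan"), True
    bp, bt = boundary_pixels(pred), boundary_pixels(true)
    d_pt = _directed_distances(bp, bt, spacing)
    d_tp = _directed_distances(bt, bp, spacing)
    pooled = np.concatenate([d_pt, d_tp])
    return float(pooled.mean()), False


# ---------------------------------------------------------------------------
# multi-class evaluation reports
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-structure and aggregate metrics for a set of label maps."""

    per_structure: dict = field(default_factory=dict)  # name -> metric dict
    mean: dict = field(default_factory=dict)
    mean_small: dict = field(default_factory=dict)
    spacing: float = 1.0
    empty_counts: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "per_structure": self.per_structure,
            "mean": self.mean,
            "mean_small_volume": self.mean_small,
            "spacing_mm": self.spacing,
            "empty_mask_counts": self.empty_counts,
        }


def evaluate_label_map(pred_label, true_label, num_classes, spacing=1.0):
    """Binary class-vs-rest metrics for each structure (labels 1..M-1)."""
    rows = {}
    for m in range(1, num_classes):
        pm, tm = pred_label == m, true_label == m
        d, d_flag = dsc(pm, tm)
        j, _ = jaccard(pm, tm)
        hd, hd_flag = hausdorff(pm, tm, spacing)
        ad, _ = assd(pm, tm, spacing)
        rows[m] = {
            "dsc": float(d),
            "jaccard": float(j),
            "hd": hd,
            "assd": ad,
            "empty": bool(hd_flag),
            "both_empty": bool(d_flag),
        }
    return rows


def aggregate_reports(
    sample_rows: list[dict],
    num_classes: int,
    spacing: float = 1.0,
    small_structures: tuple = (4, 5),
    structure_names: dict | None = None,
) -> MetricsReport:
    """Pool per-sample rows into per-structure means and aggregate rows.

    HD/ASSD entries flagged as empty are excluded from means; the counts of
    exclusions are reported.
    """
    report = MetricsReport(spacing=spacing)
    names = structure_names or {m: f"structure_{m}" for m in range(1, num_classes)}
    per = {}
    for m in range(1, num_classes):
        vals = {"dsc": [], "jaccard": [], "hd": [], "assd": []}
        empties = 0
        for rows in sample_rows:
            r = rows[m]
            vals["dsc"].append(r["dsc"])
            vals["jaccard"].append(r["jaccard"])
            if r["empty"]:
                empties += 1
            else:
                vals["hd"].append(r["hd"])
                vals["assd"].append(r["assd"])
        per[names[m]] = {
            k: (float(np.mean(v)) if len(v) else float("nan")) for k, v in vals.items()
        }
        report.empty_counts[names[m]] = empties
    report.per_structure = per
    def _nanmean(vals):
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    for key in ("dsc", "jaccard", "hd", "assd"):
        report.mean[key] = _nanmean([per[names[m]][key] for m in range(1, num_classes)])
        report.mean_small[key] = _nanmean(
            [per[names[m]][key] for m in small_structures if m < num_classes]
        )
    return report


def write_report(report: MetricsReport, json_path=None, csv_path=None):
    data = report.to_dict()
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(data, fh, indent=2)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["structure", "dsc", "jaccard", "hd_mm", "assd_mm"])
            for name, row in report.per_structure.items():
                writer.writerow([name, row["dsc"], row["jaccard"], row["hd"], row["assd"]])
            writer.writerow(
                ["Mean", report.mean["dsc"], report.mean["jaccard"], report.mean["hd"], report.mean["assd"]]
            )
            writer.writerow(
                [
                    "Mean (small volume)",
                    report.mean_small["dsc"],
                    report.mean_small["jaccard"],
                    report.mean_small["hd"],
                    report.mean_small["assd"],
                ]
            )
    return data


# ---------------------------------------------------------------------------
# GLCM texture features
# ---------------------------------------------------------------------------

GLCM_FEATURES = (
    "sum_entropy",
    "difference_entropy",
    "sum_average",
    "correlation",
    "contrast",
    "homogeneity",
    "sum_variance",
    "variance",
)


def _glcm_stats(p):
    """The eight Haralick-style statistics from one normalised symmetric GLCM."""
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    px = p.sum(axis=1)
    mu_x = float((np.arange(levels) * px).sum())
    mu_y = mu_x  # symmetric matrix
    var_x = float(((np.arange(levels) - mu_x) ** 2 * px).sum())

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    k_sum = (i + j).ravel()
    k_diff = np.abs(i - j).ravel()
    p_flat = p.ravel()
    p_sum = np.bincount(k_sum, weights=p_flat, minlength=2 * levels - 1)
    p_diff = np.bincount(k_diff, weights=p_flat, minlength=levels)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    sum_avg = float((np.arange(2 * levels - 1) * p_sum).sum())
    feats = {
        "sum_entropy": entropy(p_sum),
        "difference_entropy": entropy(p_diff),
        "sum_average": sum_avg,
        "contrast": float(((i - j) ** 2 * p).sum()),
        "homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "sum_variance": float(((np.arange(2 * levels - 1) - sum_avg) ** 2 * p_sum).sum()),
        "variance": var_x,
    }
    if var_x <= 0:
        feats["correlation"] = float("nan")  # undefined for a constant image
    else:
        cov = float((((i - mu_x) * (j - mu_y)) * p).sum())
        feats["correlation"] = cov / var_x  # sigma_x == sigma_y by symmetry
    return feats


def compare_texture_distributions(
    images_a, images_b, levels=16, offsets=((0, 1), (1, 0)), value_range=(0.0, 1.0)
):
    """Heterogeneity diagnostic between two image collections.

    Computes the eight GLCM features per image and a two-sample
    Mann-Whitney U p-value per feature (standard implementation; this module
    only wires it to the texture features).  Returns
    ``{feature: {"p_value": ..., "median_a": ..., "median_b": ...}}``.
    """
    from scipy.stats import mannwhitneyu

    feats_a = [glcm_features(im, levels, offsets, value_range) for im in images_a]
    feats_b = [glcm_features(im, levels, offsets, value_range) for im in images_b]
    out = {}
    for key in GLCM_FEATURES:
        a = np.array([f[key] for f in feats_a])
        b = np.array([f[key] for f in feats_b])
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            out[key] = {"p_value": float("nan"), "median_a": float("nan"), "median_b": float("nan")}
            continue
        stat = mannwhitneyu(a, b, alternative="two-sided")
        out[key] = {
            "p_value": float(stat.pvalue),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
        }
    return out


def glcm_features(image, levels=16, offsets=((0, 1), (1, 0)), value_range=None):
    """Eight Haralick texture statistics averaged over pixel offsets.

    ``image`` is quantised uniformly to ``levels`` gray levels — over its own
    min-max range by default, or over a fixed ``value_range`` (the right
    choice for absolute intensity scales, where location/gain shifts between
    collections are themselves the signal).  Each offset (dy, dx) contributes
    one symmetric normalised co-occurrence matrix.  A constant image yields
    NaN correlation (flagged via the value itself).
    """
    img = np.asarray(image, dtype=np.float64)
    lo, hi = value_range if value_range is not None else (img.min(), img.max())
    img = np.clip(img, lo, hi)
    if hi > lo:
        q = np.minimum((levels * (img - lo) / (hi - lo)).astype(np.intp), levels - 1)
    else:
        q = np.zeros_like(img, dtype=np.intp)
    acc = {k: 0.0 for k in GLCM_FEATURES}
    for dy, dx in offsets:
        dist = int(round(np.hypot(dy, dx)))
        angle = np.arctan2(-dy, dx)  # skimage angles are CCW from +x
        glcm = graycomatrix(
            q.astype(np.uint8), [dist], [angle], levels=levels, symmetric=True, normed=True
        )[:, :, 0, 0]
        stats = _glcm_stats(glcm)
        for k in GLCM_FEATURES:
            acc[k] += stats[k]
    return {k: v / len(offsets) for k, v in acc.items()}
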