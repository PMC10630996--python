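"""Exon-level enrichment scoring for ipaRt-style RIP coverage.

ipaRt reads out EJC binding as protected fragment coverage rather than
truncation, so the exon score is coverage-based: within the deposition
window [-36, -10] upstream of the junction, take the median of the
nonzero per-position depths in each library, average the medians across
ipaRt replicates and across mRNA-seq controls, and form the IP/mRNA
ratio. Because no last exon can carry an EJC, the empirical decision
threshold is the 95th percentile of the ratio among last exons; an exon
is *loaded* when it has window coverage in every library
(consistently detected) and its ratio strictly exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord
from .io import assign_reads, exon_frame

__all__ = [
    "IPART_WINDOW",
    "ThresholdCalibration",
    "window_median_coverage",
    "window_coverage_medians",
    "enrichment_ratio",
    "ipart_scores",
    "calibrate_threshold",
    "call_loaded",
    "apply_calls",
    "ipart_pipeline",
]

IPART_WINDOW = (-36, -10)
CALIB_PERCENTILE = 95.0
MIN_CALIBRATION_EXONS = 20


def window_median_coverage(depths: np.ndarray) -> float:
    """Median of the nonzero per-position depths of one exon window.

    Zero-depth positions are filtered before taking the median; a window
    with no coverage at all yields NaN (exon undetected in this library).
    """
    depths = np.asarray(depths)
    nz = depths[depths > 0]
    return float(np.median(nz)) if len(nz) else float("nan")


def window_coverage_medians(reads: pd.DataFrame,
                            exons: Sequence[ExonRecord] | pd.DataFrame,
                            window: tuple[int, int] = IPART_WINDOW) -> pd.Series:
    """Per-exon window median coverage for one library.

    Coverage counts every read base falling in the window (reads are
    assigned to the exon containing their 5' end and clipped at exon
    boundaries). Returns a Series indexed by exon_id, NaN where the
    window is wholly uncovered. Exons shorter than the window's far
    bound are evaluated on the truncated window.
    """
    ex = exon_frame(exons)
    assigned = assign_reads(reads, ex)
    lo, hi = window

    lengths = ex["length"].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    row_of = {eid: i for i, eid in enumerate(ex["exon_id"])}

    diff = np.zeros(total + 1, dtype=np.int64)
    if len(assigned):
        e_index = assigned["exon_id"].map(row_of).to_numpy()
        base = offsets[e_index] + lengths[e_index]
        rel5 = assigned["rel5"].to_numpy()
        rel3 = assigned["rel3"].to_numpy()
        np.add.at(diff, base + rel5, 1)
        np.add.at(diff, base + rel3 + 1, -1)
    depth = np.cumsum(diff)[:total]

    med = np.full(len(ex), np.nan)
    for i in range(len(ex)):
        L = lengths[i]
        w_lo = max(lo, -L)
        block = depth[offsets[i] + L + w_lo : offsets[i] + L + hi + 1]
        med[i] = window_median_coverage(block)
    return pd.Series(med, index=ex["exon_id"], name="median_cov")


def enrichment_ratio(ip_medians: Sequence[float], ctrl_medians: Sequence[float]) -> float:
    """IP/control enrichment: mean of replicate medians over mean of control medians.

    Any undefined (NaN) median makes the ratio NaN — the exon is then
    *undetected*, not unloaded.
    """
    ip = np.asarray(ip_medians, dtype=float)
    ct = np.asarray(ctrl_medians, dtype=float)
    if np.isnan(ip).any() or np.isnan(ct).any():
        return float("nan")
    return float(ip.mean() / ct.mean())


@dataclass(frozen=True)
class ThresholdCalibration:
    """Empirical loaded/unloaded threshold from the last-exon null set."""

    threshold: float
    calibration_set: tuple[str, ...]
    percentile: float = CALIB_PERCENTILE


def ipart_scores(ip_reads: Sequence[pd.DataFrame], rna_reads: Sequence[pd.DataFrame],
                 exons: Sequence[ExonRecord] | pd.DataFrame,
                 window: tuple[int, int] = IPART_WINDOW) -> pd.DataFrame:
    """Windowed enrichment scores for every exon.

    Columns: exon_id, gene_id, cls, length, ip_med_i / rna_med_j per
    library, ip_mean, ctrl_mean, ratio, consistently_detected (window
    coverage present in every IP and every mRNA-seq library).
    """
    ex = exon_frame(exons)
    out = ex[["exon_id", "gene_id", "cls", "length"]].copy()
    ip_cols, rna_cols = [], []
    for i, reads in enumerate(ip_reads, start=1):
        out[f"ip_med_{i}"] = window_coverage_medians(reads, ex, window).to_numpy()
        ip_cols.append(f"ip_med_{i}")
    for j, reads in enumerate(rna_reads, start=1):
        out[f"rna_med_{j}"] = window_coverage_medians(reads, ex, window).to_numpy()
        rna_cols.append(f"rna_med_{j}")
    ip = out[ip_cols].to_numpy()
    ct = out[rna_cols].to_numpy()
    out["consistently_detected"] = ~np.isnan(ip).any(axis=1) & ~np.isnan(ct).any(axis=1)
    out["ip_mean"] = ip.mean(axis=1)
    out["ctrl_mean"] = ct.mean(axis=1)
    out["ratio"] = np.where(out["consistently_detected"],
                            out["ip_mean"] / out["ctrl_mean"], np.nan)
    out.attrs["window"] = window
    return out


def calibrate_threshold(scores: pd.DataFrame,
                        percentile: float = CALIB_PERCENTILE) -> ThresholdCalibration:
    """Empirical threshold: the 95th percentile of last-exon ratios.

    Only consistently detected last exons enter the calibration set
    (undefined ratios cannot enter a percentile). The percentile uses
    linear interpolation between order statistics, raised to the next
    order statistic whenever interpolation alone would leave more than
    5% of the calibration ratios strictly above it — the defining
    property of an empirical null cut-off.
    """
    calib = scores[(scores["cls"] == "last") & scores["consistently_detected"]]
    if len(calib) < MIN_CALIBRATION_EXONS:
        raise ValueError(
            f"only {len(calib)} consistently detected last exons; "
            f">= {MIN_CALIBRATION_EXONS} needed to calibrate — provide deeper data"
        )
    ratios = np.sort(calib["ratio"].to_numpy())
    thr = float(np.percentile(ratios, percentile))
    k = int(np.ceil(percentile / 100.0 * len(ratios)))  # smallest count covering >=95%
    if (ratios <= thr).sum() < k:
        thr = float(ratios[k - 1])
    return ThresholdCalibration(threshold=thr,
                                calibration_set=tuple(calib["exon_id"]),
                                percentile=percentile)


def call_loaded(ratio: float, consistently_detected: bool,
                calib: ThresholdCalibration) -> bool:
    """Loaded iff detected in every library and ratio strictly above threshold."""
    return bool(consistently_detected and not np.isnan(ratio)
                and ratio > calib.threshold)


def apply_calls(scores: pd.DataFrame, calib: ThresholdCalibration) -> pd.DataFrame:
    """Add the loaded call column to a score table."""
    out = scores.copy()
    out["threshold"] = calib.threshold
    out["loaded"] = (
        out["consistently_detected"] & (out["ratio"] > calib.threshold)
    ).fillna(False)
    return out


def ipart_pipeline(ip_reads: Sequence[pd.DataFrame], rna_reads: Sequence[pd.DataFrame],
                   exons: Sequence[ExonRecord] | pd.DataFrame,
                   window: tuple[int, int] = IPART_WINDOW,
                   percentile: float = CALIB_PERCENTILE) -> tuple[pd.DataFrame, ThresholdCalibration]:
    """Score, calibrate on last exons, and call loading for every exon."""
    scores = ipart_scores(ip_reads, rna_reads, exons, window=window)
    calib = calibrate_threshold(scores, percentile=percentile)
    return apply_calls(scores, calib), calib
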