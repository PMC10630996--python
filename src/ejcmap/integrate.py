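"""Cross-method integration, bias stratification and peak-set agreement.

Brings the two detection routes together: per-exon expression (RPKM) and
equal-count decile bins, uridine-count strata, detection-rate tables per
stratum, the both / one / neither classification over exons of genes
expressed in both datasets, and the slop-extended Jaccard index between
peak sets from independent replicates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord
from .io import assign_reads, exon_frame

__all__ = [
    "rpkm",
    "exon_read_counts",
    "expression_table",
    "expression_bins",
    "detection_rate_by_stratum",
    "combine_calls",
    "jaccard_peaks",
]


def rpkm(read_count: int | np.ndarray, exon_length: int | np.ndarray,
         library_size: int) -> float | np.ndarray:
    """Reads per kilobase of exon per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    length = np.asarray(exon_length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("exon_length must be positive")
    out = np.asarray(read_count, dtype=float) / (length / 1e3) / (library_size / 1e6)
    return float(out) if out.ndim == 0 else out


def exon_read_counts(reads: pd.DataFrame,
                     exons: Sequence[ExonRecord] | pd.DataFrame) -> pd.Series:
    """Reads per exon (assigned by 5' end), indexed by exon_id, zeros included."""
    ex = exon_frame(exons)
    assigned = assign_reads(reads, ex)
    counts = assigned.groupby("exon_id").size()
    return counts.reindex(ex["exon_id"], fill_value=0)


def expression_table(rna_reads: Sequence[pd.DataFrame],
                     exons: Sequence[ExonRecord] | pd.DataFrame,
                     k: int = 10) -> pd.DataFrame:
    """Per-exon RPKM (averaged over mRNA-seq libraries) with decile bins."""
    ex = exon_frame(exons)
    vals = np.zeros(len(ex))
    for reads in rna_reads:
        counts = exon_read_counts(reads, ex).to_numpy()
        vals += rpkm(counts, ex["length"].to_numpy(), len(reads))
    vals /= len(rna_reads)
    out = ex[["exon_id", "gene_id", "cls", "length"]].copy()
    out["rpkm"] = vals
    out["decile"] = expression_bins(pd.Series(vals, index=ex["exon_id"]), k=k).to_numpy()
    return out


def expression_bins(rpkm_by_exon: pd.Series, k: int = 10) -> pd.Series:
    """Equal-count expression bins (1 = lowest ... k = highest).

    Exons are rank-ordered by RPKM with ties broken stably by exon_id, so
    bin membership counts differ by at most one.
    """
    n = len(rpkm_by_exon)
    if k > n:
        raise ValueError(f"cannot form {k} bins from {n} exons")
    order = np.lexsort((rpkm_by_exon.index.to_numpy(), rpkm_by_exon.to_numpy()))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    deciles = ranks * k // n + 1
    return pd.Series(deciles, index=rpkm_by_exon.index, name="decile")


def detection_rate_by_stratum(calls: pd.DataFrame, strata: Mapping[str, object] | pd.Series,
                              detected_col: str = "detected",
                              exclude_cls: tuple[str, ...] = ("last", "single")) -> pd.DataFrame:
    """Detection rate per stratum.

    ``calls`` needs exon_id, cls and a boolean detection column; ``strata``
    maps exon_id -> stratum label. Last/single exons are excluded by
    default (the canonical exon-group analysis excludes the last exon).
    Empty strata report n=0 and NaN rate.
    """
    if len(calls) == 0:
        raise ValueError("empty call set")
    df = calls.copy()
    df["stratum"] = df["exon_id"].map(dict(strata) if not isinstance(strata, pd.Series)
                                      else strata)
    df = df[~df["cls"].isin(exclude_cls) & df["stratum"].notna()]
    g = df.groupby("stratum", sort=True)[detected_col].agg(["sum", "size"])
    out = g.rename(columns={"sum": "n_detected", "size": "n"}).reset_index()
    out["n_detected"] = out["n_detected"].astype(int)
    out["rate"] = np.where(out["n"] > 0, out["n_detected"] / out["n"], np.nan)
    return out


def combine_calls(eclip_detected: Mapping[str, bool], ipart_loaded: Mapping[str, bool],
                  expressed_both: set[str],
                  exons: Sequence[ExonRecord] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify exons into both / one / neither over the shared universe.

    Exons outside ``expressed_both`` (genes not expressed and detected in
    both datasets) are classified ``excluded``. When ``exons`` is given,
    cls labels are attached and the full exon universe is reported.
    """
    ids = set(eclip_detected) | set(ipart_loaded) | set(expressed_both)
    rows = []
    for eid in sorted(ids):
        e = bool(eclip_detected.get(eid, False))
        p = bool(ipart_loaded.get(eid, False))
        if eid not in expressed_both:
            combined = "excluded"
        elif e and p:
            combined = "both"
        elif e or p:
            combined = "one"
        else:
            combined = "neither"
        rows.append((eid, e, p, combined))
    out = pd.DataFrame(rows, columns=["exon_id", "eclip_detected", "ipart_loaded", "combined"])
    if exons is not None:
        ex = exon_frame(exons)
        out = out.merge(ex[["exon_id", "cls"]], on="exon_id", how="left")
    out["union_detected"] = (out["eclip_detected"] | out["ipart_loaded"]) & (
        out["combined"] != "excluded"
    )
    return out


def _overlaps_any(a_start: np.ndarray, a_end: np.ndarray,
                  b_start: np.ndarray, b_end: np.ndarray) -> np.ndarray:
    """For each interval of A, whether it overlaps (>=1 bp) any interval of B."""
    if len(b_start) == 0:
        return np.zeros(len(a_start), dtype=bool)
    order = np.argsort(b_start)
    bs, be = b_start[order], np.maximum.accumulate(b_end[order])
    k = np.searchsorted(bs, a_end, side="left")  # b intervals starting before a's end
    prefix_max_end = np.concatenate([[np.iinfo(np.int64).min], be])
    return prefix_max_end[k] > a_start


def jaccard_peaks(a: pd.DataFrame, b: pd.DataFrame,
                  slop: int = 5) -> tuple[int, int, float | None]:
    """Slop-extended, strand-aware peak agreement between two peak sets.

    Both sets (BED-like frames with chrom/start/end/strand) are extended
    by ``slop`` nt on each end; the intersection counts peaks of A
    overlapping at least one extended peak of B on the same strand, and
    the union follows by inclusion-exclusion: |A| + |B| - |A n B|.
    Returns (intersection, union, jaccard); jaccard is None when both
    sets are empty.
    """
    if len(a) == 0 and len(b) == 0:
        return 0, 0, None
    a = a.reset_index(drop=True)
    hits = np.zeros(len(a), dtype=bool)
    b_grouped = dict(iter(b.groupby(["chrom", "strand"], sort=False))) if len(b) else {}
    for (chrom, strand), ga in (a.groupby(["chrom", "strand"], sort=False)
                                if len(a) else []):
        gb = b_grouped.get((chrom, strand))
        if gb is None:
            continue
        hit = _overlaps_any(
            ga["start"].to_numpy() - slop, ga["end"].to_numpy() + slop,
            gb["start"].to_numpy() - slop, gb["end"].to_numpy() + slop,
        )
        hits[ga.index.to_numpy()] = hit
    intersection = int(hits.sum())
    union = len(a) + len(b) - intersection
    return intersection, union, intersection / union if union else None
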