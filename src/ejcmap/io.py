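"""Read-set I/O and exon assignment.

Aligned single-end reads are carried as pandas DataFrames in BED6 layout
(chrom, start, end, name, score, strand; 0-based half-open). The read 5'
end — ``start`` on the plus strand, ``end - 1`` on the minus strand — is
interpreted as the reverse-transcriptase truncation site, i.e. the
crosslinked nucleotide, throughout.

Reads are assigned to the representative exon that contains their 5' end
on the matching strand; representative exons are assumed non-overlapping
within a (chromosome, strand) pair. Assignment attaches transcript-relative
coordinates (see :mod:`ejcmap.annotation` for the -1 = junction convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord

__all__ = ["read_bed6", "write_bed6", "exon_frame", "assign_reads", "five_prime"]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Load a BED6 file of single-end alignments."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} records without +/- strand")
    return df


def write_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    reads.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def five_prime(reads: pd.DataFrame) -> np.ndarray:
    """Genomic coordinate of each read's 5' end."""
    return np.where(reads["strand"].to_numpy() == "+",
                    reads["start"].to_numpy(),
                    reads["end"].to_numpy() - 1)


def exon_frame(exons: Sequence[ExonRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a list of ExonRecord (or an exon table) to a DataFrame."""
    if isinstance(exons, pd.DataFrame):
        return exons.reset_index(drop=True)
    return pd.DataFrame(
        {
            "exon_id": [e.exon_id for e in exons],
            "gene_id": [e.gene_id for e in exons],
            "index": [e.index for e in exons],
            "cls": [e.cls for e in exons],
            "chrom": [e.chrom for e in exons],
            "start": [e.start for e in exons],
            "end": [e.end for e in exons],
            "strand": [e.strand for e in exons],
            "length": [e.end - e.start for e in exons],
        }
    )


def assign_reads(reads: pd.DataFrame, exons: Sequence[ExonRecord] | pd.DataFrame) -> pd.DataFrame:
    """Assign reads to the exon containing their 5' end, strand-aware.

    Returns a copy of the assigned reads with extra columns:

    ``exon_id``, ``cls``, ``exon_length`` — the containing exon;
    ``rel5`` — relative position of the read 5' end (-1 = junction-adjacent);
    ``rel3`` — relative position of the 3'-most base covered inside the exon
    (read footprints are clipped at exon boundaries).

    Reads whose 5' end falls outside every representative exon are dropped;
    the number dropped is available as ``result.attrs["n_dropped"]``.
    """
    ex = exon_frame(exons)
    fp = five_prime(reads)
    exon_idx = np.full(len(reads), -1, dtype=np.int64)

    for (chrom, strand), grp in ex.groupby(["chrom", "strand"], sort=False):
        starts = grp["start"].to_numpy()
        order = np.argsort(starts)
        starts = starts[order]
        ends = grp["end"].to_numpy()[order]
        rows = grp.index.to_numpy()[order]

        mask = (reads["chrom"].to_numpy() == chrom) & (reads["strand"].to_numpy() == strand)
        if not mask.any():
            continue
        pos = fp[mask]
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        tgt = np.where(mask)[0][inside]
        exon_idx[tgt] = rows[j[inside]]

    hit = exon_idx >= 0
    out = reads.loc[hit].copy()
    k = exon_idx[hit]
    e_start = ex["start"].to_numpy()[k]
    e_end = ex["end"].to_numpy()[k]
    plus = out["strand"].to_numpy() == "+"
    fp_hit = fp[hit]

    rel5 = np.where(plus, fp_hit - e_end, e_start - fp_hit - 1)
    cov_hi = np.minimum(out["end"].to_numpy(), e_end)  # exclusive
    cov_lo = np.maximum(out["start"].to_numpy(), e_start)
    rel3 = np.where(plus, cov_hi - 1 - e_end, e_start - cov_lo - 1)

    out["exon_id"] = ex["exon_id"].to_numpy()[k]
    out["cls"] = ex["cls"].to_numpy()[k]
    out["exon_length"] = (e_end - e_start).astype(np.int64)
    out["rel5"] = rel5.astype(np.int64)
    out["rel3"] = rel3.astype(np.int64)
    out.attrs["n_dropped"] = int(len(reads) - hit.sum())
    return out.reset_index(drop=True)
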