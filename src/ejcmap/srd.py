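"""The Stop Rate Difference (SRD) statistic for truncation-based eCLIP.

At every exonic position the reverse transcriptase either arrests (the
read 5' end sits exactly there) or reads through (the read covers the
position but started further 5'-ward). The stop rate is
``arrests / (arrests + throughs)``. Each eCLIP replicate's stop rate is
tested per position against a pooled SMInput control with a 2x2 Pearson
chi-square (1 df, no continuity correction), gated one-sidedly on the
replicate rate exceeding the control rate. Positions significant
(p < alpha) in at least ``min_reps`` replicates are flagged, and the SRD
is the mean replicate stop rate minus the control stop rate. The
exon-level score averages the SRD over significant positions within the
canonical deposition window [-32, -23]; an exon is *detected* when the
window holds at least one significant position and the score is positive.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .annotation import ExonRecord
from .io import assign_reads, exon_frame

__all__ = [
    "SRD_WINDOW",
    "SECONDARY_WINDOW",
    "position_stats",
    "pool_position_stats",
    "arrest_test",
    "chi2_pvalues",
    "srd_table",
    "exon_srd",
    "secondary_window_overlap",
    "srd_pipeline",
]

SRD_WINDOW = (-32, -23)
SECONDARY_WINDOW = (-22, -13)
ALPHA = 0.05
MIN_REPS = 2


def position_stats(assigned: pd.DataFrame) -> pd.DataFrame:
    """Tabulate per-position arrest and readthrough counts per exon.

    ``assigned`` must carry exon_id / exon_length / rel5 / rel3 columns
    (see :func:`ejcmap.io.assign_reads`). A read arrests at its 5'-end
    position and reads through every position from rel5+1 to its clipped
    3' end. Returns rows for every position with any coverage:
    exon_id, position, n_arrest, n_through, stop_rate.
    """
    if len(assigned) == 0:
        return pd.DataFrame(columns=["exon_id", "position", "n_arrest", "n_through", "stop_rate"])
    eids, e_index = np.unique(assigned["exon_id"].to_numpy(), return_inverse=True)
    lengths = np.zeros(len(eids), dtype=np.int64)
    lengths[e_index] = assigned["exon_length"].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    rel5 = assigned["rel5"].to_numpy()
    rel3 = assigned["rel3"].to_numpy()
    base = offsets[e_index] + lengths[e_index]  # index of position 0 of each exon's block

    arrest = np.zeros(total, dtype=np.int64)
    np.add.at(arrest, base + rel5, 1)

    diff = np.zeros(total + 1, dtype=np.int64)
    has_thru = rel3 > rel5
    np.add.at(diff, base[has_thru] + rel5[has_thru] + 1, 1)
    np.add.at(diff, base[has_thru] + rel3[has_thru] + 1, -1)
    through = np.cumsum(diff)[:total]

    covered = (arrest + through) > 0
    idx = np.nonzero(covered)[0]
    exon_of = np.searchsorted(offsets, idx, side="right") - 1
    position = idx - offsets[exon_of] - lengths[exon_of]
    out = pd.DataFrame(
        {
            "exon_id": eids[exon_of],
            "position": position,
            "n_arrest": arrest[idx],
            "n_through": through[idx],
        }
    )
    out["stop_rate"] = out["n_arrest"] / (out["n_arrest"] + out["n_through"])
    return out


def pool_position_stats(stats: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool libraries by summing arrest/through counts per position.

    Used to merge the SMInput controls into the single control dataset
    the per-position test runs against.
    """
    merged = (
        pd.concat(stats, ignore_index=True)
        .groupby(["exon_id", "position"], as_index=False)[["n_arrest", "n_through"]]
        .sum()
    )
    merged["stop_rate"] = merged["n_arrest"] / (merged["n_arrest"] + merged["n_through"])
    return merged


def chi2_pvalues(a_s: np.ndarray, t_s: np.ndarray,
                 a_c: np.ndarray, t_c: np.ndarray) -> np.ndarray:
    """Vectorized 2x2 Pearson chi-square p-values (1 df, no correction).

    Tables with any zero marginal are degenerate and get p = 1.
    """
    a_s, t_s, a_c, t_c = (np.asarray(x, dtype=float) for x in (a_s, t_s, a_c, t_c))
    row_s, row_c = a_s + t_s, a_c + t_c
    col_a, col_t = a_s + a_c, t_s + t_c
    n = row_s + row_c
    denom = row_s * row_c * col_a * col_t
    ok = denom > 0
    stat = np.zeros_like(n)
    np.divide(n * (a_s * t_c - t_s * a_c) ** 2, denom, out=stat, where=ok)
    p = np.ones_like(n)
    p[ok] = _chi2_dist.sf(stat[ok], df=1)
    return p


def arrest_test(n_arrest_s: int, n_through_s: int,
                n_arrest_c: int, n_through_c: int) -> float:
    """Chi-square p-value for one sample-vs-control position (scalar form)."""
    return float(chi2_pvalues(np.array([n_arrest_s]), np.array([n_through_s]),
                              np.array([n_arrest_c]), np.array([n_through_c]))[0])


def srd_table(replicate_stats: Sequence[pd.DataFrame], control_stats: pd.DataFrame,
              alpha: float = ALPHA, min_reps: int = MIN_REPS) -> pd.DataFrame:
    """Per-position SRD over every position covered in >=1 replicate.

    A replicate counts as significant at a position iff its chi-square
    p < alpha AND its stop rate exceeds the control's (one-sided gate).
    ``significant`` requires at least ``min_reps`` such replicates. The
    SRD is the mean over replicates with data minus the control rate;
    positions lacking control data use control rate 0 and are flagged
    in ``control_missing``.
    """
    keys = pd.concat(
        [s[["exon_id", "position"]] for s in replicate_stats], ignore_index=True
    ).drop_duplicates()
    out = keys.sort_values(["exon_id", "position"]).reset_index(drop=True)

    ctrl = control_stats.rename(
        columns={"n_arrest": "ctrl_arrest", "n_through": "ctrl_through", "stop_rate": "ctrl_rate"}
    )
    out = out.merge(ctrl, on=["exon_id", "position"], how="left")
    out["control_missing"] = out["ctrl_rate"].isna()
    out[["ctrl_arrest", "ctrl_through"]] = out[["ctrl_arrest", "ctrl_through"]].fillna(0)
    out["ctrl_rate"] = out["ctrl_rate"].fillna(0.0)

    rates, sigs = [], []
    for i, stats in enumerate(replicate_stats, start=1):
        rep = stats.rename(
            columns={"n_arrest": f"arrest_{i}", "n_through": f"through_{i}",
                     "stop_rate": f"rate_{i}"}
        )
        out = out.merge(rep, on=["exon_id", "position"], how="left")
        p = chi2_pvalues(
            np.nan_to_num(out[f"arrest_{i}"]), np.nan_to_num(out[f"through_{i}"]),
            out["ctrl_arrest"], out["ctrl_through"],
        )
        p[out[f"rate_{i}"].isna().to_numpy()] = np.nan
        out[f"p_{i}"] = p
        sig = (p < alpha) & (out[f"rate_{i}"] > out["ctrl_rate"]).to_numpy()
        out[f"sig_{i}"] = np.where(np.isnan(p), False, sig)
        rates.append(out[f"rate_{i}"].to_numpy())
        sigs.append(out[f"sig_{i}"].to_numpy())

    rate_mat = np.vstack(rates)
    with np.errstate(invalid="ignore"):
        mean_rate = np.nanmean(rate_mat, axis=0)
    out["n_significant_replicates"] = np.vstack(sigs).sum(axis=0)
    out["significant"] = out["n_significant_replicates"] >= min_reps
    out["srd"] = mean_rate - out["ctrl_rate"].to_numpy()
    return out


def exon_srd(positions: pd.DataFrame, exons: Sequence[ExonRecord] | pd.DataFrame,
             window: tuple[int, int] = SRD_WINDOW) -> pd.DataFrame:
    """Windowed exon-level SRD score and detection call for every exon.

    Returns one row per representative exon: exon_id, cls, length,
    n_significant_positions (within the window), srd_score (mean SRD over
    those positions; NaN when none), detected, window_truncated (exon
    shorter than the window's far bound).
    """
    ex = exon_frame(exons)
    lo, hi = window
    in_win = positions[
        (positions["position"] >= lo) & (positions["position"] <= hi)
        & positions["significant"]
    ]
    agg = in_win.groupby("exon_id").agg(
        n_significant_positions=("srd", "size"), srd_score=("srd", "mean")
    )
    out = ex[["exon_id", "gene_id", "cls", "length"]].merge(
        agg, on="exon_id", how="left"
    )
    out["n_significant_positions"] = out["n_significant_positions"].fillna(0).astype(int)
    out["detected"] = (out["n_significant_positions"] >= 1) & (out["srd_score"] > 0)
    out["window_truncated"] = out["length"] < -lo
    out.attrs["window"] = window
    return out


def secondary_window_overlap(detected_secondary: set[str],
                             detected_primary: set[str]) -> float | None:
    """Fraction of secondary-window detections coexisting with a primary peak.

    Returns |secondary AND primary| / |secondary|, or None when the
    secondary set is empty.
    """
    if not detected_secondary:
        return None
    return len(detected_secondary & detected_primary) / len(detected_secondary)


def srd_pipeline(replicate_reads: Sequence[pd.DataFrame],
                 control_reads: Sequence[pd.DataFrame],
                 exons: Sequence[ExonRecord] | pd.DataFrame,
                 alpha: float = ALPHA, min_reps: int = MIN_REPS,
                 window: tuple[int, int] = SRD_WINDOW) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end SRD: reads -> per-position table and per-exon detection calls.

    ``control_reads`` (the SMInputs) are pooled into a single control.
    """
    ex = exon_frame(exons)
    rep_stats = [position_stats(assign_reads(r, ex)) for r in replicate_reads]
    ctrl_stats = pool_position_stats(
        [position_stats(assign_reads(c, ex)) for c in control_reads]
    )
    pos = srd_table(rep_stats, ctrl_stats, alpha=alpha, min_reps=min_reps)
    return pos, exon_srd(pos, ex, window=window)
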