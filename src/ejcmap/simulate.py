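"""Synthetic genome, annotation and read-set generator with known EJC truth.

The generator emulates the data-generating process the analysis is built
for, at desk scale:

* a random-sequence genome carrying single-isoform gene models on both
  strands, with log-uniform per-gene expression weights;
* splicing-dependent EJC deposition: every first/internal exon of an
  expressed gene carries an EJC with probability ``deposition_prob``;
  last (and single) exons never do;
* eCLIP libraries: reverse-transcriptase truncation reads whose 5' end
  marks the crosslinked nucleotide. Crosslinks fall inside the EJC
  footprint with a positional preference centred on the canonical -27
  offset and a multiplicative bias toward uridines; footprints devoid of
  U crosslink at a reduced efficiency. A fraction of RTs read through,
  displacing the 5' end upstream of the footprint by a geometric tail;
* SMInput controls: uniform background fragments over expressed exons;
  eCLIP libraries also contain a background admixture;
* ipaRt libraries: protease-protected fragments spanning a fixed window
  upstream of the junction of each loaded exon, with small end jitter,
  plus the same background admixture (RIP backgrounds are mRNA-like);
* mRNA-seq controls: coverage proportional to expression and exon length.

All randomness flows from a single integer seed through fixed-purpose
child seeds, so identical configurations produce byte-identical outputs.
Reads are emitted as already-aligned BED6 records confined to single
exons; sequencing errors, splice-junction reads and PCR duplicates are
out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, classify_exons, exon_table, write_gtf
from .io import BED6_COLUMNS

__all__ = ["SimConfig", "SimTruth", "build_toy_genome", "simulate_eclip",
           "simulate_ipart", "simulate_all", "write_fasta", "write_truth"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed child-seed keys so each library's stream is independent of call order
_SEED_GENOME = 0
_SEED_TRUTH = 1
_SEED_ECLIP = 10
_SEED_SMINPUT = 20
_SEED_IPART = 30
_SEED_RNASEQ = 40


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Ranges are inclusive; relative-position intervals follow the
    -1 = junction-adjacent convention.
    """

    n_genes: int = 500
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (60, 600)
    intron_length: tuple[int, int] = (60, 200)
    gap_length: tuple[int, int] = (100, 300)
    expression: tuple[float, float] = (0.5, 50.0)  # log-uniform RPKM-like weights
    deposition_prob: float = 1.0
    crosslink_offset: int = -27
    crosslink_sd: float = 2.0  # nt, positional-preference kernel width
    footprint: tuple[int, int] = (-32, -23)
    u_weight: float = 10.0
    zero_u_efficiency: float = 0.25
    readthrough_prob: float = 0.15
    read_length: int = 35
    background_frac: float = 0.1
    ipart_fragment: tuple[int, int] = (-36, -10)
    ipart_jitter: int = 3
    n_eclip_reps: int = 3
    n_sminput: int = 2
    n_ipart_reps: int = 3
    n_rnaseq: int = 2
    eclip_depth: int = 120_000
    sminput_depth: int = 120_000
    ipart_depth: int = 120_000
    rnaseq_depth: int = 240_000
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deposition_prob", "readthrough_prob", "background_frac",
                     "zero_u_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.footprint
        if not (lo <= self.crosslink_offset <= hi <= -1):
            raise ValueError("crosslink_offset must lie within the footprint")
        if self.exon_length[0] < -self.footprint[0]:
            raise ValueError("minimum exon length shorter than the EJC footprint")
        if self.exon_length[0] < -self.ipart_fragment[0]:
            raise ValueError("minimum exon length shorter than the ipaRt fragment")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``exons``: one row per representative exon — exon_id, gene_id, cls,
    chrom, start, end, strand, length, expression_weight, loaded, u_count
    (T count in the EJC footprint on the sense strand).
    ``crosslinks``: exon_id, rel_pos, count — the multiset of crosslink
    positions actually drawn by the eCLIP generator (empty until then).
    """

    exons: pd.DataFrame
    crosslinks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["exon_id", "rel_pos", "count"])
    )

    def loaded_ids(self) -> set[str]:
        return set(self.exons.loc[self.exons["loaded"], "exon_id"])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_toy_genome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel], SimTruth]:
    """Generate genome sequence, gene models and the truth skeleton.

    Genes are laid out sequentially on one chromosome with intergenic
    gaps; strand is Bernoulli(1/2) per gene. Expression weights are
    log-uniform per gene and shared by its exons. EJC deposition is drawn
    per eligible (first/internal) exon with ``deposition_prob``.
    """
    g_rng = config.rng(_SEED_GENOME)
    t_rng = config.rng(_SEED_TRUTH)

    models: list[TranscriptModel] = []
    cursor = 0
    layout: list[tuple[int, int]] = []  # genomic exon intervals, build order
    for gi in range(config.n_genes):
        cursor += int(g_rng.integers(config.gap_length[0], config.gap_length[1] + 1))
        n_ex = int(g_rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if g_rng.random() < 0.5 else "-"
        exons = []
        for k in range(n_ex):
            if k:
                cursor += int(g_rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            length = int(g_rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length
        layout.extend(exons)
        if strand == "-":
            exons = exons[::-1]  # 5'->3' in transcript orientation
        gene_id = f"g{gi + 1:04d}"
        models.append(
            TranscriptModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1",
                            chrom=config.chrom, strand=strand, exons=tuple(exons))
        )
    genome = {config.chrom: _random_seq(g_rng, cursor + config.gap_length[1])}

    ex = exon_table(models)
    lo_w, hi_w = np.log(config.expression[0]), np.log(config.expression[1])
    gene_w = np.exp(t_rng.uniform(lo_w, hi_w, size=config.n_genes))
    w_by_gene = dict(zip((m.gene_id for m in models), gene_w))
    ex["expression_weight"] = ex["gene_id"].map(w_by_gene)

    eligible = ex["cls"].isin(["first", "internal"]).to_numpy()
    loaded = eligible & (t_rng.random(len(ex)) < config.deposition_prob)
    ex["loaded"] = loaded

    ex["u_count"] = [
        _footprint_u_count(genome[config.chrom], row, config.footprint)
        for row in ex.itertuples(index=False)
    ]
    return genome, models, SimTruth(exons=ex)


def _footprint_u_count(chrom_seq: str, exon_row, footprint: tuple[int, int]) -> int:
    """T count on the sense strand within the footprint window of one exon."""
    lo, hi = footprint
    if exon_row.length < -lo:
        return 0
    if exon_row.strand == "+":
        seq = chrom_seq[exon_row.end + lo : exon_row.end + hi + 1]
        return seq.count("T")
    seq = chrom_seq[exon_row.start - hi - 1 : exon_row.start - lo]
    return seq.count("A")  # A on plus strand is U on the minus-strand transcript


def _rel_to_genomic(start: np.ndarray, end: np.ndarray, plus: np.ndarray,
                    rel_lo: np.ndarray, rel_hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map inclusive relative intervals [rel_lo, rel_hi] to genomic half-open ones."""
    g_start = np.where(plus, end + rel_lo, start - rel_hi - 1)
    g_end = np.where(plus, end + rel_hi + 1, start - rel_lo)
    return g_start, g_end


def _reads_frame(config: SimConfig, ex_rows: pd.DataFrame, rel_lo: np.ndarray,
                 rel_hi: np.ndarray, name: str) -> pd.DataFrame:
    plus = ex_rows["strand"].to_numpy() == "+"
    g_start, g_end = _rel_to_genomic(ex_rows["start"].to_numpy(), ex_rows["end"].to_numpy(),
                                     plus, rel_lo, rel_hi)
    n = len(ex_rows)
    return pd.DataFrame(
        {
            "chrom": np.repeat(config.chrom, n),
            "start": g_start.astype(np.int64),
            "end": g_end.astype(np.int64),
            "name": [f"{name}_{i}" for i in range(n)],
            "score": np.zeros(n, dtype=np.int64),
            "strand": np.where(plus, "+", "-"),
        }
    )[BED6_COLUMNS]


def _sample_background(config: SimConfig, truth: SimTruth, n: int,
                       rng: np.random.Generator, name: str) -> pd.DataFrame:
    """Uniform fragments over expressed exonic positions (weight = expr x length)."""
    ex = truth.exons
    w = (ex["expression_weight"] * ex["length"]).to_numpy(dtype=float)
    if not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("no expressed genes to draw background reads from")
    counts = rng.multinomial(n, w / w.sum())
    idx = np.repeat(np.arange(len(ex)), counts)
    rows = ex.iloc[idx]
    L = rows["length"].to_numpy()
    rel5 = -rng.integers(1, L + 1)  # uniform in [-L, -1]
    rel3 = np.minimum(rel5 + config.read_length - 1, -1)
    return _reads_frame(config, rows, rel5, rel3, name)


def _footprint_weights(config: SimConfig, sense_window: str) -> np.ndarray:
    """Per-position crosslink propensity over the footprint of one exon.

    A Gaussian positional kernel centred on the canonical offset models the
    EJC's preferred RNA contact; a multiplicative ``u_weight`` models the
    photo-crosslinking preference for uridines.
    """
    lo, hi = config.footprint
    d = np.arange(lo, hi + 1, dtype=float)
    kernel = np.exp(-0.5 * ((d - config.crosslink_offset) / config.crosslink_sd) ** 2)
    u = np.array([config.u_weight if b == "T" else 1.0 for b in sense_window])
    return kernel * u


def _footprint_sense(genome: dict[str, str], row, footprint: tuple[int, int]) -> str:
    lo, hi = footprint
    chrom_seq = genome[row.chrom]
    if row.strand == "+":
        return chrom_seq[row.end + lo : row.end + hi + 1]
    comp = str.maketrans("ACGT", "TGCA")
    seq = chrom_seq[row.start - hi - 1 : row.start - lo]
    return seq.translate(comp)[::-1]


def simulate_eclip(config: SimConfig, genome: dict[str, str],
                   truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Generate eCLIP replicate and SMInput read sets.

    Returns ``{"eclip_1": df, ..., "sminput_1": df, ...}`` (BED6 frames).
    Crosslink positions drawn for loaded exons are accumulated into
    ``truth.crosslinks``.
    """
    ex = truth.exons
    loaded = ex.loc[ex["loaded"]].reset_index(drop=True)
    if len(ex) == 0 or ex["expression_weight"].sum() <= 0:
        raise ValueError("no expressed genes")

    lo, hi = config.footprint
    fp_w = np.stack([
        _footprint_weights(config, _footprint_sense(genome, row, config.footprint))
        for row in loaded.itertuples(index=False)
    ]) if len(loaded) else np.zeros((0, hi - lo + 1))
    kernel_mass = np.exp(
        -0.5 * ((np.arange(lo, hi + 1) - config.crosslink_offset) / config.crosslink_sd) ** 2
    ).sum()
    capture = fp_w.sum(axis=1) / kernel_mass
    zero_u = loaded["u_count"].to_numpy() == 0
    capture = capture * np.where(zero_u, config.zero_u_efficiency, 1.0)
    exon_weight = loaded["expression_weight"].to_numpy() * capture

    libs: dict[str, pd.DataFrame] = {}
    xlink_tally: dict[str, np.ndarray] = {}

    no_signal = len(loaded) == 0 or exon_weight.sum() <= 0
    for rep in range(config.n_eclip_reps):
        rng = config.rng(_SEED_ECLIP + rep)
        n_bg = int(round(config.background_frac * config.eclip_depth))
        n_sig = config.eclip_depth - n_bg
        if no_signal:  # nothing deposited: the library is pure background
            n_bg, n_sig = config.eclip_depth, 0

        per_exon = (rng.multinomial(n_sig, exon_weight / exon_weight.sum())
                    if n_sig else np.zeros(len(loaded), dtype=np.int64))
        rel5_parts, row_parts = [], []
        for i in np.nonzero(per_exon)[0]:
            p = fp_w[i] / fp_w[i].sum()
            pos_counts = rng.multinomial(per_exon[i], p)
            rel = np.repeat(np.arange(lo, hi + 1), pos_counts)
            eid = loaded.at[i, "exon_id"]
            tally = xlink_tally.setdefault(eid, np.zeros(hi - lo + 1, dtype=np.int64))
            tally += pos_counts
            rel5_parts.append(rel)
            row_parts.append(np.full(len(rel), i))
        rel5 = np.concatenate(rel5_parts) if rel5_parts else np.array([], dtype=int)
        rows_i = np.concatenate(row_parts) if row_parts else np.array([], dtype=int)
        rows = loaded.iloc[rows_i]

        # readthrough: RT bypasses the crosslink, placing the 5' end a
        # geometric-tailed overshoot upstream of it
        thru = rng.random(len(rel5)) < config.readthrough_prob
        overshoot = rng.geometric(0.5, size=len(rel5))
        rel5 = np.where(thru, rel5 - overshoot, rel5)
        rel5 = np.maximum(rel5, -rows["length"].to_numpy())
        rel3 = np.minimum(rel5 + config.read_length - 1, -1)
        sig = _reads_frame(config, rows, rel5, rel3, f"eclip{rep + 1}")

        bg = _sample_background(config, truth, n_bg, rng, f"eclip{rep + 1}bg")
        libs[f"eclip_{rep + 1}"] = pd.concat([sig, bg], ignore_index=True)

    for j in range(config.n_sminput):
        rng = config.rng(_SEED_SMINPUT + j)
        libs[f"sminput_{j + 1}"] = _sample_background(
            config, truth, config.sminput_depth, rng, f"smin{j + 1}"
        )

    if xlink_tally:
        truth.crosslinks = pd.DataFrame(
            [
                (eid, int(d), int(c))
                for eid, tally in sorted(xlink_tally.items())
                for d, c in zip(range(lo, hi + 1), tally)
                if c > 0
            ],
            columns=["exon_id", "rel_pos", "count"],
        )
    return libs


def simulate_ipart(config: SimConfig, genome: dict[str, str],
                   truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Generate ipaRt replicate and mRNA-seq control read sets.

    ipaRt reads are protected fragments spanning ``ipart_fragment`` around
    each loaded exon's junction (uniform +/- ``ipart_jitter`` on each end),
    with an mRNA-like background admixture; mRNA-seq reads are uniform
    over exonic positions with counts proportional to expression x length.
    """
    ex = truth.exons
    loaded = ex.loc[ex["loaded"]].reset_index(drop=True)
    if len(ex) == 0 or ex["expression_weight"].sum() <= 0:
        raise ValueError("no expressed genes")
    w = loaded["expression_weight"].to_numpy(dtype=float)

    a, b = config.ipart_fragment
    libs: dict[str, pd.DataFrame] = {}
    for rep in range(config.n_ipart_reps):
        rng = config.rng(_SEED_IPART + rep)
        n_bg = int(round(config.background_frac * config.ipart_depth))
        n_sig = config.ipart_depth - n_bg

        per_exon = rng.multinomial(n_sig, w / w.sum()) if len(loaded) else np.array([], int)
        idx = np.repeat(np.arange(len(loaded)), per_exon)
        rows = loaded.iloc[idx]
        L = rows["length"].to_numpy()
        j = config.ipart_jitter
        lo_j = rng.integers(-j, j + 1, size=len(rows)) if j else np.zeros(len(rows), int)
        hi_j = rng.integers(-j, j + 1, size=len(rows)) if j else np.zeros(len(rows), int)
        rel_lo = np.maximum(a + lo_j, -L)
        rel_hi = np.minimum(b + hi_j, -1)
        rel_hi = np.maximum(rel_hi, rel_lo)  # keep at least 1 nt after clamping
        sig = _reads_frame(config, rows, rel_lo, rel_hi, f"ipart{rep + 1}")

        bg = _sample_background(config, truth, n_bg, rng, f"ipart{rep + 1}bg")
        libs[f"ipart_{rep + 1}"] = pd.concat([sig, bg], ignore_index=True)

    for k in range(config.n_rnaseq):
        rng = config.rng(_SEED_RNASEQ + k)
        libs[f"rnaseq_{k + 1}"] = _sample_background(
            config, truth, config.rnaseq_depth, rng, f"rna{k + 1}"
        )
    return libs


def simulate_all(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel],
                                             SimTruth, dict[str, pd.DataFrame]]:
    """Run the full generator: genome, annotation, truth and every library."""
    genome, models, truth = build_toy_genome(config)
    libs = simulate_eclip(config, genome, truth)
    libs.update(simulate_ipart(config, genome, truth))
    return genome, models, truth, libs


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: SimTruth, exon_path: str | Path,
                crosslink_path: str | Path | None = None) -> None:
    truth.exons.to_csv(exon_path, sep="\t", index=False)
    if crosslink_path is not None:
        truth.crosslinks.to_csv(crosslink_path, sep="\t", index=False)
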