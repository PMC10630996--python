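"""Gene annotation handling and the exon-relative coordinate system.

All genomic coordinates are 0-based half-open (BED convention); the 1-based
closed coordinates of a GTF are converted on input. Positions within an exon
are expressed relative to the downstream (3', junction-side) boundary of the
exon in transcript orientation: the junction-adjacent nucleotide is -1, the
5'-most nucleotide of an exon of length L is -L. All downstream statistics
(meta-exon profiles, stop rates, coverage windows) live in this coordinate
system, which makes plus- and minus-strand exons directly comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "TranscriptModel",
    "ExonRecord",
    "GenomeSequence",
    "parse_gtf",
    "select_representative",
    "representative_transcripts",
    "classify_exons",
    "relative_position",
    "count_uridines",
    "load_genome",
    "write_gtf",
    "exon_table",
    "U_COUNT_WINDOW",
]

# 7-nt uridine-count window centred on the canonical crosslink at -27.
U_COUNT_WINDOW = (-30, -24)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered chain of exons on one strand.

    ``exons`` holds (start, end) genomic intervals, 0-based half-open,
    ordered 5'->3' in transcript orientation (descending genomic order on
    the minus strand).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon interval [{s},{e})")
        starts = [s for s, _ in self.exons]
        ordered = sorted(starts, reverse=self.strand == "-")
        if starts != ordered:
            raise ValueError(f"{self.transcript_id}: exons not in transcript orientation")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class ExonRecord:
    """A strand-aware exon with its positional class within the transcript."""

    exon_id: str
    gene_id: str
    index: int  # 1-based position in transcript order
    cls: str  # first | internal | last | single
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


#: chrom -> sequence string; any Mapping works, including a pyfaidx Fasta.
GenomeSequence = Mapping[str, str]


class _FastaView:
    """Mapping view over a pyfaidx Fasta returning plain uppercase strings."""

    def __init__(self, fasta: Fasta):
        self._fasta = fasta

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self._fasta:
            raise KeyError(chrom)
        return str(self._fasta[chrom][:]).upper()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def keys(self):
        return self._fasta.keys()


def load_genome(path: str | Path) -> GenomeSequence:
    """Open an (indexed) FASTA as a chrom -> sequence mapping."""
    return _FastaView(Fasta(str(path), sequence_always_upper=True))


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into transcript models.

    Only ``exon`` features are considered; each must carry ``gene_id`` and
    ``transcript_id`` attributes. GTF 1-based closed intervals are converted
    to 0-based half-open. Exons are normalised to transcript orientation.

    Raises
    ------
    ValueError
        On a malformed line (fewer than 9 tab-separated fields), naming the
        line number. Exon features lacking a transcript_id are skipped.
    """
    records: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                continue  # rejected record: exon without identifiers
            rec = records.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
            )
            rec["exons"].append((int(start) - 1, int(end)))

    models = []
    for tid, rec in records.items():
        exons = sorted(rec["exons"], reverse=rec["strand"] == "-")
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(exons),
            )
        )
    return models


def select_representative(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Pick the representative isoform of one gene.

    Most exons wins; ties broken by larger summed exonic length; remaining
    ties broken by lexicographically smallest transcript_id, so the choice
    is deterministic under any input order.
    """
    if not transcripts:
        raise ValueError("select_representative: empty transcript list")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"select_representative: mixed gene_ids {sorted(gene_ids)}")
    return min(
        transcripts,
        key=lambda t: (-t.n_exons, -t.exonic_length, t.transcript_id),
    )


def representative_transcripts(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Reduce a transcript list to one representative per gene (sorted by gene_id)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    return [select_representative(ts) for _, ts in sorted(by_gene.items())]


def classify_exons(model: TranscriptModel) -> list[ExonRecord]:
    """Assign each exon of a transcript its positional class.

    Multi-exon transcripts yield first / internal / last; a single-exon
    transcript yields the degenerate class ``single`` (no splicing, hence
    never an EJC deposition target).
    """
    n = model.n_exons
    out = []
    for i, (s, e) in enumerate(model.exons, start=1):
        if n == 1:
            cls = "single"
        elif i == 1:
            cls = "first"
        elif i == n:
            cls = "last"
        else:
            cls = "internal"
        out.append(
            ExonRecord(
                exon_id=f"{model.gene_id}:{i}",
                gene_id=model.gene_id,
                index=i,
                cls=cls,
                chrom=model.chrom,
                start=s,
                end=e,
                strand=model.strand,
            )
        )
    return out


def relative_position(g: int, exon: ExonRecord) -> int:
    """Offset of genomic position ``g`` from the exon's 3' (junction-side) end.

    The junction-adjacent base is -1 and the 5'-most base is -length.
    Plus strand: ``g - end``; minus strand: ``start - g - 1``.
    """
    if not exon.start <= g < exon.end:
        raise ValueError(f"position {g} outside exon {exon.exon_id} [{exon.start},{exon.end})")
    if exon.strand == "+":
        return g - exon.end
    return exon.start - g - 1


def sense_sequence(exon: ExonRecord, genome: GenomeSequence) -> str:
    """Transcript-sense sequence of the exon (reverse-complemented for minus strand)."""
    if exon.chrom not in genome:
        raise KeyError(f"chromosome {exon.chrom} missing from genome")
    seq = genome[exon.chrom][exon.start : exon.end]
    return reverse_complement(seq) if exon.strand == "-" else seq.upper()


def count_uridines(
    exon: ExonRecord,
    genome: GenomeSequence,
    window: tuple[int, int] = U_COUNT_WINDOW,
) -> int | None:
    """Count U (T on the sense strand) within a relative-position window.

    ``window`` is an inclusive interval of negative relative positions,
    default the 7-nt window around the canonical -27 crosslink. Returns
    None for exons too short to contain the window.
    """
    lo, hi = window
    if lo > hi or hi > -1:
        raise ValueError(f"invalid relative window {window}")
    if exon.length < -lo:
        return None
    seq = sense_sequence(exon, genome)
    # sense index of relative position d is length + d
    return seq[exon.length + lo : exon.length + hi + 1].count("T")


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "ejcmap") -> None:
    """Write transcript models as GTF exon features (1-based closed, ascending)."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in sorted(m.exons):
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def exon_table(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Flat per-exon table over representative transcripts.

    Columns: exon_id, gene_id, index, cls, chrom, start, end, strand, length.
    """
    rows = []
    for m in models:
        for rec in classify_exons(m):
            rows.append(
                (
                    rec.exon_id,
                    rec.gene_id,
                    rec.index,
                    rec.cls,
                    rec.chrom,
                    rec.start,
                    rec.end,
                    rec.strand,
                    rec.length,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "exon_id",
            "gene_id",
            "index",
            "cls",
            "chrom",
            "start",
            "end",
            "strand",
            "length",
        ],
    )
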