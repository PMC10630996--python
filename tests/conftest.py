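"""Shared fixtures: seeded synthetic experiments at the study's problem sizes.

All simulated data are generated at test time; the session-scoped
fixtures are reused across test modules so each experiment is simulated
and analysed once.
"""

from __future__ import annotations

import pandas as pd
import pytest

from ejcmap import exon_table
from ejcmap.annotation import ExonRecord
from ejcmap.simulate import SimConfig, simulate_all, simulate_ipart, build_toy_genome
from ejcmap.srd import srd_pipeline
from ejcmap.ipart import ipart_pipeline


def make_exon(start: int, end: int, strand: str = "+", exon_id: str = "g:1",
              cls: str = "internal", index: int = 2) -> ExonRecord:
    return ExonRecord(exon_id=exon_id, gene_id=exon_id.split(":")[0], index=index,
                      cls=cls, chrom="chr1", start=start, end=end, strand=strand)


def bed(rows: list[tuple], chrom: str = "chr1") -> pd.DataFrame:
    """Build a BED6 frame from (start, end, strand) tuples."""
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(rows),
            "start": [r[0] for r in rows],
            "end": [r[1] for r in rows],
            "name": [f"r{i}" for i in range(len(rows))],
            "score": [0] * len(rows),
            "strand": [r[2] for r in rows],
        }
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: ~500 genes, universal deposition."""
    cfg = SimConfig(seed=11)
    genome, models, truth, libs = simulate_all(cfg)
    return cfg, genome, models, truth, libs


@pytest.fixture(scope="session")
def default_exons(default_sim):
    _, _, models, _, _ = default_sim
    return exon_table(models)


@pytest.fixture(scope="session")
def default_srd(default_sim, default_exons):
    cfg, _, _, _, libs = default_sim
    reps = [libs[f"eclip_{i + 1}"] for i in range(cfg.n_eclip_reps)]
    ctrls = [libs[f"sminput_{j + 1}"] for j in range(cfg.n_sminput)]
    return srd_pipeline(reps, ctrls, default_exons)


@pytest.fixture(scope="session")
def default_ipart(default_sim, default_exons):
    cfg, _, _, _, libs = default_sim
    reps = [libs[f"ipart_{i + 1}"] for i in range(cfg.n_ipart_reps)]
    rnas = [libs[f"rnaseq_{k + 1}"] for k in range(cfg.n_rnaseq)]
    return ipart_pipeline(reps, rnas, default_exons)


@pytest.fixture(scope="session")
def nojitter_ipart_sim():
    """Default geometry with zero fragment-end jitter (midpoint recovery)."""
    cfg = SimConfig(seed=11, ipart_jitter=0)
    genome, models, truth = build_toy_genome(cfg)
    libs = simulate_ipart(cfg, genome, truth)
    return cfg, exon_table(models), libs


@pytest.fixture(scope="session")
def half_deposition_sim():
    """Deposition on a random half of eligible exons (recovery conditions)."""
    cfg = SimConfig(seed=13, deposition_prob=0.5)
    genome, models, truth, libs = simulate_all(cfg)
    return cfg, exon_table(models), truth, libs


@pytest.fixture(scope="session")
def bias_sim():
    """Larger problem (3000 genes, proportional depth) for bias stratification."""
    cfg = SimConfig(seed=17, n_genes=3000, eclip_depth=720_000,
                    sminput_depth=720_000, ipart_depth=720_000,
                    rnaseq_depth=1_440_000)
    genome, models, truth, libs = simulate_all(cfg)
    return cfg, exon_table(models), truth, libs
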