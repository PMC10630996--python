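# ejcmap

Exon-level mapping of **exon junction complex (EJC)** deposition from two
complementary sequencing readouts, with a fully seeded synthetic benchmark.

The EJC is loaded by the spliceosome ~27 nt upstream of every exon–exon
junction, independent of sequence. Whether it really sits on *all*
junctions is hard to answer from any single assay: eCLIP (UV crosslinking,
read 5′ ends mark reverse-transcriptase truncation at the crosslinked
nucleotide) is highly specific but misses sites through inefficient,
uridine-biased crosslinking; RIP-style protein–protein crosslinking data
("ipaRt") read out protected-fragment coverage with no UV bias but less
positional precision. `ejcmap` implements both exon-level detection routes
and their integration:

* **Stop Rate Difference (SRD)** for eCLIP. At each exonic position the
  stop rate is `arrests / (arrests + readthroughs)`, where an arrest is a
  read 5′ end at the position and a readthrough is a read covering it from
  further upstream. Each replicate is tested per position against the
  pooled size-matched input (SMInput) with a 2×2 Pearson χ² (1 df, no
  continuity correction), gated on the replicate rate exceeding the
  control's. With ≥2 of 3 replicates significant (p < 0.05), the position's
  SRD is the mean replicate stop rate minus the control stop rate, and the
  exon score is the mean SRD over significant positions in the canonical
  deposition window **[−32, −23]** (−1 = junction-adjacent base).
* **ipaRt enrichment score**. Per exon, the median of nonzero per-position
  coverage in the window **[−36, −10]** is taken per library; the score is
  `mean(ipaRt medians) / mean(mRNA-seq medians)`. Because a last exon has
  no downstream splicing event and can never carry an EJC, the **95th
  percentile of last-exon ratios** is the empirical decision threshold;
  exons with window coverage in every library and a ratio strictly above
  it are called loaded.
* **Integration**: per-exon RPKM and equal-count expression deciles,
  uridine-count strata (7-nt window around −27), both/one/neither
  classification over commonly expressed genes, and slop-extended (±5 nt)
  strand-aware Jaccard agreement between peak sets.
* **Synthetic data**: a seeded generator (`ejcmap.simulate`) that emits a
  toy genome, one representative transcript per gene, and eCLIP/SMInput/
  ipaRt/mRNA-seq read sets (BED6) with per-exon ground truth — deposition
  on first/internal exons only, crosslinks around −27 with uridine bias,
  geometric readthrough, protected fragments, expression-proportional
  coverage — so every stage is testable end to end without downloads.

## Worked example

```bash
python examples/03_srd_detection.py
```

```
1771 significant positions; 80% inside the [-32,-23] window

detection by exon class (rate, detected, total):
          mean  sum  size
cls
first     0.66   99   150
internal  0.65  294   452
last      0.00    0   150
```

Significant arrest positions concentrate in the deposition window; about
two thirds of the (universally loaded) first/internal exons are recovered
at this sequencing depth — detection is capped by expression level and by
uridine availability in the crosslinking window, exactly the biases the
integration stage quantifies — while the last-exon rate, the empirical
false-positive level, is ~0. `examples/04_ipart_scoring.py` shows the
coverage-based route calling ~92% of the same exons loaded with a
calibrated threshold, and `examples/05_integration.py` combines both,
with the union dominating either method in every expression bin.

The same analyses are available as subcommands of a thin CLI
(`ejcmap simulate | metaexon | srd | ipart | integrate | jaccard |
run-all`); `ejcmap run-all --outdir out --seed 1` runs the whole synthetic
demonstration and writes a machine-readable `summary.json`.

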