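"""Stop Rate Difference: exon-level EJC detection from eCLIP truncations.

Per position, each replicate's stop rate (arrests / arrests+throughs) is
chi-square-tested against the pooled SMInput; positions significant in
at least 2 of 3 replicates contribute their SRD (mean replicate rate
minus control rate) to the exon score, averaged over the [-32,-23]
deposition window.
"""

from ejcmap import SimConfig, exon_table, simulate_all
from ejcmap.srd import srd_pipeline

cfg = SimConfig(seed=1, n_genes=150, eclip_depth=40_000, sminput_depth=40_000,
                ipart_depth=40_000, rnaseq_depth=80_000)
_, models, truth, libs = simulate_all(cfg)
exons = exon_table(models)

positions, calls = srd_pipeline(
    [libs[f"eclip_{i}"] for i in (1, 2, 3)],
    [libs[f"sminput_{j}"] for j in (1, 2)],
    exons,
)

sig = positions[positions["significant"]]
print(f"{len(sig)} significant positions; "
      f"{sig['position'].between(-32, -23).mean():.0%} inside the [-32,-23] window")

by_cls = calls.groupby("cls")["detected"].agg(["mean", "sum", "size"])
print("\ndetection by exon class (rate, detected, total):")
print(by_cls.round(3).to_string())
print("\nLast exons are never spliced downstream, so the near-zero rate "
      "there is the method's empirical false-positive level; the detected "
      "first/internal exons are true EJC positives, capped by expression "
      "and uridine-dependent crosslinking efficiency.")
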