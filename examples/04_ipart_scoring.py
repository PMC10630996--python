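"""ipaRt enrichment scoring with a last-exon-calibrated threshold.

Each exon's score is the ratio of the mean ipaRt window-median coverage
to the mean mRNA-seq window-median coverage in [-36,-10]. Because last
exons cannot carry an EJC, the 95th percentile of their ratios is the
empirical decision threshold.
"""

from ejcmap import SimConfig, exon_table, simulate_all
from ejcmap.ipart import ipart_pipeline

cfg = SimConfig(seed=1, n_genes=150, eclip_depth=40_000, sminput_depth=40_000,
                ipart_depth=40_000, rnaseq_depth=80_000)
_, models, truth, libs = simulate_all(cfg)
exons = exon_table(models)

calls, calib = ipart_pipeline(
    [libs[f"ipart_{i}"] for i in (1, 2, 3)],
    [libs[f"rnaseq_{k}"] for k in (1, 2)],
    exons,
)

print(f"threshold = {calib.threshold:.3f} "
      f"(95th percentile of {len(calib.calibration_set)} last-exon ratios)")
det = calls[calls["consistently_detected"]]
print(f"{len(det)}/{len(calls)} exons consistently detected "
      "(window coverage in all 3 IPs and both mRNA-seq controls)")
print("\nloaded-call rate by exon class:")
print(calls.groupby("cls")["loaded"].mean().round(3).to_string())
print("\nLoaded first/internal exons have window coverage far above their "
      "mRNA abundance; last exons, carrying only background, almost never "
      "cross their own 95th-percentile threshold.")
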