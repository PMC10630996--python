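"""Generate a synthetic EJC mapping experiment with known ground truth.

Builds a toy genome with ~150 spliced genes, deposits an EJC on every
first/internal exon, and emits eCLIP + SMInput, ipaRt + mRNA-seq read
sets as BED6. The truth table records, per exon, its class, expression
weight, deposition status and footprint uridine count — everything the
recovery analyses below are benchmarked against.
"""

from ejcmap import SimConfig, exon_table, simulate_all

cfg = SimConfig(seed=1, n_genes=150, eclip_depth=40_000, sminput_depth=40_000,
                ipart_depth=40_000, rnaseq_depth=80_000)
genome, models, truth, libs = simulate_all(cfg)

exons = exon_table(models)
print(f"genome: {sum(len(s) for s in genome.values()):,} nt, "
      f"{len(models)} genes, {len(exons)} exons")
print("exon classes:", exons["cls"].value_counts().to_dict())
print("libraries:", {name: len(reads) for name, reads in libs.items()})

loaded = truth.exons["loaded"].sum()
eligible = truth.exons["cls"].isin(["first", "internal"]).sum()
print(f"EJC deposited on {loaded}/{eligible} eligible (first/internal) exons; "
      "last exons never carry one — they are the empirical null.")
print("crosslink positions drawn (top 5):")
print(truth.crosslinks.groupby("rel_pos")["count"].sum().nlargest(5).to_string())
# The largest tallies sit at the canonical -27 offset: the generator
# crosslinks preferentially at the EJC's RNA contact point.
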