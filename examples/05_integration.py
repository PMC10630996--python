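"""Cross-method integration: expression deciles, combined calls, Jaccard.

Combines the truncation-based (SRD) and coverage-based (ipaRt) calls
over the shared exon universe, stratifies detection by expression, and
demonstrates the slop-extended Jaccard agreement between peak sets.
"""

import pandas as pd

from ejcmap import SimConfig, exon_table, simulate_all
from ejcmap.integrate import combine_calls, expression_bins, expression_table, jaccard_peaks
from ejcmap.ipart import ipart_pipeline
from ejcmap.srd import srd_pipeline

cfg = SimConfig(seed=1, n_genes=150, eclip_depth=40_000, sminput_depth=40_000,
                ipart_depth=40_000, rnaseq_depth=80_000)
_, models, truth, libs = simulate_all(cfg)
exons = exon_table(models)
rnas = [libs[f"rnaseq_{k}"] for k in (1, 2)]

_, srd_calls = srd_pipeline([libs[f"eclip_{i}"] for i in (1, 2, 3)],
                            [libs[f"sminput_{j}"] for j in (1, 2)], exons)
ipart_calls, _ = ipart_pipeline([libs[f"ipart_{i}"] for i in (1, 2, 3)], rnas, exons)

combined = combine_calls(
    dict(zip(srd_calls["exon_id"], srd_calls["detected"])),
    dict(zip(ipart_calls["exon_id"], ipart_calls["loaded"])),
    set(exons["exon_id"]), exons,
)
print("combined classification:", combined["combined"].value_counts().to_dict())

expr = expression_table(rnas, exons).set_index("exon_id")
fi = exons.loc[exons["cls"].isin(["first", "internal"]), "exon_id"]
dec = expression_bins(expr.loc[fi, "rpkm"], k=5)
m = combined.set_index("exon_id").loc[fi]
m["bin"] = dec
g = m.groupby("bin")[["eclip_detected", "ipart_loaded", "union_detected"]].mean()
print("\ndetection rate per expression quintile (eCLIP / ipaRt / union):")
print(g.round(2).to_string())
print("\nThe union dominates either method in every bin: the two readouts "
      "miss different exons, so their combination approaches the truth "
      "(here: universal deposition on first/internal exons).")

# peak-set agreement: compare the exon windows each method detected
def peaks_of(ids):
    sub = exons[exons["exon_id"].isin(ids)]
    plus = sub["strand"] == "+"
    return pd.DataFrame({
        "chrom": sub["chrom"],
        "start": sub["end"].where(plus, sub["start"]) - 32 * plus - 9 * (~plus),
        "end": sub["end"].where(plus, sub["start"]) - 22 * plus + 33 * (~plus),
        "name": sub["exon_id"], "score": 0, "strand": sub["strand"],
    })

a = peaks_of(set(srd_calls.loc[srd_calls["detected"], "exon_id"]))
b = peaks_of(set(ipart_calls.loc[ipart_calls["loaded"], "exon_id"]))
inter, union, j = jaccard_peaks(a, b, slop=5)
print(f"\npeak agreement between the two methods: |A∩B|={inter}, |A∪B|={union}, "
      f"Jaccard={j:.2f}")
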