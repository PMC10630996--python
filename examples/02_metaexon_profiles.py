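"""Meta-exon profiles: where does the signal sit relative to the junction?

The eCLIP profile uses read 5' ends (RT truncation sites); the ipaRt
profile uses read midpoints (centre of the protected fragment). Both are
normalized by the number of exons long enough to contain each position
and by library size.
"""

import pandas as pd

from ejcmap import SimConfig, exon_table, simulate_all
from ejcmap.profiles import fiveprime_profile, midpoint_profile, peak_position

cfg = SimConfig(seed=1, n_genes=150, eclip_depth=40_000, sminput_depth=40_000,
                ipart_depth=40_000, rnaseq_depth=80_000)
_, models, _, libs = simulate_all(cfg)
exons = exon_table(models)

eclip = pd.concat([libs[f"eclip_{i}"] for i in (1, 2, 3)], ignore_index=True)
p5 = fiveprime_profile(eclip, exons)
print(f"eCLIP 5'-end profile: peak at {peak_position(p5)} "
      f"({p5.n_reads_used:,} reads used)")

smin = fiveprime_profile(libs["sminput_1"], exons)
print(f"SMInput control profile: flat background, max/min signal ratio "
      f"{smin.table.query('-50 <= position <= -1')['signal'].pipe(lambda s: s.max() / s.min()):.2f} "
      "over [-50,-1]")

ipart = pd.concat([libs[f"ipart_{i}"] for i in (1, 2, 3)], ignore_index=True)
pm = midpoint_profile(ipart, exons)
print(f"ipaRt midpoint profile: peak at {peak_position(pm)}")
print("The truncation peak (-27) marks the crosslinked nucleotide; the "
      "fragment-midpoint peak (-23) marks the centre of the protected "
      "window — the same complex seen through two different readouts.")
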