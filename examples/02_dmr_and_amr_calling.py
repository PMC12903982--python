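"""Call DMRs on pooled window counts and AMRs on a carrier methylome.

DMRs: each 1-kb window's pooled (methylated, total) counts are compared
between conditions with an exact two-sided test; BH-adjusted q-values and
context-specific effect-size thresholds decide the calls (CG needs
|delta freqC| >= 0.20 and q < 0.05).

AMRs: 100-bp windows with freqC > 0.2 lying >= 90% inside an InDel's
variant-sequence span are methylation carried by the variant itself.
"""

import numpy as np
import pandas as pd

from svcascade import GenomicInterval, SVRecord, call_amrs, call_dmrs

rng = np.random.default_rng(4)
n = 2000
levels_a = rng.uniform(0.05, 0.4, n)
levels_b = levels_a.copy()
planted = rng.choice(n, 60, replace=False)
levels_b[planted] += 0.4                      # hyper-methylated in condition B

starts = np.arange(n) * 1000
total_a = rng.poisson(12, (n, 6)).sum(axis=1)   # 3 replicates x 2 sites x ~12x
total_b = rng.poisson(12, (n, 6)).sum(axis=1)
windows_a = pd.DataFrame({"chrom": "chrA01", "start": starts, "end": starts + 1000,
                          "meth": rng.binomial(total_a, levels_a), "total": total_a})
windows_b = pd.DataFrame({"chrom": "chrA01", "start": starts, "end": starts + 1000,
                          "meth": rng.binomial(total_b, levels_b), "total": total_b})
for df in (windows_a, windows_b):
    df["freqc"] = df["meth"] / df["total"]
    df["context"] = "CG"

dmrs = call_dmrs(windows_a, windows_b, "CG")
recovered = len(set(dmrs["start"]) & set(starts[planted]))
print(f"CG-DMRs called: {len(dmrs)} of {len(planted)} planted "
      f"(sensitivity {recovered / len(planted):.2f}; "
      f"{len(dmrs) - recovered} calls outside the planted set)")

# --- AMR detection on a noiseless carrier methylome
insertion = SVRecord("ins1", "INS", GenomicInterval("chrA01", 50_000, 50_001),
                     length=1200)
win_starts = np.arange(49_000, 53_000, 100)
freqc = np.where((win_starts >= 50_000) & (win_starts + 100 <= 51_200), 0.7, 0.05)
windows100 = pd.DataFrame({"chrom": "chrA01", "start": win_starts,
                           "end": win_starts + 100, "freqc": freqc})
amrs = call_amrs(windows100, [insertion])
print(f"AMR windows inside the 1.2-kb insertion span: {len(amrs)} "
      f"(each fully methylated window the inserted sequence carries)")
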