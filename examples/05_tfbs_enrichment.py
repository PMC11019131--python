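"""Promoter TFBS enrichment: recover a planted motif among decoys.

Plants one copy of a TGACGTCA-like motif in each of 50 "down-regulated"
promoters, scans those against 5,000 background promoters with a library of
21 PWMs (the planted one plus 20 random decoys), and ranks factors by the
adjusted fold enrichment FE_adj — the 99%-CI lower bound of the site-
frequency odds ratio. The planted factor should rank first and be the only
significant one; decoys hover at FE_adj < 1.
"""

import numpy as np
import pandas as pd

from agesplit import synthetic, tfbs

rng = np.random.default_rng(7)
planted_pwm = tfbs.consensus_pwm("M_PLANT", "PLANTTF", "TGACGTCA", strength=50)
decoys = [
    tfbs.random_pwm(f"M{i:03d}", f"TF{i:03d}", int(rng.integers(6, 12)), rng)
    for i in range(20)
]
library = tfbs.PWMSet([planted_pwm] + decoys)

genes = [f"G{i:05d}" for i in range(6050)]
truth = pd.DataFrame(
    {"effect_class": ["primary_down"] * 50 + ["null"] * 6000}, index=genes
)
truth["motif_planted"] = False
promoters, sites = synthetic.simulate_promoters(
    truth, planted_pwm, length=1000, seed=7, planting_rate=1.0
)
print(f"{len(sites)} motif instances planted in 50 foreground promoters")

foreground = synthetic.PromoterSet(
    {g: promoters.sequences[g] for g in genes[:50]}, "foreground"
)
pool = synthetic.PromoterSet(
    {g: promoters.sequences[g] for g in genes[50:]}, "background_pool"
)
background = tfbs.sample_background(pool, n=5000, seed=7)

records = tfbs.enrichment_scan(library, foreground, background)
final = tfbs.collapse_and_filter(records)

cols = ["tf_name", "FE_adj_freq", "FE_adj_prom", "binom_p", "fdr", "significant"]
print("\ntop five factors by FE_adj (site-frequency variant):")
print(final[cols].head(5).to_string(index=False))
print(f"\nplanted factor rank: "
      f"{1 + int(np.flatnonzero(final['tf_name'] == 'PLANTTF')[0])}")
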