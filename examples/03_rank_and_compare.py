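"""Rank hospitals under the weighted network vs discrete HSAs.

Fits both models on the same synthetic cohort and compares the fitted
between-hospital variances and the posterior hospital rankings: discrete
catchments attenuate variance and drop hospitals that never win a plurality.
"""

import numpy as np

import hsanet as hn

result = hn.run_pipeline(hn.RunConfig(
    out_dir="scratch/example_compare", seed=3,
    sim=hn.SimConfig(), burnin=1000, iterations=4000, make_plots=True,
))

m = result["metrics"]
print(f"weighted-network sigma2: {m['mm']['sigma2_mean']:.3f} "
      f"(MRR {m['mm']['mrr']:.2f})")
print(f"discrete-HSA sigma2:     {m['hsa']['sigma2_mean']:.3f} "
      f"(MRR {m['hsa']['mrr']:.2f})")
print(f"variance ratio network:HSA = {m['comparison']['ratio']:.2f}")
print(f"rank correlation (shared hospitals): "
      f"rho = {m['comparison']['spearman_rho']:.2f}")

rank = result["ranking_mm"]
flagged = rank[rank["significant"]]
print(f"{len(flagged)} hospitals credibly above/below average "
      f"(95% interval excludes 0):")
print(flagged[["median", "lower", "upper", "rank"]].round(3).to_string())
print()
print("A ratio above 1 means the discrete catchments lose between-hospital")
print("signal; the caterpillar plot is in scratch/example_compare/.")
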