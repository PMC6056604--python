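"""Build patient-flow weights and discrete HSAs from admission records.

Generates a small synthetic admission table, merges transfer episodes,
computes each area's flow profile (the multiple-membership weights), assigns
every area to its plurality hospital, and prints the catchment descriptives.
"""

import hsanet as hn

admissions, persons, hospitals, _ = hn.generate_system(
    hn.SimConfig(n_areas=30, n_hospitals=10, persons_per_area_mean=60),
    seed=42,
)
episodes = hn.merge_episodes(admissions)          # no-op here: no transfers
profiles, _ = hn.compute_area_weights(episodes)
partition = hn.assign_hsa(profiles)
summary = hn.catchment_summary(profiles, partition, persons, episodes)

st = summary.stats
print(f"{len(profiles)} areas, {len(summary.hospitals)} hospitals, "
      f"{st['hsas']['n_nonempty']} non-empty HSAs")
print(f"mean admissions per area:       {st['areas']['n_admissions']['mean']:.0f}")
print(f"mean hospitals used per area:   {st['areas']['n_hospitals']['mean']:.1f}")
top1 = st["areas"]["share_top1"]
print(f"mean top-hospital loyalty:      {100*top1['mean']:.0f}% "
      f"(IQR {100*top1['iqr'][0]:.0f}-{100*top1['iqr'][1]:.0f}%)")
msi = st["hospitals"]["market_share_index"]
print(f"market share index:             mean {100*msi['mean']:.0f}%, "
      f"range {100*msi['range'][0]:.0f}-{100*msi['range'][1]:.0f}%")
print()
print("Loyalty is the share of an area's admissions going to its most common")
print("hospital; the market share index is the share of a hospital's")
print("admissions coming from inside its own discrete catchment. Hospitals")
print("that are nowhere the plurality choice have an empty HSA and market")
print("share 0 - they are invisible to a discrete-catchment analysis.")
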