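"""Which hotspot holds the fastest-evolving lineage?

A synthetic eight-hotspot rate table is drawn with log-scale locations
matching the eight published hotspot means, then the two-level
Monte-Carlo procedure runs: each step draws 5 lineages per hotspot
without replacement, ranks the pooled 40 by rate, and records which
hotspot supplied the fastest lineage; 1000 steps form one process, and
200 independent processes give means and 95% percentile CIs.  On a
small table the exact enumeration oracle verifies the Monte Carlo.
"""

import numpy as np

import paramodiv as pv

means = [1.36, 1.07, 0.76, 0.73, 0.58, 0.40, 0.39, 0.14]
names = [
    "Paramos", "Mediterranean", "SucculentKaroo", "Hawaii",
    "Cerrado", "Cape", "California", "SWAustralia",
]
specs = [
    pv.HotspotSpec(hotspot=n, n_lineages=10, rate_location=float(np.log(m)),
                   rate_spread=0.4)
    for n, m in zip(names, means)
]
table = pv.generate_lineage_table(specs, seed=1)

rs = pv.summarize(
    table,
    pv.ResamplingConfig(per_hotspot_k=5, n_samples=1000, n_iterations=200, seed=1),
)
out = rs.table.sort_values("prob_fastest_mean", ascending=False)
print(out.round(3).to_string(index=False))
print("\nprob_fastest_mean estimates the probability that the single fastest")
print("lineage in a stratified draw comes from that hotspot; max_run_* is the")
print("longest top-of-ranking streak one hotspot achieved within a process.")

small = table.groupby("hotspot").head(3)
exact = pv.exact_fastest_probability(small, 1)
print("\nExact fastest-hotspot probabilities (3 lineages/hotspot, k=1):")
for h, p in sorted(exact.items(), key=lambda kv: -kv[1]):
    print(f"  {h:16s} {p:.3f}")
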