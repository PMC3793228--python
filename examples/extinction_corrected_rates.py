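"""Extinction-corrected rates: how the relative extinction fraction
changes the estimate.

The Magallón–Sanderson crown estimator inverts the expected richness of
a birth–death clade conditioned on survival.  Higher assumed relative
extinction eps = mu/lambda means more unseen turnover, so the same
standing richness implies a *lower* net rate.  The conventional grid
{0, 0.5, 0.9} spans no extinction to severe extinction.
"""

import paramodiv as pv

records = pv.load_paramo_lineages()
print(f"{'lineage':22s} {'eps=0':>7s} {'eps=0.5':>8s} {'eps=0.9':>8s}")
for rec in records:
    rates = [
        pv.ms_rate(rec.n_species, rec.crown_age_mean, eps, "crown")
        for eps in (0.0, 0.5, 0.9)
    ]
    print(f"{rec.lineage_id:22s} {rates[0]:7.2f} {rates[1]:8.2f} {rates[2]:8.2f}")

print("\nRates are per lineage per Myr; eps=0 reproduces the pure-birth column.")
print("Net rates shrink as assumed extinction grows, but the ranking of")
print("lineages is preserved.")
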