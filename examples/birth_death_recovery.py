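"""Parameter recovery: does the estimator get back the rate that
generated the trees?

Yule trees with known birth rate are simulated, the crown estimator is
applied to each (tip count, known age) pair, and the median estimate is
compared with the truth.  The same experiment with extinction uses the
eps-matched crown estimator on reconstructed birth-death trees.
"""

import numpy as np

import paramodiv as pv

lam, t_stop, reps = 0.5, 8.0, 200
est = [
    pv.pure_birth_rate(
        pv.simulate_yule(pv.SimulationConfig(birth_rate=lam, stop_time=t_stop, seed=s)).n_tips,
        t_stop, n0=2,
    )
    for s in range(reps)
]
print(f"Yule: lambda={lam}, t={t_stop}, {reps} trees")
print(f"  median estimate {np.median(est):.3f}  (truth {lam})")
print(f"  per-tree IQR    {np.percentile(est, 25):.3f}-{np.percentile(est, 75):.3f}")

lam, mu, reps = 1.0, 0.5, 500
eps, t_stop = mu / lam, 3.0
est = [
    pv.ms_rate(
        pv.simulate_birth_death(
            pv.SimulationConfig(birth_rate=lam, death_rate=mu, stop_time=t_stop,
                                condition_on_survival=True, seed=s)
        ).n_tips,
        t_stop, eps, "crown",
    )
    for s in range(reps)
]
print(f"\nBirth-death: lambda={lam}, mu={mu} (eps={eps}), t={t_stop}, {reps} trees")
print(f"  mean estimate {np.mean(est):.3f}  (truth r = lambda - mu = {lam-mu})")
print("\nSingle-tree estimates scatter widely (richness is one noisy draw);")
print("aggregates over many clades are what the estimator recovers well.")
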