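"""Kaplan-Meier curves and log-rank tests between EMT groups.

The generator links the overall-survival hazard to the EMT group
(hazard ratio 2 for high vs low); the log-rank test recovers the
difference while the progression endpoint is analyzed the same way.
"""

from emtime import km_estimate, logrank_test
from emtime.simulate import SimulationConfig, generate_cohort

bundle = generate_cohort(SimulationConfig(
    cohort_id="DEMO", n_samples=400, seed=3, hazard_ratio_high_vs_low=2.0))
groups = bundle.truth.group
os_data = bundle.clinical.endpoint("os")

times, events = {}, {}
for label in ("high", "intermediate", "low"):
    members = groups.index[groups == label]
    times[label] = os_data.loc[members, "time"].to_numpy()
    events[label] = os_data.loc[members, "event"].to_numpy()
    curve = km_estimate(times[label], events[label])
    print(f"EMT-{label:<12} n={curve.n_total:3d} events={curve.n_events:3d} "
          f"S(500 d)={curve.survival_at(500):.2f}")

res = logrank_test(times, events)
print(f"\n3-group log-rank: chi2={res.chi2:.2f} (df={res.df}), p={res.p:.2e}")
two = logrank_test({k: times[k] for k in ("high", "low")},
                   {k: events[k] for k in ("high", "low")})
print(f"high vs low:      chi2={two.chi2:.2f} (df={two.df}), p={two.p:.2e}")
# EMT-high samples carry twice the baseline hazard, so their survival
# curve sits below EMT-low and the log-rank test rejects decisively.
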