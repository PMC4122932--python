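"""Miniature power analysis of the ksk(20)^2 detector.

Runs a handful of reduced-scale replicates of a strong sweep and a weak
sweep, builds a small extreme-value neutral null, and prints the detected
fraction of each scenario.  (The full analysis uses 100+ replicates and an
800-replicate null; see the `kskscan power` command.)
"""

from kskscan import Scenario, StudyConditions, power_table

conditions = StudyConditions().rescaled(10.0)
scenarios = [
    Scenario("strong sweep (s=0.05)", "snv", s=0.05),
    Scenario("weak sweep (s=0.01)", "snv", s=0.01),
    Scenario("microsatellite phi=5", "msat", phi=5),
]
results = power_table(scenarios, reps=10, seed=7, conditions=conditions,
                      null_reps=100)
for r in results:
    print(f"{r.scenario:28s} detected {r.detected}/{r.replicates} "
          f"(power {r.power:.2f})")
print()
print("A completed strong sweep is almost always detected; a weak sweep")
print("rarely exceeds the extreme-value critical value; microsatellite")
print("selection sits in between, depending on delta_msat.")
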