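"""Deterministic base case: lifetime costs and QALYs for both arms.

Loads the shipped defaults (published unit costs, utilities and pathway
probabilities plus flagged synthetic stand-ins for unpublished inputs),
rolls back both decision trees, runs the 160-cycle cohort model and prints
the incremental result.
"""

from copdcue import CostUtilityModel, load_config

params = load_config()
model = CostUtilityModel(params)
result = model.evaluate()

print(f"{'arm':<14}{'cost (£)':>12}{'QALYs':>10}")
print(f"{'RP2.1 test':<14}{result.cost_intervention:>12.2f}{result.qaly_intervention:>10.3f}")
print(f"{'usual care':<14}{result.cost_control:>12.2f}{result.qaly_control:>10.3f}")
print(f"{'difference':<14}{result.incremental_cost:>12.2f}{result.incremental_qaly:>10.3f}")
print(f"classification: {result.classification}")

# A negative cost difference with a positive QALY difference means testing
# both saves money and gains health: the tested arm dominates usual care,
# so no ICER is reported.
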