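"""Probabilistic sensitivity analysis: CE plane and acceptability curve.

Every cost is drawn from its fitted Gamma distribution and every
probability/utility from its Beta distribution; each draw re-runs both
arms end to end.  The fraction of draws with positive net monetary benefit
at each willingness-to-pay threshold forms the acceptability curve.
"""

from copdcue import CostUtilityModel, load_config
from copdcue.cea import ceac, run_psa

model = CostUtilityModel(load_config())
samples = run_psa(model, n=2_000, seed=42)

frame = samples.to_frame()
print(frame.describe().loc[["mean", "std"]].to_string())
share_dominant = ((frame.incremental_cost < 0) & (frame.incremental_qaly > 0)).mean()
print(f"\nshare of draws in the dominant quadrant: {share_dominant:.1%}")

curve = ceac(samples)
for wtp in (0.0, 10_000.0, 20_000.0, 30_000.0, 50_000.0):
    print(f"P(cost-effective at £{wtp:>6,.0f}/QALY) = {curve.at(wtp):.3f}")
# The probability at £20,000/QALY is the headline decision-uncertainty
# summary: how often the test wins once parameter uncertainty is allowed for.
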