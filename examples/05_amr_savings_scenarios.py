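"""Trajectory-scaled resistance savings and the UK testing-cost comparison.

Anchors annual global AMR costs to the 2023 resistance rate of each proxy
pathogen (MRSA, PRSP; synthetic trajectories to 2040), applies a constant
relative reduction attributable to testing (1-25%), and values the gap
between the usual-care and tested cost streams as annual savings — then
sets those savings against the cost of testing UK COPD exacerbations.
"""

from copdcue import load_config, synthetic
from copdcue.amr import scenario_grid, uk_net_position, uk_testing_cost

params = load_config()
cfg = params.amr

traj_cfg = dict(cfg["trajectories"])
traj_cfg.pop("assumption", None)
trajectories = {name: synthetic.trajectory_from_config(name, spec)
                for name, spec in traj_cfg.items()}
for name, traj in trajectories.items():
    print(f"{name}: 2023 rate {traj.rate_at(2023):.3f} -> 2040 rate "
          f"{traj.rate_at(2040):.3f}  (synthetic)")

grid = scenario_grid(trajectories,
                     {k: float(v) for k, v in cfg["annual_cost_bases_gbp"].items()},
                     rmf=float(cfg["rmf"]), copd_share=float(cfg["copd_share"]))
full_share = grid[grid.uk_share == 1.0]
pivot = full_share.pivot_table(index=["pathogen", "cost_basis"],
                               columns="reduction", values="annual_savings_gbp")
print("\nannual savings (£bn) by reduction in resistance:")
print((pivot / 1e9).round(2).to_string())

unit_cost = params.costs["rp21_test"].mean
print("\nUK testing costs vs savings (MRSA, GDP basis, 25% UK cost share):")
saving = full_share[(full_share.pathogen == "mrsa")
                    & (full_share.cost_basis == "gdp")
                    & (full_share.reduction == 0.01)].annual_savings_gbp.iloc[0]
for fraction in cfg["uk_exacerbation_fractions"]:
    patients, cost = uk_testing_cost(float(cfg["uk_annual_diagnoses"]),
                                     float(fraction), unit_cost)
    net = uk_net_position(saving, 0.25, cost)
    print(f"  test {fraction:.0%} of cases: {patients:,.0f} patients, "
          f"£{cost/1e6:.1f}m/year; net of 25%-share savings: £{net/1e6:+.1f}m/year")
# Even the most conservative savings cell dwarfs the cost of testing every
# exacerbating COPD patient in the UK.
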