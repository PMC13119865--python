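# Methods

## Model structure

The model couples a short-run decision tree (one exacerbation episode,
under a year, undiscounted) to a lifetime Markov cohort model. The two arms
— rapid-panel-guided treatment versus usual care — share a single tree
topology and differ only in (i) the probability of receiving antibiotics at
first line (1 − test sensitivity = 0.03 versus 0.80), (ii) the arm-specific
improvement probabilities, (iii) the admission-stage hospitalisation
probabilities, and (iv) the test unit cost, which enters the tested arm
exactly once at the root.

Tree pathways: first-line treatment is antibiotics alone or steroids plus
antibiotics. Non-responders receive a second round — repeat antibiotics or
antibiotics with an A&E attendance (antibiotic-only failures, split
50/50 by default) or repeat steroids + antibiotics — then a third round,
after which failures reach the admission stage. In usual care the admission
probability depends on whether the infection is bacterial (0.20) or viral
(0.10); in the tested arm on the first-line treatment received (0.15
antibiotics-first, 0.10 steroids + antibiotics). Admitted patients die with
probability 0.05 or recover fully/partially (50/50 by default); admission
candidates managed in the community are partially recovered. Terminal
payoffs are the full/partial recovery utilities (0.6607 / 0.5558); deaths
score zero.

Episode severity classes follow the recovery round: recovered first-line =
mild; recovered at the second or third round = moderate; reached the
admission stage = severe. Rollback (probability-weighted bottom-up
expectation, pruning zero-probability branches) yields expected episode
cost, expected payoff and the severity distribution.

## Cohort model

Ten states — {stable, mild, moderate exacerbation} × GOLD {II, III, IV}
plus absorbing dead — over 160 three-month cycles from age 60 to 100.
The alive-block transition matrix is the product of independent severity
and (one-way) GOLD-progression moves; disease-specific excess death and
age-dependent all-cause mortality combine as competing risks,
q = 1 − (1 − q_ac)(1 − q_ds), with alive transitions rescaled by survival
so every row sums to one. All-cause annual probabilities convert to cycles
as 1 − (1 − q)^0.25 and are looked up at floor(age).

Entry: the tree's mild class enters the mild exacerbation states, moderate
and severe enter the moderate states (the most severe alive state — the
model has no persistent "severe" state because severe exacerbation is
represented as an admission *event*: a per-cycle admission probability in
exacerbation states carrying the hospital-stay cost and a small excess
death probability). Episode deaths enter the dead state. Entry mass spreads
across GOLD stages by a configured mix (uniform by default; not published).

Accrual uses start-of-cycle occupancy: cycle-t QALYs are occupancy · utility
× 0.25 years, costs are occupancy · per-state cost. State costs price
per-cycle resource-use quantities at the published unit costs plus the
expected admission cost; state utilities are the GOLD-stage utilities
scaled by an exacerbation multiplier (1.0 / 0.85 / 0.70). Discounting is
mid-cycle: increment t is weighted (1 + 0.035)^(−(t + 0.5)·0.25). We read
"half-cycle method" as mid-cycle discounting of full-cycle increments — the
alternative (averaging adjacent-cycle occupancy) is a second-order
difference; the choice is isolated in one operation
(`markov.discount_half_cycle`).

The arm totals add the undiscounted episode cost and an episode QALY
contribution (terminal utility × one cycle length, 0.25 y) to the
discounted lifetime totals. The cohort is an expected-value (Markov cohort)
simulation; the 10,000-patient scale of the study population is carried by
the probabilistic analysis, not by microsimulation.

## Parameters and distributions

All published inputs ship verbatim in `src/copdcue/data/default_config.yaml`:
19 unit costs (2022 GBP, Gamma), 3 recovery utilities, 3 GOLD-stage
utilities and 14 pathway probabilities (Beta). Distributions are fitted by
method of moments — Gamma shape (m/s)², scale s²/m; Beta via
ν = m(1−m)/s² − 1 — the standard convention when sources report only mean,
SE and family. An SE with s² ≥ m(1−m) admits no Beta; the policy is
configurable (`raise` or `clamp` to 0.95·√(m(1−m)) with a warning, default
clamp). One published control-arm row (mean 0.80, SE 0.8) is impossible and
is presumed a typo; the shipped default uses 0.16, the 20%-of-mean pattern
of every other probability row. The tested arm's antibiotic probability is
validated at load time against 1 − sensitivity so the structural assumption
is an enforced identity, not two free numbers. The four admission-stage
probabilities are taken from the one-way sensitivity table (they appear
nowhere else) with SEs following the same 20% convention.

## Sensitivity analyses

*One-way (DSA):* bounds are base × (1 ∓ 0.392) — a 95% interval for an SE
of 20% of the mean — with probabilities and utilities capped at 1. This
single rule reproduces all twelve published minimum/maximum pairs at their
printed rounding, which is why it ships as the default (per-item overrides
are accepted).

*Threshold:* the break-even test price solves NMB(λ = £20,000) = 0 by
bisection to £0.01 on a [0, 10⁵] bracket; the price enters the cost
difference linearly with slope one, so the root is unique.

*Probabilistic (PSA):* 10,000 draws by default. Every distribution-carrying
item is sampled independently (no correlation structure is published);
parameters shared across arms use the same draw in both arms within an
iteration. Draws are generated vectorised per item in a fixed deterministic
item order from one seeded generator — equivalent in reproducibility to
per-draw substreams and much faster. Because only tree/cost/utility items
are sampled, the per-cycle transition matrices are identical across draws;
the engine therefore precomputes the discounted occupancy-propagation
operator A = Σ_t d_t·C_t (C_t the t-step matrix product) once, after which
a draw is two tree rollbacks plus entry·A·v products. This fast route is
algebraically identical to the explicit cycle loop and is tested against it
directly and via the SE→0 degeneracy. The acceptability curve counts draws
with NMB > 0 (exact ties count half) on a £0–50,000 grid in £1,000 steps.

## AMR procedures

*Per-prescription penalty:* $100 × 10¹² GDP loss over 35 years → $2.857
× 10¹²/year (displayed $2.8 trillion); 14.1 DDD/1000/day × 7.8 × 10⁹ people
× 365 days → 4.01 × 10¹⁰ DDD/year; ÷ 5-day courses → 8.03 × 10⁹
prescriptions/year; division, conversion at 0.800769 GBP/USD and RMf 0.37
give £105.44. The published chain prints $356.96 → £285.84 → £105.76, which
is not exactly implied by its own intermediates (it back-solves to a global
population of ≈7.78 × 10⁹); the module carries both chains, uses the
canonical published values downstream by default, and logs the £0.32
divergence. The RMf itself is not published; 0.37 is the unique 2-dp value
mapping £285.84 to £105.76. The penalty (or the broad/narrow-spectrum
alternatives £7.45/£14.89) is added to both antibiotic-course cost items.

*Trajectory-scaled savings:* yearly cost_t = base annual cost ×
(rate_t / rate_2023) × RMf-if-GDP-basis × 7.5% COPD share. The tested
scenario multiplies every rate by (1 − reduction) while staying anchored to
the usual-care 2023 rate; "adjusted to an annual value" is implemented as
the mean of the yearly differences over 2023–2040 (sum-over-period and
terminal-year readings are config options). The RMf applies only to the
GDP-derived basis; the hospital (£554bn) and productivity (£155bn) bases
already concern the human population, and their combined scenario is the
exact sum of the components. UK shares (100/50/25%) scale the savings
linearly — the published reduced-share rows are not exact fractions of
their own 100% rows, and no attempt is made to reverse-engineer that.

## Synthetic inputs

Four inputs the evidence base does not print are generated, flagged
`assumption: true` in the config and enumerated in every run manifest:

- **Resistance trajectories** (2023–2040): drift curves with seeded noise,
  clipped to [0.001, 0.999] and anchored exactly at the 2023 start rate.
  Defaults: MRSA 0.30 declining 2%/year, PRSP 0.25 rising 1.5%/year —
  qualitative shapes (slowly evolving, one falling, one rising), not values
  read off any figure.
- **All-cause mortality**: Gompertz q(age) = 2 × 10⁻⁵·e^(0.097·age)
  (≈0.7% at 60, ≈33% at 100), an England-and-Wales-like shape, not the
  2022 life table.
- **Transition intensities and resource use**: per-cycle severity
  transitions with a sticky moderate state (0.70 self-transition), 1%/cycle
  GOLD progression, admission probabilities 0.02/0.12 (mild/moderate) and
  small excess mortality (0.0005/0.002), plus per-state resource quantities
  chosen once as clinically plausible primary/secondary-care contact rates.
- **Tree splits not printed anywhere**: bacterial fraction in usual care
  (0.5), A&E share of second-line antibiotic failures (0.5), full-recovery
  share after admission (0.5).

Consequently the tests demonstrate *internal correctness* (engines match
independent oracles; published arithmetic chains and bound rules reproduce
exactly) and *directional* findings (dominance, break-even price above list
price), but passing tests do not certify the published lifetime magnitudes
(£57,341/£60,103 costs, 9.747/9.721 QALYs, £355 threshold, 70%
acceptability), which depend on unpublished upstream inputs. Under the
shipped stand-ins the model lands in the same regime: dominant base case,
break-even price ≈£424, acceptability ≈0.76 at £20,000/QALY.

## Numerical choices

Chance-node probabilities must sum to 1 within 10⁻¹²; zero-probability
branches are pruned before rollback. Resolved transition rows are checked
to 10⁻¹², occupancy conservation to 10⁻⁹. Dominance classification uses a
10⁻⁹ tolerance for "equivalent"; an ICER is reported only when both
increments are nonzero with agreeing signs, and the zero-QALY edges are
labelled weakly dominant/dominated rather than given a ratio. Bisection
tolerance for the threshold price is £0.01. Problem sizes throughout are
the study's own: 160 cycles, 10,000 PSA draws, 10⁶-draw moment checks in
the test suite.

## Limitations

No GOLD-stage regression, no treatment-effect waning, no parametric
survival extrapolation, no parameter correlation in the PSA, no EVPI, and
no re-derivation of the resistance-forecasting model behind the
trajectories. The consumption→resistance elasticity is represented only by
the assumed constant 1–25% reduction grid.
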