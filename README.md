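# copdcue

Cost-utility model of rapid multiplex respiratory-panel testing (Biofire
FilmArray RP 2.1+) for acute exacerbations of COPD in the community, with
two procedures for pricing the antimicrobial-resistance (AMR) externality of
antibiotic prescribing.

## Who this is for

Health economists and HTA analysts who want a tested, configuration-driven
re-implementation of a decision-tree-plus-Markov cost-utility analysis:
every input is a named, auditable configuration entry, every unpublished
input is a flagged synthetic stand-in, and the internal engines are verified
against independent oracles.

## The model

A short-run **decision tree** covers one exacerbation episode. In the tested
arm only patients with a positive bacterial result receive antibiotics
(P(antibiotics) = 1 − sensitivity = 0.03); in usual care prescribing follows
clinical judgement (P = 0.80). Both arms share one topology: first-line
treatment (antibiotics alone, or steroids + antibiotics), up to two further
treatment rounds for non-responders, then a hospital-admission stage whose
survivors are fully or partially recovered. Rollback gives each arm's
expected episode cost C, expected utility payoff, and a severity
distribution (mild = recovered first-line; moderate = recovered later;
severe = reached the admission stage; dead).

The severity distribution seeds a lifetime **Markov cohort model** with 10
states — {stable, mild, moderate exacerbation} × GOLD {II, III, IV} plus
dead — run over 160 three-month cycles from age 60 to 100, with
age-dependent all-cause mortality overlaid as a competing risk
(q = 1 − (1 − q_ac)(1 − q_ds)). Costs and QALYs accrue per cycle
(ΔQALY_t = Σ_s π_t(s)·u(s)·0.25) and are discounted at 3.5%/year with a
half-cycle correction, (1+r)^(−(t+0.5)·0.25).

Results are reported as incremental cost ΔC and QALYs ΔQ, the ICER ΔC/ΔQ
(or a dominance classification), and net monetary benefit
NMB(λ) = λ·ΔQ − ΔC at λ = £20,000/QALY. Sensitivity analyses: one-way
swings of ±39.2% (probabilities capped at 1), a bisection search for the
break-even test price (NMB = 0), and a 10,000-draw probabilistic analysis
(Gamma for costs, Beta for probabilities/utilities, method-of-moments fits)
yielding a cost-effectiveness plane and acceptability curve.

Two AMR procedures: (1) a **per-prescription penalty** — an annualised
global GDP loss of resistance divided by yearly global prescription volume,
converted to GBP and scaled by a resistance-modulating factor (RMf = 0.37),
added to every antibiotic-course cost; (2) **trajectory-scaled savings** —
annual AMR costs anchored to 2023 resistance rates of proxy pathogens
(MRSA, PRSP) and scaled along their 2023–2040 trajectories; a constant
relative reduction in resistance (1–25%) attributable to testing is valued
as a yearly savings stream (× 7.5% COPD prescribing share, optional RMf,
UK cost shares) and compared with national testing costs.

## Worked example

```bash
python examples/01_base_case.py
```

```
arm               cost (£)     QALYs
RP2.1 test         9857.85     9.564
usual care         9910.08     9.550
difference          -52.24     0.014
classification: dominant
```

Under the shipped defaults the tested arm saves £52 per patient over a
lifetime and gains 0.014 QALYs — it *dominates* usual care (cheaper and
more effective), so no ICER is reported. The magnitudes depend on the
flagged synthetic stand-ins for unpublished inputs (per-state resource use,
transition probabilities, mortality curve); the direction of the effect is
the robust finding, and `examples/02_sensitivity_and_threshold.py` shows it
survives every one-way parameter swing, with a break-even test price of
£424 — well above the £94 list price. The remaining examples cover the
probabilistic analysis and both AMR procedures; `copdcue suite --out
results` runs everything from the command line and writes CSV/JSON plus a
manifest of every assumption-flagged input used.

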