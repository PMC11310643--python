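# econeval

A three-part economic evaluation of **Mobile Link**, an mHealth (SMS/voice
messaging) intervention that connects female entertainment workers in
Cambodia to outreach workers and health services, compared with usual care
(in-person counseling, HIV/STI testing, condoms, a toll-free hotline).
The package is for health economists and modellers who want to reproduce,
probe, or re-parameterize the evaluation: every input is an explicit,
editable fixture, and every stage is a tested library function with a thin
CLI on top.

The three analyses, driven by one config:

1. **Cost analysis** — total, per-person and incremental costs of the
   intervention vs usual care, from a payer perspective and a combined
   payer+patient perspective (participant time saved by outreach contact,
   valued at the earnings rate).
2. **Cost-effectiveness analysis** — a probabilistic decision model over a
   1-year horizon. Five binary trial outcomes are converted to DALYs
   averted: with no mortality pathway, per outcome *i*

   ```
   DALYs_i = (ARD_i / 100) × DW_i,        ARD_i = R_M,i − R_U,i   (percent)
   ```

   where `R_M`, `R_U` are the endline risks in the intervention and
   usual-care arms and `DW_i` the disability weight. Uncertainty is
   propagated by Monte Carlo: each arm's risk is drawn from a normal
   (base case), beta, or uniform distribution moment-matched to its
   reported mean/SD, and each disability weight from a moment-matched
   beta. Results are summarized as the ICER `ΔC / E[ΔE]`, net monetary
   benefit `λ·ΔE − ΔC`, a cost-effectiveness acceptability frontier over
   willingness-to-pay thresholds λ, and break-even analyses at the
   Cambodian threshold range (US $835–$1671 per DALY averted, 50–100% of
   2019 per-capita GDP).
3. **Budget impact analysis** — undiscounted financial cost of scaling
   messaging and outreach services to ~70% of the estimated 50,000 female
   entertainment workers over 5 years, with a year-1 startup cost and
   per-person per-year unit costs.

A `synthetic_trial` module generates two-arm binary-outcome trial data
(with configurable dropout) matching the statistical structure the model
assumes, so the whole pipeline can be exercised end-to-end without any
real participant data.

## Worked example

```sh
econeval cea --out results --seed 947251
```

writes `dalys_averted.csv` (mean DALYs averted and 5th–95th percentile
predicted interval per outcome, 10,000 simulations, normal family):

```
family,outcome,mean_dalys,pi_low,pi_high
normal,hiv_testing,-0.00189,-0.02497,0.01988
normal,sti_testing,0.00059,0.00015,0.00118
normal,modern_contraceptive_use,-0.00020,-0.00156,0.00102
normal,no_forced_drinking,0.00182,-0.01500,0.02008
normal,low_or_no_gbv,0.01729,-0.00134,0.04678
normal,total,0.01762,-0.01908,0.05828
```

and `cea_summary.csv` with the headline numbers (abridged):

```
incremental_cost_per_person_payer          199
incremental_cost_per_person_payer_patient  195.00
mean_total_dalys_averted_payer             0.01762
icer_payer                                 11294.6
icer_payer_patient                         11067.8
required_effect_dalys                      0.11909
required_cost_reduction_fraction           0.85205
```

Reading: the intervention costs US $199 more per person than usual care
(US $195 once participants' time savings are credited) and averts a mean
0.0176 DALYs per person, for an ICER of ~US $11,300 per DALY averted —
far above the US $1671 upper Cambodian threshold. To reach that threshold
the incremental cost would have to fall by ~85%, or the effect would have
to reach 0.119 DALYs averted. Negative rows (HIV testing, contraceptive
use) are outcomes on which the intervention underperformed usual care.

`econeval cost`, `econeval bia` and `econeval simulate-trial` run the
other stages; every result CSV has a `.meta.json` sidecar with the seed,
simulation count and config hash needed to re-run it bit-identically.
The budget impact run projects a 5-year horizon total of US $1.59 million
(62.6% outreach workers, 17.5% messaging, 19.9% startup) for 34,790
people covered — US $45.70 per person per year.

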