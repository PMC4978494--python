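# Methods

## Model structure

A cohort enters the model at diagnosis of node-positive HER2+ early breast
cancer, at the midpoint age of its 5-year group, having completed
anthracycline chemotherapy. The comparison is a 12-month trastuzumab regimen
(concurrent with a 4-month taxane) versus the taxane alone. Six states are
tracked on an annual cycle: treatment (cycle 1 only), remission, CHF,
pre-terminal/terminal, death from breast cancer, death from other causes.
The run continues to age 110 or cohort extinction (alive fraction < 1e-12).

Within a cycle, breast-cancer death and other-cause death compete as constant
hazards. The per-cycle death probability is `1 − exp(−(h_bc + h_oc))` with
the cause split proportional to the hazards; because both arms use
exponential within-cycle survival, the engine's survival curve equals the
closed-form `exp(−Σ hazards)` and can be validated analytically. The
individual-level monthly micro-simulation used as a test oracle has the same
within-year distribution by construction, so any disagreement beyond
Monte-Carlo noise indicates a bookkeeping defect, not a discretisation gap.

Hazards:

- `h_oc = m_b(age_start + t − 1)`, the life-table rate at the attained age
  (age advances one year per cycle).
- `h_bc = ρ_eff(t) · k_s · m_e(t − 1)`, the excess rate at years-since-
  diagnosis, scaled by the subtype multiplier `k_s` and — in the trastuzumab
  arm during cycles 1..8 — the age-band risk ratio. `m_e` is exactly zero
  from the cure year (20) onward, after which the cohort's conditional
  mortality equals the background population's (verified exactly in tests).

### CHF pathway

All CHF (NYHA III/IV) arises at month 6 of cycle 1 in 1% of the trastuzumab
arm's survivors at that point. Cycle 1 is therefore simulated in two
half-year steps: full treatment effect to month 6, then the CHF subcohort
completes the cycle — and the rest of the benefit window — at
`effective_rr(ρ, 0.5)`, i.e. retaining half the hazard reduction after
discontinuation. CHF symptoms are reversible and last 6 months: the
subcohort carries the CHF disability weight for months 6–12 of cycle 1
(additive with the remission weight, clamped at zero) and incurs the CHF
cost bundle once. No excess cardiac mortality is modelled: cardiac mortality
is assumed to equal the background population's in both arms.

### Half-cycle handling

Members dying of other causes within a cycle accrue half a cycle of their
living state's QALYs and costs (uniform death timing). Members dying of
breast cancer accrue the full 12 months as 11 months pre-terminal + 1 month
terminal, replacing remission time; this is also how the dying-pathway states
enter occupancy (the dying fraction occupies the pathway in its death cycle).
The cycle-1 living weight is time-weighted: 4 months at the treatment DW,
the remainder at the remission DW. These conventions are deliberate choices
where the cycle structure leaves timing open; the accrual layer exposes them
in one place (`outcomes.accrue`).

## Valuation

QALY^DW weight per person-year: `max(0, 1 − DW_state(t) − pYLD(age))`. The
remission DW decays geometrically, `0.174 · 0.8^(t−1)`, and is zero after the
cure year (return to normal health, still subject to pYLD). No DW precedes
other-cause death. With all DWs and the pYLD schedule removed, the accrual
reduces exactly to discounted life-years — this identity is both a test and
the life-years-gained scenario.

Discounting is discrete annual, `(1 + r)^−(t−1)`, cycle 1 undiscounted,
r = 3% in the base case. Intervention costs are booked entirely in cycle 1
without intra-year discounting. The last-6-months cost for other-cause
deaths is booked in the death cycle. Unrelated (background) health-system
costs apply to all alive person-time, including post-cure; removing them is
the "offsets removed" scenario.

## Calibration

**Subtype multipliers.** The subtype intercept adjustment is realised as a
multiplicative excess-hazard scale `k_s` (equivalent to an additive
log-hazard shift). Given 5-y relative survival values `rs5_s` and proportions
`p_s`, ratios of `S_s(5) = exp(−k_s H5)` must match ratios of `rs5_s`, which
fixes `k_s` up to a common offset; the offset is root-found (Brent, residual
tolerance 1e-12) so that `Σ p_s S_s(5) = exp(−H5)`. The system also has a
closed form, used as an independent oracle in tests. Infeasible inputs (a
rs5 spread wider than the cumulative excess hazard can express with positive
multipliers) are rejected with the residual.

**HR → RR conversion.** The trials report an all-cause OS hazard ratio;
treatment acts on the excess hazard only, so the cause-specific risk ratio ρ
solves `Σ_t [m_b + ρ m_e] = hr · Σ_t [m_b + m_e]` over an 8-year horizon
(the trials' follow-up scale and the assumed benefit duration; configurable).
ρ = hr exactly when background mortality vanishes, and decreases as
background mortality grows — the conversion reproduces the published band
pattern (≈0.62 at age 35, ≈0.53 at 65 on the synthetic fixture, versus the
published 0.63/0.50 on the original inputs). The base case uses the
published band values directly as inputs; the conversion machinery is used
for the treatment-effect-heterogeneity scenario (OS HR 0.49 re-converted on
the model's own inputs) and for validation.

**Fixture scale.** The synthetic excess-hazard template declines
geometrically (15%/year from an initial rate, shape only); its scale is
root-found so the chemotherapy-alone pooled (subtype × stratum) cohort aged
50–54 has 10-y OS = 0.740000 ± 1e-6. Calibration is scale-invariant in the
template and re-derives the subtype multipliers at every trial scale.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* the analysis assumes: exponentially
rising background mortality (Gompertz, b = 2e-4 at age 25, log-slope
0.085/year — NZ-female-like level); early-concentrated excess mortality with
statistical cure; subtype proportions 37/15/3/45 (%) with prognosis ordering
ER+/PR+ best to ER−/PR− worst (default rs5 0.88/0.84/0.78/0.73); a pYLD ramp
(0.02 at 25, +0.0022/year, capped 0.25); phase costs (diagnosis/treatment
25k, remission 2k, pre-terminal 45k, terminal 90k NZD/year with a mild age
gradient); exponentially rising unrelated costs (1.5k at 25, +3.5%/year);
and three deprivation strata scaling background mortality (×0.90/1.00/1.15,
weights 0.33/0.34/0.33). It does **not** reproduce the registry's EMR
regressions, ethnicity-specific life tables, or confidential prices, so
absolute ICERs are fixture-dependent: passing tests demonstrate the method's
internal consistency and the *relative* heterogeneity pattern (QALY-gain
ratio worst/best ≈ 2.3, ICER ratio < 0.5, ICERs rising with age), not NZ
price-list conclusions. Cardiac monitoring has no published unit cost; the
default assumes NZ$200 per quarterly scan, flagged as an assumption.

## Uncertainty analysis

PSA draws (default 2,000; deterministic given the seed) are independent
across parameters: log-normal band RRs (per-band SE(lnRR), drawn
independently per band by default, togglable to one shared deviate),
log-normal CHF rate (SE 0.211 on the log scale), beta disability weights
(published alphas), gamma costs as mean-1 multipliers with 10% SE
(shape = (mean/SE)² = 100, scale = SE²/mean). CEACs count draws with
positive net monetary benefit, well-defined in all quadrants. Ratio CIs
(worst- vs best-prognosis QALY gain or ICER) are 2.5/97.5 percentiles of
per-draw ratios from draw sets paired by seed. The tornado uses analytic
2.5/97.5 quantiles of each distribution one at a time, expected values
elsewhere; on the fixture its two widest bars are the excess-hazard risk
ratio and the trastuzumab drug cost, with all DW bars far narrower.

## Numerical choices

- Root finding throughout is bracketed Brent with near-machine relative
  tolerance; no stochastic steps outside the PSA.
- EMR hazards are piecewise-constant within each year since diagnosis; the
  life table is piecewise-constant within each year of age.
- Pooled ICERs are always recomputed from pooled increments (mediant), never
  averaged over stratum ICERs.
- Stratum multipliers `k_s` are calibrated once at the pooled level and held
  fixed across deprivation strata (the strata differ only in background
  mortality and pooling weight).
- Problem sizes: the full base case is 14 age groups × 4 subtypes × 3
  strata × 2 arms (336 cohort runs, < 1 s); the test suite uses a
  100,000-individual micro-simulation oracle and small PSA draw counts, and
  completes in seconds.

## Known limitations

- No explicit recurrence state (captured implicitly by the excess-mortality
  formulation) and no temporary treatment interruptions.
- Treatment effect is assumed homogeneous across subtypes within an age band
  in the base case; subtype differences are driven entirely by baseline
  prognosis.
- The additive DW + pYLD combination (clamped at zero) is a modelling choice;
  multiplicative combination would give slightly different weights at high
  morbidity.
- Absolute monetary results depend on synthetic cost schedules and are not
  policy estimates.
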