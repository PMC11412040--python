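# Methods

## Model structure and assumptions

The model follows one cohort per treatment arm over a single year. A
patient's adherence stratum (compliant / partially compliant /
non-compliant, by medication possession ratio) is fixed for the year and
determines the per-cycle probabilities of a first relapse requiring
hospitalization (`ph`) or managed in ambulatory care (`po`). The first
relapse is absorbing for outcome classification: a patient's annual
outcome is exactly one of {stable, outpatient relapse, hospitalized
relapse}. There is no mortality, no discounting, and no multi-year
extrapolation; treatment switching is not modelled (intent-to-treat: all
costs attach to the initial treatment). Treatment discontinuation is not a
separate event — the inputs provide no discontinuation parameters — and is
effectively folded into non-adherence.

Six arms are modelled (olanzapine, risperidone, aripiprazole × ODT, SOT).
ODT and SOT of a molecule share relapse and adverse-event probabilities;
only adherence and drug price differ. Formulation groups (ODT + SOT)
report the *sum* of their member arms' costs and QALYs — the published
group totals are arithmetic sums of the arm totals (6140 = 3034 + 3106),
which doubles the per-patient scale of group results — while group outcome
proportions are unweighted means over members.

## The cycle exponent K

The relapse inputs (2–12% per adherence stratum) cannot be annual
probabilities: they are far below the published annual hospitalization
percentages (11–26%). They are treated as per-cycle probabilities under a
constant hazard, so the annual stable probability is `(1 − ph − po)^K`
with `K` the number of effective cycles per year. `K` is the model's one
clinical degree of freedom. It is fitted once by bounded 1-D least squares
(`scipy.optimize.minimize_scalar`, bounds [0.5, 12], tolerance 1e-8)
against the nine published annual outcome percentages (three drug groups ×
three outcomes, group marginals taken as the mean of the ODT and SOT arm
marginals), giving **K = 3.4750083**, which is frozen in the shipped
configuration. At this K every published outcome cell is matched within
1.5 percentage points. The relapse mass is split hospitalized : outpatient
in the stratum's ratio `ph : po` (the natural competing-risk tie-break).

## Occupancy and QALYs

Outcome-state durations are not published. A hospitalized relapse is
assigned one inpatient episode of 11.7 days — anchored to the published
length of stay per hospitalization event — and an outpatient relapse a
30-day episode (configurable; a conventional acute-episode length).
Episode days carry the stratum's relapse-state utility, the rest of the
year its stable-state utility. Adverse events carry costs but no utility
decrement (none is published); decrements default to zero. With the
calibrated K and these defaults, all six arm QALYs land within +0.007 of
the published values (tolerance band ±0.02).

## Costs and the stable-care scale

Annual cost per patient = drug acquisition (daily price × 365 × the
stratum's representative MPR) + stable-time outpatient basket + relapse
event baskets + adverse-event baskets. Representative MPRs are the
midpoints of the published category ranges: 0.90 / 0.70 / 0.40
(configurable). The month used to prorate the stable basket is 365/12 =
30.42 days. The diabetes adverse event, which has no resource-use column,
is costed as one unit of the "other medication" cost line (MAD 229).

Pricing the published monthly stable basket at the published unit costs
yields ≈ MAD 21,000/year — several times the published *total* annual
costs (≈ MAD 3,000–3,800). A single `stable_care_scale` factor multiplies
the stable basket so the cost side can be reconciled against a published
total; the fit is affine and solved in closed form, clamped to be
non-negative. Against the olanzapine SOT published total the fit clamps at
**scale = 0 with an unreachable residual of ≈ MAD +5,481**: even with the
stable basket removed entirely, drug + relapse + adverse-event costs
exceed the published total. The calibration reports this residual; the
shipped default is scale = 0. The scale is a declared reconciliation
device, not an inference about how the published totals were derived.

## Monte Carlo engines

`evaluate_expected` is the exact probability-weighted engine (deterministic,
the oracle for everything else). `simulate_microcohort` mirrors the
published 1,000,000-patient design: each patient consumes exactly five
uniform variates (adherence stratum; outcome against the cumulative
[hospitalized, outpatient) intervals; three adverse-event Bernoullis), so
results are independent of iteration order and reproducible given the
seed. Tests verify agreement with the exact engine within 3 standard
errors at n = 200,000 per arm across three seeds, and multinomial
consistency of outcome counts (chi-square, α = 0.001). The default number
of patients per arm is 1,000,000; tests use 50,000–200,000, which is
ample since the microsimulation estimates the same expectations.

## Sensitivity analysis

**One-way (tornado).** Every scalar input is addressable by a dotted path
(e.g. `utilities.non.stable`). Each parameter is swept to base × (1 ± f),
default f = 20%, clamped to validity (probabilities and utilities to
[0, 1]; an adherence share renormalizes the other two proportionally), and
the comparison's ICER is recomputed at both endpoints. Entries are ranked
by ICER spread. Because the base-case QALY difference between groups is
small, parameters that push the denominator toward zero produce very large
spreads; see "Known limitations".

**Screening (sequential bifurcation).** Parameters are screened against a
cost threshold by recursive bisection: a block is perturbed jointly, each
parameter in its cost-increasing direction (prices, quantities, relapse
and adverse-event probabilities up; compliant/partial adherence shares
down), and a block whose joint effect is below the threshold is discarded.
Because total cost is monotone in each perturbed direction, the joint
effect bounds every member's individual effect, so the surviving shortlist
is provably identical to one-at-a-time screening — verified against the
brute-force oracle on 32-parameter instances.

**Probabilistic (PSA).** Second-order Monte Carlo, default 1000
iterations. Distributions follow standard health-economics practice: beta
(method of moments) for relapse/adverse-event probabilities and utilities
with SE = 10% of the mean; gamma for unit costs and drug prices with SE =
20% of the mean; Dirichlet over each arm's adherence triple preserving the
base means (concentration set so the compliant share has a 10% relative
SE). Within a molecule the ODT and SOT arms share one draw per clinical
parameter (relapse, adverse events), reflecting the model's assumption
that formulations are clinically identical; adherence and prices are drawn
per arm. Utility draws are re-sorted within each stratum so the ordering
invariant holds; infeasible beta moments are clamped. Every drawn set
passes full validation. The CEAC reports, on a 0–400,000 MAD grid that
always contains the 250,832.40 threshold exactly, the frequency with which
each compared strategy attains the maximum net monetary benefit (ties
split equally).

## Synthetic data

`generate_parameter_set` emits structurally valid random parameter sets
whose dominance relations are known by construction: in the `one_dominant`
plan all arms share adherence, utilities and adverse events while strategy
0 has strictly lower relapse probabilities and a strictly cheaper drug, so
it must be cheaper and more effective through the monotone engine
(verified in 100/100 seeds). `all_equal` produces identical arms
(equal-effect ties everywhere) and `frontier_chain` strictly increasing
cost and QALY. Utilities are ordered both within strata and across strata
so more adherence always means more QALYs. These sets exercise the whole
pipeline without the reference fixtures, but they do not emulate real-data
features such as correlated adherence and relapse estimates, sampling
error in the inputs, or heterogeneity within strata — passing them shows
the machinery is correct, not that any particular clinical claim holds.
`perturb_reference_set` applies multiplicative noise (≤ ±50%) to the
reference set, restoring all invariants, for robustness tests.

## Numerical choices

Probability triples are validated to sum to 1 within 1e-9; the outcome
split computes the hospitalized fraction before multiplying so a zero
outpatient rate cannot produce a negative probability. Calibration uses a
bounded scalar minimizer (tolerance 1e-8; recovery of a known K verified
to 1e-4). Frontier ties in cost break by QALY descending then name;
extended dominance removes points whose incoming sequential ICER strictly
exceeds their outgoing one (collinear points survive). NMB ties in the
CEAC split probability equally. All randomness flows through
`numpy.random.default_rng` with explicit seeds.

## Known limitations

Three published results are *not* reproducible from the published input
tables, and the corresponding checks are left failing rather than
loosened:

1. **Cost levels and rank order.** Modelled totals (MAD ≈ 8,600–13,000)
   exceed the published totals (≈ 3,000–3,800) even with the stable-care
   basket removed, and the published ordering (each ODT arm cheaper than
   its SOT arm; aripiprazole group cheaper than risperidone's) cannot
   hold under MPR-prorated drug pricing: the ODT price premium times
   adherence always exceeds the relapse savings implied by the published
   relapse tables.
2. **Arm-level CEAC.** The published > 90% probability that olanzapine
   ODT is cost-effective rests on its published cost advantage over
   olanzapine SOT. Without it (limitation 1), olanzapine ODT wins on
   QALYs alone and its CEAC at the Moroccan threshold computes to ≈ 0.83.
   The group-level result (olanzapine ODT+SOT vs the comparator groups,
   ≈ 0.96–0.97) does reproduce.
3. **Tornado top parameter.** The published most-influential parameter
   (stable-state utility of the non-compliant stratum) has the largest
   effect on the QALY difference here too, but by ICER spread it ranks
   below parameters that drive the small QALY denominator toward zero,
   because the reconstructed cost difference is much larger than the
   published one.

The published one-way interval endpoints are not comparable at all: the
parameter ranges behind them are not published. Results are specific to
branded-product 2022 Moroccan prices and to the one-year horizon.
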