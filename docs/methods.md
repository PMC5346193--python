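# Methods

## The design problem

A flexible-entry multi-arm trial lets each participant restrict
randomisation to a subset of arms she finds acceptable, provided the subset
keeps at least one arm from every treatment class — so every realised
comparison still informs the class-level question. The toolkit models the
2 × 2 reference case (two LARCs versus two comparators, nine admissible
schemes) but the algebra is generalised to any number of classes with the
same "≥ 1 arm per class" rule; the closed-form scheme count is
Π_classes (2^{arms in class} − 1), and `enumerate_schemes` is tested against
a brute-force power-set filter for all 1 ≤ a, b ≤ 4.

Scheme identifiers are canonical: the sorted arm ids joined by `+`. This is
a toolkit convention (no ordering is inherent in the problem) chosen so that
state keys, file columns and report tables are stable.

## Minimisation

Variant: marginal-totals Pocock–Simon. For an incoming participant with
factor levels ℓ_f, the score of candidate arm k is Σ_f w_f · c_f(ℓ_f, k),
where c_f is the running count of previous allocations to arm k at that
level. The minimal-score arm is assigned with probability p; otherwise one
of the remaining arms is drawn uniformly; ties among minimal arms are broken
uniformly. Defaults: equal weights w_f = 1 and p = 0.8 — the common choice
that preserves unpredictability while controlling imbalance; p = 1 gives the
deterministic algorithm used in the score-oracle tests. The production
systems this emulates rarely publish their exact variant; both the variant
parameters and a pooled cross-scheme state mode are configurable, with
one-state-per-scheme the default (each scheme recruits its own
sub-population, so pooling would let one scheme's imbalance distort
another's allocations).

RNG contract: every allocation consumes exactly two draws from a named
`numpy.random.Generator` — a uniform for the biased coin and a second
uniform for the within-set index — whether or not the coin or the tie-break
mattered. The audit log records the cumulative draw index, so any allocation
sequence replays bit-exactly from (seed, draw index). Invalid input
(missing factor level, unknown arm) raises before any draw is consumed.

Properties verified by test rather than assumed: conservation of counts;
independence of per-scheme states; the one-factor/two-arm bound (at p = 1
the arm difference at any level never exceeds 1); and balance superiority —
in a 200-replicate paired simulation (100 participants per replicate,
identical covariate streams) minimisation at p = 0.8 yields strictly smaller
mean maximum marginal imbalance than coin-flip randomisation.

## Accrual simulation

The screening funnel draws, per screened patient, a categorical eligibility
outcome; randomised patients draw a scheme and baseline covariates. The
default eligibility probabilities are the reference pilot's empirical rates:
77/504 randomised, with the non-randomised 427 split 42 (conception plans),
35 (contraindication), 33 (no disease at laparoscopy), 94 (treatment
preference) and a pooled 223 "other". The stated exclusion percentages in
the source round correctly only against the 427 non-randomised denominator
(42/427 ≈ 10%), which is the reading adopted.

Preference comes in two modes: a categorical distribution over schemes
(default: the pilot's empirical distribution) or independent per-arm
acceptance probabilities conditioned on the class constraint by redrawing.
Covariates are drawn marginally: age ~ N(31, 7.5²) truncated to [16, 45]
(rejection sampling), disease stage categorical (0.47, 0.26, 0.14, 0.13),
complete excision with probability 0.92, pain score ~ N(58, 18.5²)
truncated to [0, 100], smoking 0.48, BMI ~ N(27, 5.7²) with
missing-completely-at-random probability 17/77. The generator does **not**
model covariate correlations, centre-level recruitment rates, temporal
accrual dynamics or informative missingness; passing tests therefore show
that the pipeline recovers the *marginal* rates it was given, not that real
cohorts look like these.

## The pilot fixture

The fixture reconstructs the 77-participant pilot cohort so that every
published margin is exact. Scheme choices live on a 3 × 3 grid — rows: which
LARC subset was accepted (LNG-IUS only / DMPA only / both), columns: the
comparator analogue — with published margins rows (27, 36, 14), columns
(28, 27, 22) and two published cells: both×both = 5 (accepted all four) and
DMPA×COCP = 14. The 63 single-LARC and 55 single-comparator totals split
27/36 and 28/27, the only integer pairs consistent with the published
rounded percentages (43/57% and 51/49%).

The interior is under-determined, so it is completed by a deterministic
rule: visit free cells in row-major order and assign each the **largest**
value that leaves the remaining transportation problem solvable (checked by
backtracking — a naive greedy min(row, col) fill strands the fixed cells and
is infeasible). The result,

|            | COCP only | none only | both |
|------------|-----------|-----------|------|
| LNG-IUS only | 14 | 13 | 0 |
| DMPA only    | 14 | 5  | 17 |
| both LARCs   | 0  | 9  | 5 |

preserves every published number, including the derived two-way total 46
and three-way total 26. Any other consistent fill would too; determinism is
what makes the fixture and its tests stable.

Covariate margins (stage 36/20/11/10, complete excision 71, age < 35 = 53,
smoking 34 yes / 6 missing, BMI missing 17, pain missing 2) are reproduced
exactly by block assignment; the joint structure is unpublished, so blocks
are combined by independent seeded permutations, with continuous values
drawn conditional on their categorical margin (age within/above the 35-year
cut). The centre split of the 77 is also unpublished: round-robin over the
six centres, permuted. The fixture is bit-identical for a fixed seed.

## Feasibility rule and adaptation

The prespecified rule — a design attracting under 10% of randomisations is
infeasible — admits two readings, both implemented and always reported:
`compatible_uptake` (fraction of participants whose accepted set contains
every candidate arm; the default, and the reading under which the four-way
design's 5/77 = 6.5% fails the threshold) and `allocation_share` (the
literal per-arm reading: the smallest share of realised allocations among
candidate arms). A third supporting figure, `scheme_selection` (accepted
set equals the candidate exactly), is reported because sole-design options
are naturally discussed that way — e.g. the DMPA-vs-COCP two-way scheme was
picked by exactly 14/77 = 18%. The candidate sweep scores every admissible
subset, not only the patient-facing schemes, so dropped-arm designs rank on
the same scale.

The threshold is monotone by construction (raising it never rescues a
candidate) and `compatible_uptake` is antitone in the candidate set; both
are property-tested. The probability that a design passes the rule under a
known preference distribution is a binomial tail, which the simulated pilot
sweep matches within Monte-Carlo error.

Adaptation: if the full design passes, it is kept with its original
sample-size block. Otherwise the fallback is the class-versus-comparator
design — participants preselect their class member before randomisation
(strata: each member plus a no-preference stratum sub-randomised among
members), so the per-member stratified analyses stay unbiased. The
comparator arm is an explicit input, not inferred from pilot data: in the
reference trial it was chosen on external evidence, which is outside this
toolkit's scope.

## Sample size and power

Power of the two-sided two-sample t test is evaluated from the noncentral-t
distribution: df = 2n − 2, noncentrality δ/(σ√(2/n)), power
P(|T| > t_{1−α/2,df}). The minimal n walks this monotone function from the
closed-form normal-approximation start. The noncentral-t method is the
default because it reproduces the reference design's published totals —
148/group (592 across four arms; 750 recruited at 20% attrition rounded up
to a multiple of 50) and 160/group (320; 400 recruited) — where the plain
normal approximation gives 146 and 159; the approximation remains available
via `method="normal"`. Bonferroni adjustment rounds half-up when a
reporting precision is given (0.05/6 = 0.00833 → 0.01 at 2 dp), matching
how adjusted alphas are quoted in protocols. Attrition inflation is
ceil(n/(1 − a)) rounded up to a configurable multiple; whether the
reference's 750 was "next multiple of 50" or an ad-hoc round figure is
unknowable, so the multiple is a parameter (reference config: 50).

Stratified power evaluates each stratum at floor(n_total · share / 2) per
arm; a stratum under 2 per arm reports "not estimable". The Monte-Carlo
check simulates independent normal outcomes with no baseline adjustment
(none is specified for these calculations) and agrees with the analytic
power within 3 binomial SEs on a six-point grid; statsmodels'
`TTestIndPower` serves as an additional independent oracle in the tests.

## Problem sizes and numerical choices

Desk-scale defaults keep the full suite around a few seconds: 10⁴ draws for
the uniformity chi-square, 4,000–8,000 replicates for Monte-Carlo power,
n = 5,000 for parameter recovery, 200 paired replicates for balance
superiority, 600 simulated pilots for the pass-rate calibration, and a
504 × 20 screening cohort for the funnel-rate check. Statistical test
tolerances are 3 SEs (3.5 for the pass-rate calibration, which compounds
simulation and oracle error). Truncated normals use rejection sampling;
the age-recovery test allows an extra 0.5-point margin for the small
downward shift truncation to [16, 45] induces on the mean. All randomness
flows through `numpy.random.default_rng` seeds; every simulation in the
package and tests is reproducible from its stated seed.

## Known limitations

- Covariates are simulated independently; no correlation structure, no
  centre effects, no secular trends.
- The fixture's grid interior and joint covariate structure are one
  deterministic completion of under-determined published margins — exact on
  every margin, arbitrary (but declared) inside.
- No outcome analysis: the pain score is treated as a given 0–100 number;
  instrument scoring, baseline adjustment and longitudinal modelling are out
  of scope, as are group-sequential boundaries and type-I-error accounting
  across pilot and main phases (the pilot performs no outcome testing).
- Unequal allocation ratios and stratified-permuted-block alternatives to
  minimisation are not implemented.
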