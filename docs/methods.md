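# Methods

This note documents the model, the simulation design, the numerical
choices and the known limitations of `apisim`.

## Genetic model

Every queen carries a bivariate additive genetic value `(a_w, a_q)`: a
worker effect, expressed by her daughters' worker group, and a queen
effect, expressed by herself. Base queens are drawn from `N(0, G0)` with

```
G0 = [[var_w, cov_wq],
      [cov_wq, var_q]]
```

Drones are haploid: a drone of queen Q carries `g = a_Q/2 + φ` with
Mendelian term `φ ~ N(0, (1 − F_Q)/4 · G0)`, so unrelated base drones have
covariance `G0/2` and the unconditional drone variance is `G0/2` at any
`F`. A daughter queen receives `a = a_dam/2 + ψ + g_father` with
`ψ ~ N(0, (1 − F_dam)/4 · G0)`; at `F = 0` the three terms sum to `G0`.
The worker group of a colony is the infinite-worker-group limit
`a_W = a_queen/2 + mean(D drones)` — the D = 8 drones contribute equally
and no worker-side Mendelian residual remains (a finite worker group would
add one; see Limitations).

Colony phenotypes follow `y = u_year + a_w(W) + a_q(Q) + e` with
`u_year ~ N(0, var_year)` drawn once per year and i.i.d. residuals
`e ~ N(0, var_e)`. Year effects are treated as fixed in estimation
regardless of how they were generated.

Four canonical parameter sets are provided (`GeneticParameterSet.preset`):
`(var_w, var_q, cov_wq, var_e)` = (10, 10, 0, 30), (20, 10, 0, 30),
(10, 10, −5, 30) and (20, 10, −√200/2 ≈ −7.07, 30), i.e. genetic variances
of one- and two-thirds of the residual variance and genetic correlations of
0 and −0.5. `var_year` defaults to 10 — an ordinary environmental
year-to-year spread of the same order as the genetic variance; it only
moves the fixed-effect level, not the variance components.

## Breeding scheme (the synthetic-data generator)

One replicate of the default scheme:

* **Year 0** — `18 × n_families` (432) unrelated, non-inbred founder BQs,
  each open-mated to 8 unrelated base drones; all founder colonies
  phenotyped; the best 24 queens across families become dams.
* **Years 1–10** — each selected dam produces 24 BQ and 20 DPQ daughters.
  Daughters are mated at birth: BQ cohorts of years 1–2 open-mated (first
  DPQs become available for drone production at age 2, i.e. in year 3),
  cohorts of year ≥ 3 controlled-mated; DPQs always open-mated. Winter
  mortality then removes exactly 25 % of colonies within each family
  (18 BQ + 15 DPQ phenotyped per dam — the per-family counts are exact by
  design, so record counts are deterministic: 432 + 10 × 792 = 8352).
  One BQ per family is selected on her own colony phenotype; 2/3 of the
  dams (16) are selected on their DPQ progeny mean, and 3 surviving DPQs
  per selected dam form a sister group used two years later. Group-to-BQ
  assignment is a balanced round-robin: 576 matings over 16 groups = 36
  matings per group.
* **Controlled mating** — SS: one sister drawn uniformly supplies all 8
  drones; PS: each drone's sister is drawn uniformly *with replacement*.
* **Open mating** — 8 fresh unrelated drones per queen, `N(0, G0/2)`; in
  the two-subpopulation structure, DPQ sister groups are allocated to the
  `−α` / `+α` subpopulation in balanced halves per year. `α` defaults to
  half a genetic SD per trait, so the queen-effect means of the two drone
  populations differ by exactly one `σ_Q`.

Ages: dams reproduce at age 1; DPQs are mated-from at age 2 (drones of the
sister groups selected two years earlier). A queen's father drone therefore
comes from a DPQ three birth-years her senior — the scheme's "2-year sire
path" refers to the DPQ's age when her drones are used.

Every queen's father is an *individual drone* drawn uniformly among her
dam's 8 mates, and the realized genealogy (including drone identities) is
kept. True inbreeding coefficients are computed lazily from it by a
memoized coancestry recursion (`f(mother, son-drone) = (1 + F)/2`, drone
self-coancestry 1) and scale the Mendelian variances. Mortality, selection
ties and every other stochastic choice flow from a single per-replicate
generator, so identical seeds reproduce a replicate bit-for-bit.

What the generator does **not** emulate: finite worker groups, queen
re-mating or supersedure, spatial mating-station structure, overlapping
queen lifespans beyond the fixed schedule, genotyping. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to these real-data features.

## Relationship matrix

All entities — queens, sire entries (identified DPQs, dummy DPQs,
pseudo-sire groups of S sisters, open groups of S = 100 unknown queens) and
worker groups — enter one matrix `A` on the scale `a_ij = 2 f_ij` (twice
the coancestry of random draws from each entity's allele distribution).
Each non-founder row regresses on at most two parents with coefficients
1/2, so `A = T D T'` with unit-triangular `T`, and `A⁻¹` is assembled
directly from the factor (9 nonzeros per entity). Key diagonal rules:

* queens: `a_ii = 1 + F_i`, `F_i = a(dam, mate)/2`;
* open group: `a = d = 1/S` (average over S unknown, unrelated,
  non-inbred members);
* pseudo-sire group of S sisters of `(dam, mate)`:
  `a_PP = (1/S)(1 + a(dam,mate)/2) + (1 − 1/S)·ā_sisters`;
* worker group (queen Q, mate M, D drones):
  `d_W = (2 − a_MM)/(4D)` — the drone-sampling variance of one mating —
  and `a_WW = (a_QQ + 2 a_QM + a_MM)/4 + d_W`.

Two offspring of one mating share the same father drone with `p = 1/D` and
the same father DPQ with `1/D + (1 − 1/D)/S` (`shared_father_probs`; the
value is exactly 1 at S = 1). The default `group_level` mode shares sire
entries across matings exactly as the pedigree records them; same-mating
sibling covariances then omit the O(1/D) same-drone excess (at most
`1/(2D)` on any entry). The `exact_per_mating` mode inserts a latent
drone-pool node per realized mating with diagonal
`a_LL = a_src + (2 − a_src)/D`, which makes the plain 1/2–1/2 recursion
exact for *all* pairs — including same-colony queen/worker-group pairs —
at the cost of a singular `A` (worker groups become exact linear
combinations), so it serves verification, not estimation. A gene-dropping
oracle (unique founder alleles, per-locus re-realization of the drone
allocation, `â_ij = 2 × IBD share`) confirms exact mode within Monte-Carlo
error on every pair; it is the ground truth the recursion is held to.

## Estimation scenarios

The estimation pedigree keeps every dam link and re-encodes only the sire
side: identified single sire (the true DPQ under SS; a uniformly chosen
sister under PS), one dummy DPQ per DPQ dam's sister group (a pedigree
daughter of the true DPQ dam, so her inbreeding and relationships are
computed, not assumed zero), one dummy DPQ per mating, or a shared
pseudo-sire group with S = 3. Open matings map to a single 100-member open
group; the two-subpopulation scenarios either add one open group per
subpopulation, drop the DPQ records, or add a non-genetic effect with
three levels (base drones, subpopulation A, B) to the model — fixed with
the controlled level as zero reference, or random i.i.d. with its own
variance component.

## REML

Worker groups are terminal entities: the worker effect of colony `c`
decomposes exactly as `a_w(W_c) = (a_w(Q_c) + a_w(M_c))/2 + m_c` with an
independent residual `m_c ~ N(0, d_c · var_w)`. The implementation
marginalizes `m_c` into a record-specific residual variance
`r_c = var_e + var_w · d_c`, which removes the worker-group equations
(≈ 45 % of the system) without changing the restricted likelihood; the
test suite verifies the identity against a dense explicit-worker-group
likelihood to machine precision.

The restricted log-likelihood is evaluated exactly through one sparse
factorization of the mixed-model matrix per point
(`−2RL = log|R| + log|G| + log|C| + y'Py + const`; SuperLU with symmetric
minimum-degree ordering). Iterations take Newton steps with the exact
average-information matrix (data-side products and sparse solves) and a
central finite-difference score; steps that leave the parameter space are
bent back by flooring the eigenvalues of the 2 × 2 genetic covariance at
`1e−6 × trace`, and steps that fail to improve the likelihood are
Levenberg-damped. Starting values default to
`(var_w, cov_wq, var_q, var_e) = (5, 0, 5, 35)` (group variance 1.0).
Convergence is declared when the largest relative parameter change falls
below `1e−8` or the likelihood is stationary to ~`1e−10` relative — the
finite-difference score has a noise floor near `1e−5`, so on flat ridges
the parameter criterion alone could chatter indefinitely. On systems up to
2000 records a final polish phase re-localizes the optimum with
Richardson-extrapolated scores (parameter accuracy better than `1e−4`,
used by the oracle comparisons); large batteries skip it, as replicate
noise dwarfs `1e−3`-level localization. Estimates of `r_WQ` are clamped to
`[−1, 1]`; predicted standard errors come from the inverse AI matrix at
the optimum; breeding values are the BLUP solutions at the final
parameters. Degenerate tiny datasets drive the optimum to the boundary of
the parameter space; such fits are flagged non-converged and excluded from
aggregation (but counted).

## Summary statistics

Relative bias and relative SE are the mean and (population) SD across
converged replicates of `(estimate − truth)/truth × 100`; deviations above
20 % are "strong". Errors of `r_WQ` are reported in absolute units (its
true value may be 0). Genetic trends are OLS slopes of cohort-mean
(E)BVs of all BQ candidates — survivors and casualties alike — on birth
year over the closed-nucleus cohorts 5–10, unweighted (cohorts are
equal-sized); the trend error is `(estimated − true)/true` and undefined
when the true slope is 0. Replicate `r` of a battery uses seed
`base_seed + r`; batteries are embarrassingly parallel with a
deterministic merge order.

## Problem sizes used by the test suite

The suite verifies structure on one full 24-family replicate, runs
parameter recovery on 20 replicates of the 12-family nucleus, and
reproduces the bias patterns of the mis-specified scenarios on 8
replicates at 12 families — half the default nucleus, an explicit
configuration axis of the study design under which mean errors are
essentially unchanged while standard errors grow by √2. Tolerances scale
accordingly: a reproduced bias must lie within
`max(3 percentage points, 3 × SD/√n_rep)` of its reference value, with SD
the spread measured at the run's own scale. Full-replication batteries
(200 × 24 families) are overnight runs exposed through
`apisim battery`.

## Known limitations

* Single phenotype per colony and single-trait analysis only.
* No genetic groups for open-mated dams of breeding queens: if BQs (not
  just DPQs) were open-mated to a structured drone population, their mates
  would contribute genes to the nucleus and the open-group device used
  here would not absorb the subpopulation means.
* No probabilistic multi-sire pedigree reconstruction; uncertainty is
  modeled only through the group entries and their sharing probabilities.
* The random-group model estimates a variance from three levels; with
  some parameter sets such fits frequently fail to converge, which is
  reported (convergence rate), not repaired.
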