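# Methods

## The models

`iamfam` implements two structural equation models for indirect assortative
mating on a single phenotype, estimated from extended families built around
twin and sibling pairs.

**iAM-ACE (one generation).** Each adult's phenotype is
`P = a·A + c·C + t·T + e·E`, with additive-genetic (A), sibling-shared
environmental (C), twin-shared environmental (T) and non-shared
environmental (E) factors of unit variance.  Partners do not match on P but
on a latent *sorting factor* `S = ã·A + c̃·C + t̃·T + ẽ·E`.  Assortment is a
copath `μ` connecting the partners' sorting factors: it induces covariance
without changing any variance.  A chain may traverse at most one copath per
partnership, giving

| dyad | covariance |
| --- | --- |
| partner | `μ·Cov(P,S)²` |
| twin/sibling | `a²f + c² + t²·r_t` |
| sibling-in-law | `Cov(P,S_sib)·μ·Cov(P,S)` |
| co-sibling-in-law | `μ²·Cov(S,S_sib)·Cov(P,S)²` |

with `f = 1` for MZ twins and `f = (1 + μã²)/2` for DZ twins and full
siblings at intergenerational equilibrium, and `r_t = 1` for twins, `0` for
ordinary siblings.  The model is identified by fixing `ã = a`; only the
relative composition of S is estimable, so all reported sorting-factor
quantities are shares of Var(S).

**iAM-COTS (two generations).** Two children are added per couple.  The
offspring phenotype is
`P_o = a1·A1' + a2·A2 + p·(P_m + P_f) + c1'·(C_m + C_f) + c2·C2 + e2·E2`,
where `A1'` is the transmitted genetic factor (mid-parent value plus
segregation noise of variance `k = 1 − f_FS`), `A2` the offspring-unique
genetic factor (sibling correlation 0.5, cousin correlation `q` = 0.25 for
MZ-parent cousins, 0.125 otherwise), and `C2`/`E2` offspring-unique
environmental factors.  Three transmission pathways connect the
generations: passive genetic (`a1`), direct phenotypic (`p`) and passive
environmental (`c1'`).  The offspring loading `a1` is a free path; fixing
any one of `a1`, `p`, `c1'` to zero removes exactly one degree of freedom.

**Gene–environment correlation.** When genetic and environmental
transmission co-occur, the offspring's genetic and shared-environmental
components become correlated.  The parent generation's A–C covariance `ω`
is not free: it is constrained to equal the offspring gene–environment
correlation, implemented as `ω = Corr(a1·A1' + a2·A2, F + c2·C2)` with
`F = p·(P_m+P_f) + c1'·(C_m+C_f)`.  We use the phenotype-weighted
composites because the parent-side quantity being matched is the
correlation of A and C *as they enter the phenotype*; an unweighted sum of
factors would equal the offspring gene–environment correlation only when
`a1 = a2` and `c2 = 1`.  The constraint is solved by fixed-point iteration
(start 0, tolerance 1e-10, cap 100 iterations) inside every likelihood
evaluation, keeping the outer optimisation unconstrained.  With `ω ≠ 0`
the path from A to S gains a second leg, so the equilibrium sibling
correlation generalises to `f = (1 + μ(ã + ωc̃)²)/2`, which reduces to the
standard expression when `ω = 0`.

`V_rAC = 2acω` is always reported as its own variance component.  With
`ω ≠ 0`, attributing it to the genetic or the environmental side would be a
convention, not an estimate, so it is never folded into either.

**Variants.**  Direct assortment ties `c̃ = c, t̃ = t, ẽ = e` (−3 df);
direct assortment with measurement error ties only `c̃, t̃` (−2 df); the
social-stratification variant adds one latent factor with equal loading on
every member of the extended family, contributing its variance uniformly to
all cells including the diagonal (+1 df).  The cross-generation loading of
the stratification factor is not settled by the single-generation design;
we apply it to all eight members uniformly.

## Expected covariances

All 4×4 and 8×8 matrices are assembled from explicit latent covariance
blocks per dyad class (within-person, sibling, partner-copath, in-law,
co-in-law) rather than a generic RAM engine, so every cell can be audited
against the path-tracing rules.  Cells of equivalent dyads (e.g.
twin1–partner2 and twin2–partner1) are filled from one computed value and
are therefore bitwise identical.  Matrices are checked for positive
semi-definiteness; violations signal an inadmissible parameter region.

One subtlety: with purely genetic transmission, the MZ avuncular covariance
equals the parent–offspring covariance only when `ẽ = 0`.  An MZ co-twin
shares A, C and T with the parent but not E, so the co-parent-mediated part
of the avuncular path uses `Cov(P,S) − eẽ` where the parent's uses
`Cov(P,S)`.  The test suite asserts equality in the `ẽ = 0` case and the
strict inequality otherwise.

## Estimation

Families are grouped by zygosity and missingness pattern; each group's
likelihood is evaluated from sufficient statistics (count, mean, scatter),
so full-information ML costs the same at 5,000 and 500,000 families.
Optimisation is bounded L-BFGS-B on the natural scale (non-negative focal
paths, unrestricted sorting paths and `μ`), with inadmissible regions
(non-PSD matrix, `|μ|·Var(S)` ≥ 0.9999, failed ω fixed point) mapped to a
large penalty.  Starting values come from moment heuristics (observed
variance, partner correlation); five jittered restarts with a fixed RNG
seed guard against local optima, and nested fits can be started from the
projection of the full fit (`fit_nested_pair`), which also guards against
negative likelihood-ratio statistics.  One mean is estimated per
generation, shared across roles.

Standard errors come from the numerical Hessian of −2LL at the optimum
(`statsmodels.tools.numdiff`); confidence intervals for standardised
quantities use the delta method with a numerical Jacobian.  Likelihood
ratio tests use the standard chi-square reference even for
boundary-adjacent parameters; this is conservative for variance components
and is reported as-is, not corrected.

The empirical module fits semi-constrained covariance matrices (equivalent
dyads equal, means and variances equal within generation) by the same FIML
machinery and standardises to correlations afterwards.  Fisher r-to-z
intervals use the number of complete dyads pooled over equivalent cells as
the effective n; this is an approximation under FIML with constraints,
validated by coverage simulation in the test suite.

## The simulator

The simulator is forward-time and mechanistic, and doubles as the
Monte-Carlo oracle for the analytic covariances:

* genetics follow the infinitesimal model: a child's transmitted additive
  value is the mid-parent value plus segregation noise of variance `k`;
* couples form by rank-matching on S after adding Gaussian noise of
  variance `Var(S)·(1−r)/r`, which realises a partner correlation `r` on S
  while leaving every marginal exactly unchanged (matching only permutes
  individuals) — the copath, mechanically;
* with `ω = 0` the population is iterated (default 15 generations, stopped
  early when Var(A) moves < 1e-4) so the equilibrium genetic variance and
  sibling correlation *emerge* rather than being imposed; realised values
  are verified against `(1 + μã²)/2` in the tests.

With `ω ≠ 0` the parent generation is instead drawn one-shot at the
nominal equilibrium (Var(A) = 1, sibling correlation f, Cov(A,C) = ω):
seeding C from mid-parent genetic values inside the generational loop
creates a feedback with a different stable fixed point (Var(A) ≈ 0.83 at
study-scale parameters), because the ω constraint is a statement about the
stationary state, not a generative rule.  Matching and breeding — the
substantive content of the oracle — remain fully mechanistic in both modes.
Offspring-unique genetic variance is carried by a phenotype-neutral parent
factor U, so the cousin correlation q = 0.25 / 0.125 also emerges from
transmission rather than being inserted.

Randomness comes from a single seeded `numpy` Generator with vectorised
draws; output is bit-reproducible for a fixed seed and n (per-family
substreams are not used — they are incompatible with population-level
matching).

**Default conditions.**  `published_ea_ace()` encodes focal shares
0.46/0.12/0.07/0.35, sorting shares proportional to 0.38/0.55/0.05/0.03
(the printed percentages sum to 101) and a sorting-factor partner
correlation of 0.68.  `published_ea_cots()` was calibrated once by least
squares so the implied quantities match the published two-generation
results (see `presets.py` for the full list).  The default zygosity mix
(2,447 MZ / 3,360 DZ / 206,263 FS families) mirrors the study population.

**What the generator does not emulate:** unbalanced family sizes beyond
the 8-role template, sex-specific paths, convergence after partner
formation, inbreeding, non-Gaussian phenotypes (years-of-education
coarseness), and cohort effects.  Passing tests therefore show the
machinery is internally correct under the model's own assumptions, not
that the model is correct for any real trait.

## Validation design and problem sizes

* Oracle sweep: 5 random parameter sets × 3 zygosities for both models.
  The tolerance band is 3 Monte-Carlo SEs at 200,000 families; each
  entry's point estimate is computed from 400,000 simulated families and
  pooled over equivalent cells, so that across the ~240 entries checked
  the probability of a spurious 3σ exceedance is ~0.5% rather than ~50%.
  The band itself is never widened.
* Parameter recovery: 16 independent replicates of 50,000 families
  (balanced thirds across zygosity groups — the informative design for a
  validation study; the study's own mix is 97% full-sibling families).
  The mean recovered value of every standardised component must lie
  within ±0.05 of the generating value.  A single replicate has an SE
  near 0.1 for the sorting-factor shares, consistent with the published
  CIs, so a per-replicate check would measure noise, not accuracy.
* LRT calibration: 200 replicates of 4,500 families generated under
  direct assortment; the rejection rate of the 3-df test at α = 0.05 must
  be within 3 binomial SEs of 5%.
* All decompositions are conservation-checked exactly (shares sum to 1;
  pathway components sum to the standardised parent–offspring matrix
  entry).

## Known limitations

* The chi-square reference for boundary parameters is conservative.
* The Fisher-interval effective n under FIML constraints is approximate.
* The ω constraint assumes the gene–environment correlation is constant
  across generations; the simulator enforces it only at the observed
  two-generation window.
* Sorting-factor shares are weakly identified without a substantial
  number of MZ/DZ families; standard errors are honest about this.
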