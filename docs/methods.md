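# Methods

## Problem and model

In line and hybrid breeding, a cross of two homozygous parents is
characterized by the distribution of genotypic values among the inbred
lines (doubled haploids or single-seed-descent RILs) that can be derived
from it. Under an additive marker model with intercept β₀ and per-dose
effects u_j, write g_j for twice the effect of the maternal allele at
locus j (g_j = maternal dosage × u_j with {0,2} homozygote coding) and h_j
for the paternal analog. A derived line carries g_j or h_j with
probability ½, so

    μ  = β₀ + Σ_j (g_j + h_j)/2
    σg² = Σ_c Σ_{j,k} cov(Z_j, Z_k),   cov(Z_j, Z_k) = (q_jk/2 − ¼)(g_j − h_j)(g_k − h_k)

where the double sum runs over all ordered locus pairs on a chromosome,
including j = k (the diagonal supplies the single-locus variances
(g_j − h_j)²/4; a pairs-only reading would drop them, which is why the
implementation treats the sum as var(ΣZ_j) = ΣΣcov). Loci on different
chromosomes assort independently and contribute nothing off-diagonal.

q_jk = P(locus k carries the maternal allele | locus j does) = ½ + 2·D_jk,
with D_jk the expected LD between parental-origin indicators:

* (F1)^t-DH:  D = (1−2r)/4 · (1−r)^t, hence q = ½ + (1−2r)/2 · (1−r)^t
* (F2)^t-SSD: D = (1−2r)/(4(1+2r)) · (1−r)^t, hence q = ½ + (1−2r)/(2+4r) · (1−r)^t

The SSD factor 1/(1+2r) is the Haldane–Waddington fixpoint of repeated
selfing; t counts generations of random intermating after the F1, during
which LD decays by (1−r) per generation (infinite-population expectation).
At t = 0 these reduce to the classical q = 1 − r (DH) and q = 1/(1+2r)
(RIL) results. Recombination frequencies come from a pluggable mapping
function; Haldane r = (1 − e^(−2d))/2 (d in Morgans) is the shipped
default and is the mapping function consistent with the no-interference
count-location crossover model the simulator uses. Kosambi or any other
distance→r function can be passed wherever a map function is accepted; it
is an extension point, not a shipped option. cM→Morgan conversion (÷100)
happens exactly once, inside `haldane_r`.

Crosses are ranked by the superior progeny value s = μ + i·σg, or the
usefulness U = μ + i·σg·h, where i = φ(z_p)/p is the standard truncated
normal selection intensity for a selected fraction p and h is the square
root of the heritability, supplied by the user, not estimated.

## Marker effects

Effects are estimated by RR-BLUP: the mixed-model equations

    [ 1′1   1′Z        ] [β₀]   [1′y]
    [ Z′1   Z′Z + λI   ] [u ] = [Z′y]

with raw {0,1,2} dosages in Z (the explicit intercept absorbs column
means; centering would change nothing but the intercept). For m ≤ n the
(m+1)-dimensional system is solved directly; for m > n an algebraically
equivalent n-dimensional kernel solve is used (both paths agree to 1e−8,
property-tested). Residual missing dosages are mean-imputed per marker
before solving; users preferring another imputation can pre-impute.

λ = σe²/σu² defaults to REML: the intercept is projected out with an
orthonormal contrast basis, the projected kernel ZZ′ is diagonalized once,
and the 1-D profile REML criterion is minimized over log λ ∈ [−10, 10]
with tolerance 1e−8. A fixed-λ policy gives exact reproducibility where
needed. Heteroscedastic (per-marker variance) models are out of scope.

## Quality control

Training panels are filtered lines-first, then markers (fixing an order
makes results reproducible; missing fractions for markers are computed on
the surviving lines). Lines are kept at missing fraction ≤ 10% (removal
requires strictly more); markers must be polymorphic, have missing
fraction strictly below 10%, and gene diversity 1 − Σp_i² ≥ 0.1 with
p = mean dosage / 2 over non-missing calls. A marker failing several
filters is counted once, under the first failed filter in the order
polymorphism → missingness → diversity. Heterozygous calls are legal in
the training panel (candidate parents must be fully homozygous).

## Simulation oracles

Three independent routes check the closed forms:

1. **Exact enumeration** (F1-DH, ≤ 20 loci per chromosome): all 2^L gamete
   patterns with probability ½·Π(r_i or 1−r_i) over adjacent intervals,
   exploiting the Markov property of crossover patterns under
   no-interference; chromosomes combine by independence. Agreement with
   the closed form is at 1e−10, and the enumerator itself is guarded by a
   second, naive pure-Python enumeration in the tests.
2. **Two-locus selfing recursion**: the exact 16-state ordered-diplotype
   recursion under selfing, iterated to fixation (total heterozygosity
   < 1e−12), reproduces D/(1+2r) to 1e−8 on a grid of r and initial D.
3. **Monte-Carlo meiosis**: crossover counts per chromosome are Poisson
   with mean equal to the marker span in Morgans, locations i.i.d.
   uniform (count-location, no interference; crossovers outside the
   marker span are unobservable and not generated). DH lines double one
   gamete of an (F1)^t individual; SSD lines self (F2)^t individuals for
   `n_self` generations (default 10, leaving ≈ 2^-10 residual
   heterozygosity per locus) and then fix remaining heterozygous loci by
   a fair coin, an unbiased closure to the F∞ limit the formulas target.
   Intermating runs in a finite population (default N_im = 200 for
   realism; validation tests use 2000 to suppress drift, since the
   formulas assume infinite population size). Replicate r of a run uses
   generator seed `seed + r`, so every replicate is independently
   reproducible.

Monte-Carlo consistency is asserted at 4 standard errors of the
replicate-scatter SE (20000 progeny per case), for DH and SSD at
t ∈ {0, 1, 2}.

## Synthetic data

The generator emulates the statistical structure of a NAM-style study:
founder haplotypes drawn with per-marker allele frequencies uniform on
(0.1, 0.9), a panel bred through 5 generations of random mating with
recombination on the same linkage map used downstream (independent-marker
draws would leave the pairwise variance terms untested), phenotypes
y = β₀ + Zu + e with residual variance scaled to the configured
heritability on the realized panel, and homozygous parents produced as
doubled gametes of panel individuals. The `nam_like_preset` fixes the
study dimensions: 10 chromosomes × 140 cM (1400 cM), 325 markers (one per
4.3 cM on average), 258 training lines, 26 parents, 40 QTL with N(0, 0.3²)
per-dose effects, heritability 0.8, intercept 70 (a days-to-flowering
scale). Missing calls, when enabled, are placed in the training panel
only; parents are delivered complete. What the generator does not emulate:
population structure and kinship beyond 5 generations of mixing,
multi-allelic haplotype blocks, genotyping error, and selection — so
passing tests demonstrate correctness of the formulas and estimation
machinery under the stated model, not predictive accuracy on real panels
(where effect-estimate error substantially attenuates variance
predictions).

## Numerical choices and edge cases

* Variance accumulation is a dense quadratic form per chromosome, O(L²)
  with no distance cutoff — exact, and cheap at a few hundred markers.
* σg² more negative than −1e−9 is a hard error (the matrix is a true
  covariance); values in (−1e−9, 0) are clamped to 0 with a warning.
* Markers monomorphic within a cross stay in μ and contribute 0 to σg².
* Markers with a missing parental dosage are dropped from both parents'
  sums for that cross, with a warning.
* Same-locus pairs use q_jj = 1 by construction; cross-chromosome pairs
  use q = ½ (D = 0).
* Cross enumeration order: unordered pairs, output sorted by s
  descending, ties broken lexicographically by parent ids —
  deterministic end-to-end, and repeated pipeline runs at a fixed seed
  produce byte-identical output files.

## Validation problem sizes

The study-scale comparison uses the nam-like preset: RR-BLUP effects with
REML λ, the 25 crosses of parent 1 with parents 2–26, analytical σg²
(F1-DH, t = 0) against the average of 25 replicate variance estimates
from 200 simulated DH progeny each — the per-cross family size and
replication of the simulation protocol this package's comparisons are
modeled on. The observed Pearson correlation between analytical and
simulated variances is ≥ 0.98 (typically ≈ 0.998); `scripts/acceptance.py`
recomputes it from scratch for any seed.
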