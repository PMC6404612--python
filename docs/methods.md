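# Methods

## The model

An allopolyploid such as hexaploid wheat carries three subgenomes (A, B,
D) whose markers can be separated by chromosome name. `subgblup` partitions
the genetic variance of a line to those subgenomes and their inter-genomic
interactions with a multi-kernel linear mixed model on trial records
y:

    y = 1μ + Xβ + Qγ + Σ_l Z g_l + ε,
    g_l ~ N(0, σ²_l K_l),   ε ~ N(0, σ² I),

where X holds trial (environment) dummies, Q optional population-structure
covariates, and Z maps records to lines. The supported model families are

| family      | random genetic terms                   |
|-------------|----------------------------------------|
| `G`         | whole-genome additive                  |
| `ABD`       | A, B, D subgenome additive             |
| `GxG`       | whole-genome additive + epistatic H    |
| `ABDxABD`   | A, B, D + A⊙B, A⊙D, B⊙D interactions  |
| `ABDxABD+3way` | the above + A⊙B⊙D                   |

### Kernels

The additive kernel is VanRaden's method I,
K = c⁻¹(M−P)(M−P)ᵀ + 0.01·I with P = 1ₙ(2p)ᵀ and c = 2pᵀ(1−p) for
{0,1,2} allele counts. The 0.01 ridge ("nugget") restores full rank after
centering. For inbred boolean scores ({0,1}) we center by column means and
use c = Σp(1−p) — the inbred analog of the same construction; a flag
doubles scores to {0,2} for the literal diploid form. Subgenome kernels
K_A, K_B, K_D apply the identical construction to each subgenome's marker
block with its own frequencies and scaling, which gives the exact partition
c_G·K_G = c_A·K_A + c_B·K_B + c_D·K_D on nugget-free kernels.

The additive×additive epistatic kernel is
H = K⊙K − c⁻²(W⊙W)(W⊙W)ᵀ (W = M−P), equal to 2c⁻²EEᵀ where E contains all
pairwise products w_j⊙w_k (j<k); K⊙K alone is its large-m approximation.
Because no marker is shared across subgenomes, inter-genomic interaction
covariances are exactly Hadamard products of the component kernels
(K_A⊙K_B equals the scaled cross-pair design (c_Ac_B)⁻¹FFᵀ).

Nugget placement: epistatic and interaction kernels are always formed from
nugget-free additive components — a ridge on the components would leak
into the cross terms and break the exact pairwise identities — and every
kernel entering a fit then receives its own 0.01·I. The epistatic H reuses
the additive kernel's c rather than re-estimating a scaling of its own.

### Population structure

Breeding programs violate the Hardy–Weinberg independence of subgenomes,
so realized subgenome kinships are collinear. Since every additive kernel
is proportional to MMᵀ, one SVD of the column-centered whole marker matrix
removes the structure from all subgenomes at once: the first k PC scores Q
(left singular vectors × singular values) become fixed covariates, and the
matrix is rebuilt with those singular values zeroed (M̃, column means
restored) before subgenome kernels are computed. Properties used by the
tests: Qᵀ(M̃ − means) = 0, the removed part lies in span(Q), and the
variance explained by k axes is the cumulative squared-singular-value
fraction.

Numerical choices: the SVD is applied to the column-centered matrix (the
construction is stated without centering in some treatments; centering
makes "variance explained" well defined and the removed axes mean-free);
each singular vector's sign is fixed so its largest-magnitude loading is
positive, making Q reproducible across BLAS builds; Q columns are scaled
to unit SD before entering the fixed design purely for conditioning (fits
are invariant to that scaling); kernels built from M̃ recompute column
means from M̃ itself. The default k = 5 follows the leveling-off of the
subgenome-collinearity diagnostic (pairwise Pearson correlation of
off-diagonal kinship entries) in the motivating datasets; k is always a
user parameter, with the diagnostic as guidance.

## REML

Variance components are estimated by average-information REML. Per
iteration the record covariance V = Σσ²_l ZK_lZᵀ + σ²I is Cholesky
factored; the restricted log-likelihood is evaluated in the
error-contrast form

    l_R = −½[(n−p)log 2π + log|V| + log|XᵀV⁻¹X| − log|XᵀX| + yᵀPy],

which equals the exact density of an orthonormal error-contrast basis and
is therefore checked against a brute-force evaluation in the tests. The AI
matrix ½ yᵀPV_iPV_jPy approximates the Hessian; a Newton step is accepted
only if the likelihood does not decrease, with step halving and an
EM-style fixed-point fallback (θ_i ← θ_i·yᵀPV_iPy / tr(PV_i)) otherwise.
Components pinned at the lower bound (10⁻⁸ × phenotypic variance) with a
downhill score are held in an active set and excluded from the Newton
solve — without this, near-boundary components force the solver into a
slow EM crawl. Convergence is |Δl_R| < 10⁻⁶ between accepted iterations.
Start values split the phenotypic variance equally across all components.

At convergence, boundary components are reported as exactly zero (their
BLUPs are then exactly zero vectors) and all final quantities — likelihood,
AI matrix, fixed effects, BLUPs — are recomputed at the reported
parameters, so the record decomposition y = Xβ̂ + ΣZĝ_l + ε̂ is exact.
Standard errors and sampling correlations of the variance estimates come
from the inverse AI matrix (pseudo-inverse with a warning when boundary
estimates make it singular). AIC is −2l_R + 2t with t the number of
variance parameters, boundary-clamped components included; it is
comparable only across fits sharing data and fixed design, which
`compare_aic` enforces with a warning. The likelihood-ratio test of nested
random structures uses the boundary null ½χ²₀ + ½χ²_d for d added
variance components (a plain χ²_d is available by flag); aliased fixed
columns are avoided by dropping each factor's first level, and any residual
rank deficiency is reported with the offending column names.

## Prediction and cross-validation

The whole-genome value of a line is the sum of all genetic term BLUPs
plus, when structure was removed, the column-centered Qγ̂ contribution;
subgenome breeding values (SGEBVs) are the per-kernel BLUPs. The
quantile report flags lines at or above the 95% quantile per column and
dense-ranks them — the parental-selection view in which the best line per
subgenome is typically not a whole-genome candidate.

Two properties of this design are worth spelling out. First, predicting
an *interaction* effect for a masked line requires off-diagonal structure
in the interaction kernel: entries of K_A⊙K_B are products of additive
kinships, so in an unstructured population (kinships O(1/√m)) the
interaction kernels are near-diagonal and inter-genomic epistasis is real
but unpredictable — cross-validation gains from epistatic kernels only
appear when the population carries relatedness (families, subpopulations),
as breeding programs do. Second, under exactly zero heritability the K = I
benchmark itself correctly shrinks every line value to zero, so "accuracy
≈ 0" is measured against the centered noise line means, and a constant
prediction vector is assigned accuracy 0 by convention.

Cross-validation masks *all* records of each fold's lines, refits, and
predicts the masked lines purely through their kernel relationships
(kernels and allele frequencies are computed once on all genotyped lines,
as all lines are genotyped up front; only phenotypes are masked). Fold
sizes put the remainder r = n − k⌊n/k⌋ entirely into the last fold,
reproducing the 4×289 + 291 split of a 1,447-line population in five
folds. Pooled predictions are correlated once per replicate against
"true" genetic values defined as line BLUPs from the same trial-adjusted
model with K = I — a benchmark that requires some replication of lines
across trials to be identified. Whether the fixed Qγ̂ component belongs in
the predicted "whole genome effect" is ambiguous; it is included by
default (GEBVs are defined with the centered structure term) and excludable
via `include_structure=False`.

## Synthetic data

`simdata` generates inbred {0,1} genotypes on three subgenomes with
unequal marker counts (defaults 550/650/300) and narrower allele-frequency
range on D (its recent single-lineage origin left it the least diverse
wheat subgenome). Subpopulation structure is Balding–Nichols-style: each
of the (default 3) subpopulations draws marker frequencies around the
ancestral value with variance F·p(1−p), F = 0.05 by default; realized MAF
below the floor (0.02) triggers a redraw. Phenotypes follow the subgenome
decomposition G = A+B+D+AB+AD+BD+ABD: additive terms are centered scores ×
normal effects, interaction terms are products of centered cross-subgenome
pairs at 200 sampled causal pairs per term (sampling keeps simulation
O(n·pairs); the kernels model all pairs), and each term is rescaled so its
realized variance equals its configured σ² exactly. Default architecture
σ²_A:σ²_B:σ²_D = 0.3:0.4:0.1 against residual 1.0, epistasis off unless
configured. Records emulate unbalanced multi-environment trials: each line
appears in 3 of 6 trials and 2% of lines are checks replicated in every
trial — the record depth (≈3/line) mirrors, at desk scale, the ~6
records/line of the motivating multi-year breeding dataset and keeps the
K = I benchmark fit identified.

Two generators serve two purposes. The sparse-causal-pair generator above
produces *realistic* architectures, under which part of the interaction
variance is absorbed by additive terms whenever structure correlates
markers across subgenomes — the same absorption seen in real data, which
is why it is used for the qualitative pattern checks (epistasis accuracy
gain, three-way boundary, additive G-vs-ABD equivalence). For solver
*consistency* checks, `simulate_from_model` instead draws each g_l from
N(0, σ²_l K_l) with the model's own kernels, so the generating and fitted
models coincide and estimates must recover the truth up to Monte Carlo
error.

What passing the synthetic tests does not show: the generator has no
linkage disequilibrium within subgenomes, no selection or pedigree
dynamics, no genotype-by-environment interaction, and marker effects are
Gaussian — conclusions about real populations with strong LD structure or
G×E require the real-data pipeline.

## Problem sizes and runtime

Dense linear algebra throughout (no sparse or low-rank switches): a fit
factorizes the n_records × n_records covariance per iteration, which is
the right regime for populations up to a few thousand lines. The shipped
test and acceptance problem sizes — 50 replicates of the 7-component model
at 500 lines × 2 records, 1,000-replicate LRT calibration at 100 lines,
five-fold × 10-replicate CV at 200–400 lines — were chosen so the whole
suite runs on one CPU in minutes while leaving the Monte Carlo error small
relative to the tolerances tested.

## Known limitations

- Mode imputation stands in for the categorical random-forest imputation
  often applied to GBS marker data; it is deterministic and testable, and a
  user-supplied imputer hook is provided, but it ignores between-marker
  correlation. Mode ties break toward the lower (major/reference) score
  with a logged warning. Markers are filtered before imputation.
- Cross-subgenome additive covariance blocks (an unstructured subgenome
  covariance) are out of scope; subgenome effects are modeled independent
  given the kernels.
- AIC parameter counting (variance parameters only) matches common
  mixed-model software but differs across packages; cross-software AIC
  equality is not claimed.
- Under a true zero variance component the REML estimate has an
  asymptotic 50:50 point mass at zero, so a single boundary flag is not
  evidence of absent variance; the tests treat boundary frequencies
  accordingly.
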