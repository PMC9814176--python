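# Methods

This note documents the models, the numerical choices, and what the synthetic
data do and do not establish.

## Genomic relationships

Additive kinship uses VanRaden's form with column-centered dosages,
`w_ij = x_ij − 2p_i`, denominator `2 Σ p_i(1−p_i)`; dominance kinship uses the
orthogonal codes `−2q², 2pq, −2p²` for dosages 0/1/2 with denominator
`4 Σ (p_i q_i)²`. Allele frequencies are computed on the **hybrid** panel —
the prediction targets — not on the parents; for a diallel these differ
materially because hybrids carry excess heterozygosity. A `center=False` flag
reproduces the raw 0/1/2 cross-product (same denominator) for comparison;
only the centered form has the mean-diagonal ≈ 1 + f̄ calibration of a
relationship matrix, which is why it is the default. Missing dosages are
imputed to their conditional expectation (2p additively; 0, the mean
dominance code under HWE, for dominance). QC order is fixed — call rate,
parental heterozygosity, monomorphism, MAF — and each step is logged; the
call-rate and MAF rules remove at `≤ threshold` (strictly-greater survives).

## Enviromic kernel

Weather variables are summarized per phenology window — means for intensive
variables (temperature, humidity, day length), sums for accumulative ones
(rainfall, radiation); which variables are summed is configurable because no
universal rule exists. After column standardization (constant columns
dropped, logged), `K_E = WW'/(tr(WW')/q)`: PSD, trace exactly `q`, invariant
to rescaling `W`. With scaled covariates the columns of `W` are centered, so
`K_E` has zero row sums — environments are characterized by *contrasts*. Two
consequences worth knowing: (i) G×E generated through `K_E` is automatically
a pure interaction (it sums to zero across environments within a genotype);
(ii) with few environments the diagonal of `K_E` can be very uneven, which
matters for design (below).

## Stage-1 analysis

Fixed-block trials (RCBD with two blocks) are solved by OLS with genotype and
block as fixed classes; the BLUE is the genotype least-squares mean.
Augmented trials use a single-variance-component REML: with
`V = σ²_e (I + γ ZZ')` and block-diagonal `ZZ'`, the restricted likelihood is
profiled down to a 1-D bounded search over `log γ` (Woodbury identities per
block, no dense `n × n` algebra), `γ ∈ [10⁻⁶, 10⁶]`. Checks simply enter the
genotype class. Heritability uses a method-of-moments decomposition on the
genotype × environment cell-mean table after removing block means within
environments (exact for a balanced RCBD), with harmonic-mean replicate counts
under imbalance, negative estimates truncated at zero, and the entry-mean
formula `H² = σ²_g/(σ²_g + σ²_ge/n_E + σ²_e/(n_E n_rep))`. Plant height gets
the same z-score standardization as the other traits (no rank-based
transform).

## Kronecker kernels and the spectral budget

Composite kernels store factors only; entries are factor products, blocks are
elementwise factor-block products, and the spectrum is the outer product of
factor spectra — a panel of `n_g · q · n_t` cells never materializes its
`cells²` covariance. Cells are ordered genotype-major, environment next,
trait fastest, and always addressed by id tuples in public interfaces. The
budget is the smallest `n` whose top-`n` eigenvalues reach 98% of the total.
This rule only bites when the genomic factor has a decaying spectrum:
unrelated founders give a flat spectrum and a budget near the full panel,
which is why the synthetic founders are structured (below).

## Training-set optimization

Fitness is the mean prediction error variance of unphenotyped cells under a
unit-variance GBLUP with ridge `λ = σ²_e/σ²_u` (default 1, matching h² = 0.5
on the standardized scale). The GA is generational with elitism (2), size-n
set encoding, tournament selection (3), union-crossover down-sampled
uniformly to size n, per-cell swap mutation (rate 0.05), a bounded FIFO tabu
map (capacity 10,000) whose hits reuse the stored fitness instead of
re-evaluating, and a look-ahead step: one steepest single-swap refinement of
the best elite per generation (exhaustive when `n(m−n) ≤ 200` swap pairs,
else over 40 sampled pairs). Termination: 60 generations or 15 without
improvement. Everything is deterministic given the seed. A check genotype's
full environment × trait cells are carried outside the budget; design sizes
are reported as budget cells and check cells separately.

**A limitation found and kept visible.** PEV is an absolute-error criterion,
while prediction ability is a per-environment Pearson correlation —
scale-free. On a 3-environment panel the uneven diagonal of `K_E` lets the
GWT kernel's PEV optimum concentrate cells in the highest-variance
environment, lowering PEV while starving the others; the optimized-beats-
random comparison is therefore run on the GET kernel, where prior cell
variances are even across environments and the advantage is real (≈ +3–7%
mean PA at the smallest budget on the bundled panel). With many environments
(real `K_E` diagonals are milder) this pathology weakens, but it is inherent
to PEV-mean and worth knowing before trusting a GWT design at small `q`.

## Bayesian multi-kernel GBLUP

Under genotype-major ordering the five models' random terms have Kronecker
cell covariances: A: `G_a ⊗ J_q`; D: `G_d ⊗ J_q`; AE: `G_a ⊗ I_q`;
DE: `G_d ⊗ I_q`; W: `J_g ⊗ K_E`; AW: `G_a ⊗ K_E`; DW: `G_d ⊗ K_E` (J =
all-ones); multi-trait mode appends `Σ_T` as a trailing factor. The sampler
works on the observed cells only (likelihood restriction — no data
augmentation): each term's covariance among observed cells is
eigendecomposed once, coefficients are sampled in that basis where the full
conditionals are diagonal, environment(-by-trait) means get a flat prior,
variance components scaled-inverse-χ² full conditionals with df 5 and scale
from var(y) split equally across terms and residual (an R² = 0.5
convention). Unobserved cells receive the posterior mean of their conditional
expectation through the kernel cross-covariance; the reported cell-level sds
quantify that projected posterior, not the full predictive variance.

Defaults are 10,000 iterations, burn-in 1,000, thinning 2; effective sample
sizes per variance chain use the initial-positive-sequence estimator. In
multi-trait mode the residual is a single shared variance: traits enter
standardized, so a common residual scale is reasonable, and it keeps the
coefficient updates diagonal (an unstructured trait residual would force a
dense solve per term per iteration). The genetic covariance between traits
is fully honored through `Σ_T`, which is supplied as known — in this pipeline
it is always available from the full BLUE table (`sigma_t_from_blues` is the
estimated/plug-in path). Variance components can be held fixed
(`fix_variances`), which makes the sampler a Monte-Carlo solver for the
closed-form mixed-model equations — the basis of the ridge-oracle test.

## Synthetic data: what it emulates, what it does not

Founders are inbred (dosage 0/2), drawn from a small number of ancestral
groups diverging by a Balding–Nichols model (defaults: 3 groups, Fst 0.25).
This structure is deliberate: real breeding panels are structured, and the
spectral budget rule is only meaningful when the genomic spectrum decays.
Hybrids follow a partial diallel; genetic values sit on the standardized
scale with main genetic variance 1, split `v_a = 0.85 / v_d = 0.15`
(dominance orthogonalized against additive per trait so the split is exact),
and the target genetic correlation matrix is imposed exactly on both
components by re-mixing marker-driven values (linear combinations of marker
effects remain marker effects; hybrids span only the parental subspace, so
raw draws scatter too widely at realistic panel sizes). G×E deviations are
marker-driven with environment covariance `K_E` (default) or compound
symmetry; under `K_E` they are pure interactions (zero row sums).

Residual variance is calibrated so the *classical* entry-mean H² matches its
target: pure (sum-to-zero) interactions map into the classical iid frame as
`σ²_ge → V_ge·E/(E−1)`, `σ²_g → V_g − V_ge/(E−1)`, and the calibration uses
those. This caps the feasible H² — with `gxe_ratio` 0.8 and three
environments the ceiling is ≈ 0.6 — so the strong-G×E bundled panel
("mini-hel": 30 hybrids × 3 environments × 3 traits, RCBD) uses H² targets
(0.45, 0.5, 0.5) rather than the 0.6–0.8 typical of real maize trials. The
defaults elsewhere (H² 0.62/0.78/0.80, `gxe_ratio` 0.3, correlations
GY–PH −0.5, GY–EH −0.5, PH–EH 0.8 after the ear-height re-expression) are in
the range reported for tropical maize. Not emulated: linkage maps and LD
decay along chromosomes, selection history, spatial field trends, outliers,
and year-to-year weather carryover — so passing tests show the *machinery*
is correct and the qualitative claims hold under the assumed generative
model, not that real-data accuracies will match.

## Problem sizes and runtime

The test suite and the acceptance script run on scaled-down instances chosen
as the smallest panels where each effect is measurable: the 270-cell
mini panel for end-to-end claims (10 seeds, 2,000-iteration chains), 300
observations for variance-component recovery (10,000 iterations), a 6-cell
kernel for the exhaustive GA oracle, and ≤ 200-dimensional kernels for the
spectral oracle. The full suite completes in about half a minute on one CPU;
the acceptance script in about one minute.

## Seed discipline

Every stochastic component (generator, GA, Gibbs, partitions, random
designs) takes an explicit seed; the pipeline fans a single global seed out
to stages via `seed·1000 + offset` with a fixed offset table, so any stage
can be reproduced in isolation and identical configs give hash-identical
artifact manifests.
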