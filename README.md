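# otsgp — optimized training sets for multi-trait multi-environment genomic prediction

`otsgp` is a Python library for designing **selectively-phenotyped training
sets** in hybrid crop breeding and for fitting the multi-kernel Bayesian GBLUP
models that exploit them. It targets the situation a maize (or any
single-cross) breeder faces every season: thousands of candidate hybrids,
several trial environments, several traits — and a field-phenotyping budget
that covers only a fraction of the genotype × environment × trait grid. The
library answers *which cells of that grid to phenotype* so that the rest can
be predicted from markers and environmental data.

## What it does

1. **Markers** — QC of parental inbred genotypes (call rate, parental
   heterozygosity, monomorphism, MAF), in-silico F1 hybrid synthesis, and
   genomic relationship matrices: additive
   `G_a = W_A W_A' / (2 Σ p_i(1−p_i))` with VanRaden centering, and dominance
   `G_d = W_D W_D' / (4 Σ (p_i q_i)²)` with codes `−2q², 2pq, −2p²`.
2. **Enviromics** — daily weather summarized over crop phenology windows
   (0–14, 15–35, 36–60, 61–90, 91–120 days after emergence) into an
   environment × covariate matrix `W`, and the enviromic kernel
   `K_E = WW' / (tr(WW')/q)` — a relationship matrix for environments.
3. **Stage 1** — per-environment genotype BLUEs (fixed blocks for an RCBD,
   1-D profile REML for augmented designs with random blocks), an ear-height
   re-expression `EH_tr = −|EH − 80|` that makes its selection direction
   oppose yield, z-scoring of all traits, entry-mean broad-sense heritability
   `H² = σ²_g / (σ²_g + σ²_ge/n_E + σ²_e/(n_E n_rep))`, and the trait
   covariance `Σ_T`.
4. **Kernels** — lazy Kronecker kernels over (genotype, environment, trait)
   cells: `Σ_G ⊗ I_q ⊗ Σ_T` ("GET", environments unrelated) and
   `Σ_G ⊗ K_E ⊗ Σ_T` ("GWT", environments related through weather), with
   spectra computed factor-wise (never materializing the full matrix).
5. **Design** — the phenotyping budget `n` is the number of leading kernel
   eigenvalues holding 98% of total variance (the spectral core-size rule);
   the actual cells are chosen by a look-ahead genetic algorithm with a tabu
   memory minimizing the mean GBLUP prediction error variance
   `PEV(T) = mean_{i∉T} [K_ii − K_iT (K_TT + λI)⁻¹ K_Ti]` of the
   unphenotyped cells. Three GA samples form OTS 1; pairwise unions OTS 2;
   the full union OTS 3; size-matched random designs are the control.
6. **Prediction** — five nested Bayesian GBLUP models fitted by Gibbs
   sampling: M1 (env + additive + dominance), M2 (+G×E), M3 (+W),
   M4 (M3 + G×E), M5 (M3 + G×W), single- or multi-trait (known `Σ_T`),
   with CV1 (new hybrids) / CV2 (incomplete trials) evaluation by Pearson
   prediction ability per trait × environment.
7. **Economics** — phenotyping costs (4 USD/plot grain yield, 2 USD/plot
   heights), genotyping (20 USD per parental line; hybrids assembled in
   silico), accuracy `PA/√H²` per trait, and **response to selection per
   10,000 USD** = mean accuracy / total cost × 10,000.

A first-class synthetic-data generator (`otsgp.synthdata`) produces complete
studies — structured inbred founders, partial-diallel hybrids, weather-driven
environments, three correlated traits with additive + dominance + enviromic-
driven G×E, RCBD or augmented plot records — with known truth, so every stage
is testable end-to-end without any external download.

## Worked example

`examples/03_training_set_design.py` sizes and optimizes a training set on a
bundled synthetic panel (30 hybrids × 3 environments × 3 traits):

```
panel: 270 candidate cells (30 hybrids x 3 envs x 3 traits)
98% of kernel variance is carried by 75 components -> budget n = 75 (28% of the grid)
GA design PEV-mean: 0.4631
random designs PEV-mean: median 0.5242, best of 30 0.5020
```

The genetic algorithm's design has a lower mean prediction error variance
than every one of 30 random designs of the same size — the unphenotyped 72%
of the grid is better covered by kinship and enviromic similarity.
`examples/04_gblup_models.py` then fits all five models under CV1 on the same
panel:

```
mean CV1 prediction ability (grain yield, 10 partitions):
  M1  0.487   env + additive + dominance
  M2  0.518   M1 + G x E
  M3  0.493   M1 + enviromic main effect (W)
  M4  0.522   M3 + G x E
  M5  0.525   M3 + G x W (reaction norm on enviromic similarity)
```

Models carrying an interaction term (M2/M4/M5) predict held-out hybrids
better than the main-effects models (M1/M3), because the panel's G×E is
driven by environmental similarity that those terms can model. The other
examples cover marker QC and kinship (01), the enviromic kernel (02), and
the per-dollar economics (05).

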