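# Methods

## Model

The method treats driver-gene discovery as a proximity problem on a directed
gene-interaction network. A random walker starts at a sample's altered genes
and restarts with probability β per step; its stationary visiting
distribution defines how much "relevance" each gene receives from the
sample's alterations. Two channels are diffused independently — somatic
mutation weights and absolute log2 fold-change of expression — and a gene's
integrated score in a sample is the *minimum* of its two channel scores.
The minimum implements a double-high requirement: differential expression is
treated as a downstream consequence of mutation, so genuine drivers should
be proximal to both signals, while a gene that is extreme in only one
channel (a sparse-sample mutation artifact, a noisy expression outlier) is
demoted to its weaker channel. Per-sample scores are converted to ranks and
summed across samples, which makes the cohort ranking insensitive to
per-sample scale and robust to individual outlier samples.

Assumptions worth stating: the interaction network is taken as given and
treated as the gene universe (genes outside it are dropped from both omics
with a logged count — they can never be candidates); edge direction carries
signal, so normalization uses in- plus out-degree; both channel matrices are
column-normalized so each sample contributes unit mass per channel, making
the elementwise minimum meaningful on a common scale.

## Normalization and diffusion

With aᵢⱼ = 1 iff there is an edge j→i, the normalized adjacency entry is
(aᵢⱼ + aⱼᵢ)/(deg_out(j) + deg_in(j)). Columns of genes with at least one
edge sum to exactly 1; isolated genes (possible after subsetting) keep zero
columns and their diffusion column reduces to β·eⱼ, so they retain but never
gain relevance. The influence matrix D = β[I − (1−β)A^norm]⁻¹ is computed by
a dense LU solve; this is exact and fast up to the ~10⁴-gene networks the
method targets. A fixed-point iteration (D ← βI + (1−β)A^norm D, tolerance
1e-9) is provided for larger problems; the two agree to 1e-6 on test graphs,
and both are checked against the truncated Neumann series
β·Σ(1−β)ᵏ(A^norm)ᵏ in the tests. β = 0 is rejected because the resolvent is
singular for a column-stochastic matrix; β = 1 returns the identity exactly.
The default β = 0.48 balances diffusion against retention of the source
signal and is exposed in the configuration.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.48 | restart probability; 1 = no diffusion |
| `pseudocount` | 0.5 | added to numerator and denominator of the fold change; bounds ALFC at zero expression while preserving monotonicity |
| `prdsm_threshold` | 0.308 | strict lower bound for keeping a synonymous variant in the filtered PrDSM scheme |
| `sift_transform` | `as_stated` | raw SIFT score used as the missense weight; `one_minus` flips to deleteriousness orientation |
| `top_n` | 50 | evaluation cutoff (precision/F1/partial AUC) |
| `stratify_top_k` / `sd_threshold` | 7 / 5.0 | biomarker count and expression-SD filter for stratification; the SD threshold is on the scale of the supplied expression matrix (abundance-scale units assumed) |
| `robustness_repeats` | 10 | random subsets per size in the robustness protocol |

Note the SIFT convention: in SIFT itself *low* scores mean deleterious, yet
the published weighting uses the raw score; `as_stated` reproduces that
behavior, and the discrepancy is deliberately left to the user via
`sift_transform`.

## Design choices where the design was open

- **Expression normalization.** Column normalization is applied to the
  expression channel as well as the mutation channel: the elementwise
  minimum is only meaningful when both channels carry unit column mass.
- **Multiple variants per gene per sample.** Weights are summed (a heavier
  deleterious burden should inject more heat); the uniform scheme caps the
  sum at 1, which restores the binary mutation-status matrix exactly.
- **Sample universe.** The integrated analysis runs on the intersection of
  samples present in the MAF and the tumor expression matrix; membership is
  decided before weighting, so a sample whose variants are all dropped by a
  scheme keeps an all-zero (reported) column. Single-omics rankings use
  their full cohorts.
- **Ranks and ties.** Rank 1 is the highest score; ties receive average
  ranks (keeping every column's rank sum at n(n+1)/2); all final orderings
  break ties lexicographically, making outputs byte-identical across
  platforms.
- **Min-source proportions.** The share of min-score cells supplied by each
  channel is cell-weighted over (gene, sample) cells of the top genes; exact
  ties count toward both channels, so the two proportions can exceed 1 in
  sum.
- **Partial AUC.** T counts gold genes restricted to the ranking's gene
  universe by default (configurable), since genes absent from the network
  are unreachable; tie-breaking between positives and negatives follows the
  strict rank order.
- **Combined centrality baseline.** Degree and betweenness centrality live
  on incomparable scales, so each is min-max rescaled to [0, 1] before
  averaging. Betweenness is computed on the directed graph with unit
  weights.
- **Stratification.** Biomarker expression is z-scored per gene before
  k-means (otherwise the SD > 5 selection would make high-variance genes
  dominate by scale); k-means uses 25 restarts under a fixed seed and keeps
  the best inertia. The *high-risk* label is assigned by survival, not by
  cluster index: the group with the smaller restricted mean survival time up
  to the last common follow-up time is high-risk, ties broken toward the
  group with more events.
- **Robustness seeding.** Each (subset size, repeat) draw uses an RNG seeded
  by (master seed, size, repeat), so extending the size grid never perturbs
  earlier draws.

## Synthetic cohorts

The fixture generator emulates the structure the method assumes and nothing
more. Networks are directed random graphs in which a small hub set (5% of
genes) is preferentially chosen as edge endpoints, mirroring the elevated
connectivity of known cancer genes; the planted drivers are the top-degree
hubs. Per sample, drivers mutate with probability 0.4 and background genes
with 0.01; variant classes are drawn from a fixed mix (55% missense, 20%
synonymous, 10% stop-gain, 10% frameshift, 5% in-frame) with uniform [0, 1]
deleteriousness scores. Expression has a log-normal per-gene baseline
(median 50, log2-SD 1.5); in a tumor sample each mutated driver and its
first network neighbors shift by +2 on the log2 scale over log2-normal noise
(SD 0.5) relative to the paired normal. Effects are planted on first
neighbors only — recovering multi-hop structure is the diffusion's job, so
fixture and method stay independent. Survival is exponential (baseline mean
1000 days) with a threefold hazard for samples carrying at least two mutated
drivers and 30% uniform censoring. The defaults (200 genes, 5 drivers, 100
samples) were frozen after a calibration run in which every seed recovered
all five drivers in the top 20.

What the fixtures do *not* model: mutational signatures, copy number,
expression covariance between genes, batch effects, or realistic
gene-symbol vocabularies. Passing tests therefore demonstrate the
correctness of the machinery and recoverability of planted signal, not
performance on real tumor cohorts.

## Numerical notes and degenerate inputs

Self-loops are removed at network load (an input reduced to nothing by this
is an error). All-zero score columns (a sample with no network-mapped
alterations) are left zero, reported, and receive total-tie average ranks.
Column-stochasticity of A^norm and D is asserted to 1e-10/1e-8; the
closed-form/series agreement to 1e-6. A clustering that returns a single
non-empty group yields a flagged degenerate stratification with no p-value
rather than an error. The log-rank implementation delegates to lifelines
and is validated against a hand-tabulated observed-minus-expected
computation in the tests.

## Known limitations

The ranking inherits the network's biases: highly connected genes attract
relevance from many sources, and genes missing from the network are
invisible. Only coding mutations and RNA expression are integrated; copy
number, methylation and non-coding variation are out of scope. The SD > 5
biomarker filter is scale-dependent and should be adjusted for
non-abundance-scale expression units. Robustness and recovery statements in
the test suite are calibrated on the synthetic conditions above at modest
problem sizes (hundreds of genes/samples), chosen so the whole suite runs in
seconds.
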