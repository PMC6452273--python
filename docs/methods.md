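# Methods

`cooccur-phylo` tests whether pairs of binary genome traits — in the
motivating application, components of DNA double-strand-break repair
systems ("system" traits) and CRISPR-Cas subtypes ("cas" traits) scored as
present/absent across bacterial genomes — are associated over and above
what shared ancestry and gene frequencies would produce. The pipeline has
a phylogeny-naive screening stage and a phylogeny-aware confirmation stage,
followed by clustering of the significant calls.

## Screening stage

**Frequency filter.** Only traits with presence frequency strictly between
`freq_lo` (default 0.01) and `freq_hi` (default 0.99) are analysed: traits
that are nearly absent or nearly universal carry almost no co-occurrence
information and destabilise the 2×2 statistics. The inequalities are
strict.

**Φ coefficient.** For each (system, cas) pair we build the 2×2 table
a = both present, b = system only, c = cas only, d = both absent, and
compute

    Φ = (ad − bc) / √((a+b)(c+d)(a+c)(b+d)),

identical to the Pearson correlation of the two 0/1 indicator vectors.
If any margin is zero, Φ is undefined; the pair is reported untestable
(never silently set to 0) and excluded from downstream aggregates — a
silent zero would bias the ΔΦ t-test toward the null.

**Control genes and ΔΦ.** Each system trait is matched to `k_controls`
(default 10) control traits sampled without replacement among controls
whose frequency lies within ±`margin` (default 0.01, absolute) of the
target's; when fewer than k qualify the margin widens in +0.01 steps (each
widening logged) up to 0.5. ΔΦ = |Φ(system, cas)| − mean |Φ(control, cas)|
over the matched controls, and a one-sample one-sided t-test asks whether
mean ΔΦ > 0 across all pairs. A zero-variance ΔΦ sample is degenerate: the
test returns p = 0 if the common value is positive and p = 1 otherwise,
with a warning.

**Fisher/Bonferroni.** Each pair's table gets a two-sided Fisher exact
test (minimum-likelihood convention: the p-value sums the hypergeometric
probabilities of all same-margin tables no more probable than the observed
one). Significance is declared at p ≤ α/m with α = 0.05 and m = the number
of pairs actually tested in the run; m is recorded in every output row
rather than hard-coded, since it depends on the filtering outcome.

## Phylogeny-aware stage

Only pairs passing the Bonferroni screen proceed (the screen gates the
expensive test; this ordering is part of the pipeline contract).

**Models.** Two binary traits define four joint states, ordered
(0,0), (0,1), (1,0), (1,1). The *independent* model gives each trait its
own gain and loss rate (4 parameters); the *dependent* model lets each
trait's gain/loss rates differ according to the partner's state
(8 parameters). Instantaneous double transitions are forbidden in both, so
the independent model is nested in the dependent one via the embedding
q13 = q24 = α₁, q31 = q42 = β₁, q12 = q34 = α₂, q21 = q43 = β₂.

**Likelihood.** Felsenstein pruning over the four joint states, with
per-branch transition matrices exp(Q·t) computed from a shared
eigendecomposition of Q (fallback: scaling-and-squaring when Q is near
defective; contract: rows of exp(Qt) sum to 1 within 1e-10, zero-length
branches map to the exact identity). Partial likelihoods are rescaled per
node and the scale accumulated in log space. Impossible data under a
frozen chain return −∞. The root is combined with a uniform prior over the
four states by default — standard in ML discrete-character software and
agnostic about ancestral states; a stationary prior is available by flag
(with it, likelihood under the reversible embedded model is invariant to
re-rooting along a branch, which the test suite checks).

**Fitting.** Maximum likelihood over log-rates (bounds [1e-8, 1e3]) with
multi-start L-BFGS-B: one moment-based start (rates sized to one expected
event per mean root-to-tip depth, split by observed frequency) plus
`n_starts − 1` seeded random starts; convergence tolerance 1e-10 on the
objective. Under either supported root prior the independent model's
likelihood factorises per trait, so its two traits are fitted separately as
2-parameter problems with the closed-form 2-state transition matrix. The
dependent fit always includes the embedded independent MLE among its
starts and keeps the best of the raw start values and optimizer outputs,
so the nesting inequality lnL_dep ≥ lnL_indep holds by construction and a
negative LRT statistic can only be optimizer noise (it is clipped at 0).

**LRT and the median rule.** The statistic 2(lnL_dep − lnL_indep) is
referred to χ² with 4 degrees of freedom (the parameter-count difference
of the two models as defined). Robustness to phylogenetic uncertainty is
assessed by recomputing the LRT p-value on a set of bootstrap(-like)
trees; a pair is called significant when the median p across that set is
strictly below the threshold (default 0.01). Bootstrap-tree fits are
warm-started from the main-tree MLE with `boot_n_starts` (default 1)
fresh starts, which changes nothing statistically (each fit still
maximises its own likelihood) but cuts the cost several-fold.

## Signed matrix and clustering

Pairs significant under *both* the Bonferroni screen and the median rule
get sign(Φ) ∈ {−1, +1}; everything else is 0. Rows (cas) and columns
(system) with no nonzero entry are dropped, and the remaining matrix is
clustered with agglomerative single-linkage ("nearest neighbour")
clustering on Euclidean distance, rows and columns independently. The
linkage itself is delegated to `scipy.cluster.hierarchy`; correctness is
validated in the tests against a naive O(n³) oracle using tie-invariant
summaries (sorted merge heights and the cophenetic/minimax matrix), which
coincide for every valid tie-breaking rule. Output is leaf orders plus
merge tables, not a rendered figure.

## Synthetic data

The generator produces data with the statistical structure the pipeline
assumes, so every stage can be calibrated without any external dataset:

- **Trees**: pure-birth (Yule) trees. Starting from two root lineages,
  each lineage splits at rate λ; after the n-th lineage appears the
  process runs one further Exp(nλ) waiting time and tips are sampled, so
  E[root-to-tip depth] = Σ_{k=2..n} 1/(kλ). Yule rather than birth–death:
  the application's trees are inputs, not objects of inference, and one
  parameter suffices for calibration.
- **Trait pairs**: the 4-state chain sampled down the tree with exact
  per-branch transition probabilities, root state uniform, stationary or
  fixed.
- **Controls**: i.i.d. Bernoulli columns at chosen frequencies by default —
  a deliberately phylogeny-free null that isolates the screening stage from
  the phylogenetic one. An optional on-tree mode instead evolves each
  control as a 2-state chain with rates tuned to its target stationary
  frequency, giving controls realistic phylogenetic autocorrelation. There
  is also a phylogeny-free correlated-pair generator (bivariate Bernoulli
  with a planted Φ) used to calibrate the ΔΦ procedure in isolation.
- **Bootstrap stand-ins**: copies of a tree with each branch length
  multiplied by an independent lognormal factor with mean 1 and chosen
  coefficient of variation (topology unchanged), emulating the
  branch-length component of reconstruction uncertainty. Real alignment
  bootstraps also perturb topology; that is out of scope here, so the
  median rule's robustness claim is demonstrated against branch-length
  noise only.

What the synthetic data do *not* emulate: horizontal transfer hotspots,
lineage-specific rate variation, missing data, and the mutual-exclusivity
structure of functionally analogous gene families. Passing the calibration
tests therefore shows the machinery is correct and well-calibrated under
its own model, not that the model captures every feature of real genome
collections.

All generators and the pipeline honour a single master seed: per-stage
substreams are derived as `SeedSequence([seed, crc32(stage_name)])`, so
reruns are byte-identical and stages are reproducible in isolation.

## Problem sizes used in the test suite

The statistical tests run at the sizes the package's own calibration
experiments use: 200-tip trees with all baseline rates 1 (mean root-to-tip
depth ≈ 4.9, i.e. several expected gain/loss events per lineage);
200 replicates for the type-I experiment (median rule over 5 jittered
trees per replicate, CV 0.15); 100 replicates for LRT power under the
planted dependent model (partner-conditional 5× gain / 5× slower loss) and
12 full-pipeline recovery runs; 1000 genomes for the ΔΦ calibration.
Exactness oracles (Φ vs Pearson, Fisher vs exact enumeration, pruning vs
exhaustive state summation, clustering vs naive single linkage) run on
1000, 1000, 100 and 100 random instances respectively.

## Known limitations

- The LRT's χ²₄ reference is asymptotic; at a few hundred tips it tends to
  be mildly conservative. The calibration tests bound the empirical
  type-I rate within [0.01, 0.10] at nominal 0.05 rather than pinning it.
- ML fitting only; no Bayesian (RJ-MCMC) variant, no covarion/hidden-rate
  extensions, no >2-state traits, no ancestral-state output.
- Control genes are matched on frequency only, as in the screening design;
  any residual phylogenetic structure in real control genes is not
  modelled by the Bernoulli null.
- The bootstrap-median rule treats the supplied tree set as exchangeable;
  it does not weight trees by support.
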