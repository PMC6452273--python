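# cooccur-phylo

Phylogeny-aware screening of evolutionary associations between two families
of binary genome traits — built for presence/absence profiles of DNA
double-strand-break repair components ("system" traits) and CRISPR-Cas
subtypes ("cas" traits) across bacterial genomes, but applicable to any two
labelled sets of binary traits on a phylogeny.

Naive co-occurrence counts conflate three things: genuine evolutionary
dependence, the background frequency of the genes, and shared ancestry
(related genomes inherit both traits together). The pipeline addresses all
three in two stages:

1. **Screen (phylogeny-naive).** For every (system, cas) pair with
   presence frequency strictly inside (1%, 99%), build the 2×2 table
   (a = both present, b/c = one only, d = both absent) and compute
   Φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)). Each system trait is compared
   against k frequency-matched control genes (±1% margin, widened stepwise
   if needed): ΔΦ = |Φ_pair| − mean|Φ_controls|, aggregated in a one-sided
   t-test of mean ΔΦ > 0. Pair-level independence is tested with a
   two-sided Fisher exact test under Bonferroni correction (α = 0.05 over
   the m pairs tested).
2. **Phylogenetic confirmation.** Pairs passing Bonferroni are re-tested
   with a correlated-evolution likelihood-ratio test: maximum-likelihood
   fits of an independent (4-rate) and a dependent (8-rate) gain/loss
   Markov model over the four joint trait states (Felsenstein pruning;
   double transitions forbidden), LRT = 2(lnL_dep − lnL_indep) against
   χ²₄, repeated across a set of bootstrap trees; a pair is significant if
   the **median** p across trees is < 0.01. Surviving pairs enter a signed
   {−1, 0, +1} matrix (sign = sign Φ) that is clustered with single-linkage
   (nearest-neighbour) hierarchical clustering.

A seeded synthetic-data module (Yule trees, Markov trait evolution,
Bernoulli control genes, branch-length-jittered bootstrap stand-ins) makes
every stage testable and calibratable without downloads. See
`docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import cooccur_phylo as cp

# a 200-genome clade and a pair of traits that evolve dependently:
# cas gained 5x faster and lost 5x slower when the system is present
tree = cp.simulate_tree(n_tips=200, birth_rate=1.0, seed=1)
model = cp.PairRateModel.dependent(
    q12=1, q13=1, q21=1, q24=1, q31=1, q34=5, q42=1, q43=0.2
)
pair = cp.simulate_pair_traits(tree, model, seed=2)

fit_i = cp.fit_model(tree, pair, "independent", n_starts=3, seed=3)
fit_d = cp.fit_model(tree, pair, "dependent", n_starts=3, seed=3)
stat, p = cp.lrt(fit_i, fit_d)
print(f"lnL independent = {fit_i.loglik:.2f}")
print(f"lnL dependent   = {fit_d.loglik:.2f}")
print(f"LRT = {stat:.2f}, chi2_4 p = {p:.2e}")
```

Output:

```
lnL independent = -213.20
lnL dependent   = -199.82
LRT = 26.76, chi2_4 p = 2.22e-05
```

The dependent model improves the log-likelihood by ~13.4 units; the LRT
rejects independent evolution at p ≈ 2e-5 — the planted dependence is
detected. Running the same data through the median rule over jittered
trees, or a whole trait table through `cp.run_all(...)`, adds the
bootstrap-robustness and multiple-testing layers:

```bash
cooccur-phylo run-all --config config.yaml --outdir out/
```

writes `screen_results.tsv`, `phylo_results.tsv`, `signed_matrix.tsv`,
clustering orders/merge tables and a machine-readable `summary.json`;
reruns with the same config and seed are byte-identical.

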