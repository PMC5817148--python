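# traitrates

Transition-rate analysis of a discrete (five-state) trait on rooted
phylogenies: Mk-type likelihoods, an eight-model maximum-likelihood family
with AIC selection, two phylogenetic-signal tests, reversible-jump MCMC
over rate-class models with Bayes factors, ancestral-state estimation, and
cross-method rate synthesis. Everything runs on synthetic data generated
in-repo; no external downloads are required.

## Layout

| module | contents |
| --- | --- |
| `traitrates.treeio` | `PhyloTree` / `TraitData`, Newick + trait-TSV I/O, star-tree construction, MRCA |
| `traitrates.mklik` | Q matrices, `exp(Qt)`, pruning log-likelihood, node marginals, brute-force oracles |
| `traitrates.mlfit` | rate-model schemes (single / symmetric / unconstrained), threshold-and-bin reduced models, multi-start ML fitting, AIC selection, ML ancestral states |
| `traitrates.parsignal` | Sankoff minimum transitions (+ exhaustive oracle), permutation test, star-vs-tree ΔAIC |
| `traitrates.rjmcmc` | reversible-jump sampler over rate-class partitions, model classification, Bayes factors vs. matched prior-only runs, Geweke diagnostic, Bayesian ancestral states, posterior rate means |
| `traitrates.summarize` | rate standardization/averaging/ranking, Spearman correlations, report assembly |
| `traitrates.synthdata` | Yule trees, CTMC trait simulation with recorded histories, the preset two-clade scenario |
| `traitrates.pipeline` | `run_all` orchestration, `RunConfig`, CLI |

## CLI

```sh
traitrates simulate --variant small --seed 1 --out data/
traitrates fit-ml  --tree data/tree.nwk --traits data/traits.tsv --seed 1 --out out/
traitrates signal  --tree data/tree.nwk --traits data/traits.tsv --n-perm 10000 --out out/
traitrates mcmc    --tree data/tree.nwk --traits data/traits.tsv --mu 100 \
                   --generations 1000000 --sample-freq 500 --out out/
traitrates mcmc    --tree data/tree.nwk --traits data/traits.tsv --mu 100 \
                   --generations 1000000 --sample-freq 500 --prior-only --out out/
traitrates run-all --config config.yaml --seed 1 --out out/
```

`run-all` executes the whole workflow (ML selection, signal tests, one
posterior + one prior-only chain per configured prior mean, Bayes factors,
ancestral states per tagged clade, summary tables) and writes a
`manifest.json` with seeds and SHA-256 checksums of every output.
Outputs are deterministic for fixed seeds.

A config file (YAML or JSON) mirrors the fields of
`traitrates.pipeline.RunConfig`, e.g.

```yaml
scenario: small          # or tree_file/trait_file for your own data
prior_means: [1, 10, 100, 500]
n_generations: 1000000
sample_freq: 500
n_permutations: 10000
seed: 1
```

## Output tables (`run-all` / `summarize`)

- `signal_table.tsv` — minimum transitions, permutation null median, p-value, star-tree ΔAIC, best AIC/k.
- `bf_k_mu*.tsv` / `bf_models_mu*.tsv` — log Bayes factors (natural log and log10) per free-parameter class and per model signature.
- `rate_mean_se.tsv` — per-transition mean ± SE of standardized rates across (method × dataset) combinations, with ranks and a top-4 flag.
- `rate_correlations.tsv` — Spearman correlation matrix across combinations.
- `ancestral_states.tsv` — ancestral state probabilities per tagged clade per method.
- `trace_mu*_{posterior,prior}.tsv` — MCMC samples (iteration, canonical model signature, k, all 20 realized pair rates, lnL, tree index) with a JSON metadata sidecar.

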