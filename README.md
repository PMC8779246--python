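# bprsnet

Regularized partial-correlation network analysis of ordinal symptom ratings,
built around the 18-item Brief Psychiatric Rating Scale (BPRS) as used in
large schizophrenia cohorts such as REAP-AP (n = 1438, items scored 1 "not
present" to 7 "very severe").

The package is for researchers who treat a symptom scale as a network — the
"psychonectome" view, in which symptoms and their mutual dependencies *are*
the object of analysis — and need the full inferential chain from raw ordinal
ratings to a defensible network with stability diagnostics:

1. **Polychoric correlation.** Each item is modeled as a discretized latent
   standard normal; thresholds come from the marginal category proportions
   and each pairwise latent correlation ρ maximizes the contingency
   likelihood Σ_ab n_ab log π_ab(ρ), with π_ab a bivariate-normal rectangle
   probability.
2. **EBIC-tuned graphical lasso.** The latent correlation matrix S enters the
   L1-penalized Gaussian likelihood
   `log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|`, fit along a descending
   100-point λ path; the extended BIC
   `−2ℓ(Θ) + E log n + 4 γ E log p` (γ = 0.5) selects λ, and the selected
   precision matrix is reported as partial correlations
   `w_ij = −Θ_ij / √(Θ_ii Θ_jj)`.
3. **Centrality.** Strength `s_i = Σ_j |w_ij|`; closeness and betweenness on
   shortest paths with edge length `1/|w_ij|`.
4. **Spin-glass communities.** Simulated annealing of the configuration-null
   Potts Hamiltonian
   `H(σ) = −Σ_{i<j} (a_ij − γ s_i s_j / 2m) δ(σ_i, σ_j)` on absolute weights
   (γ = 0.5, up to 17 spins, geometric cooling 1 → 0.01 at factor 0.99).
5. **Resampling inference.** Case-dropping bootstrap with CS-coefficients
   (the largest drop fraction keeping subsample/full centrality correlation
   ≥ 0.7 with 95% probability; > 0.25 interpretable, > 0.5 preferred),
   nonparametric bootstrap intervals, and an exact/Monte-Carlo permutation
   test of mean centrality between node groups (e.g. the 8 DSM vs 10
   non-DSM BPRS symptoms, enumerable exactly: C(18,8) = 43,758).
6. **Synthetic cohorts.** A latent-Gaussian copula generator with a planted
   sparse block network and per-item marginals matched to the published
   REAP-AP frequency table, so every step can be validated against known
   ground truth without any patient data.

## Worked example

```python
from bprsnet import (make_truth_network, sample_ordinal, fit_network,
                     centrality_table, spinglass_partition)

truth = make_truth_network(seed=1)              # planted 10/3/5 blocks
data = sample_ordinal(truth, n=1438, seed=2).data
net = fit_network(data)
print(f"{net.edge_count} of {net.possible_edges} edges "
      f"({100 * net.edge_fraction:.1f}%)")
print(net.edge_list().head(3).to_string(index=False))
table = centrality_table(net)
print("most central:", table.top_node("strength"))
part = spinglass_partition(net, seed=7)
print("communities:", part.n_communities)
```

prints

```
71 of 153 edges (46.4%)
node_i node_j   weight
   GRA    DEP 0.292303
   EMO    CON 0.274541
   EMO    GRA 0.246065
most central: GRA
communities: 2
```

i.e. the EBIC-selected network keeps 71 partial-correlation edges, the
strongest linking grandiosity and depressive mood at w = 0.29; grandiosity
has the largest summed edge mass, and the annealer finds two symptom
clusters in this replicate (false cross-block edges can merge two of the
three planted blocks; see `docs/methods.md`).

The `examples/` directory has one short script per capability:
descriptive tables, network estimation, centrality + communities,
stability + permutation inference, and the one-call pipeline with a
machine-readable report. A thin CLI wraps the same calls
(`bprsnet simulate | estimate | centrality | communities | stability |
permtest | report`).

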