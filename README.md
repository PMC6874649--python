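# pollinet

Priority plant selection for pollinator restoration from quantitative
plant–bee visitation networks.

## The problem

Habitat restoration for bees works best when the plant species sown are the
ones that actually sustain bee communities, but plant species are far from
interchangeable: a few generalists with distinct visitor assemblages carry
most of a network's species and visits. Given a quantitative bipartite
network — a plants × bees matrix of visit counts `a_ij` — `pollinet`
answers four questions a restoration planner would ask:

1. **Which plants?** Rank plants by species-level network metrics and
   simulate community recovery "from scratch": plants are added in
   multiples of two following the ranking until a coverage target
   (by default 80% of the original bee species, or of the original visits)
   is met. Rankings are compared with a random baseline (exact
   hypergeometric expectation or Monte Carlo) and a genetic algorithm over
   fixed-size plant sets; an exhaustive minimum-set search serves as a
   testing oracle on small networks.
2. **Can phylogeny substitute for interaction data?** Test whether the
   selected species are phylogenetically clustered: standardized effect
   sizes of the mean pairwise distance (MPD → NRI) and mean nearest-taxon
   distance (MNTD → NTI) against abundance-weighted null draws from the
   species pool, with negative scores indicating clustering; plus
   between-network phylogenetic turnover (`comdist`) and ANOSIM by biome.
3. **Which families?** Compare each family's observed selection count with
   its expected count (family share of plants × selection size) across
   networks using one-sample z-tests.
4. **What do the restored networks look like?** At equal plant number,
   compare links, interaction diversity exp(H), bee specialization d′,
   network specialization H2′, robustness to random bee extinctions, and a
   proxy for exported pollination function — the Müller shared-visitor
   index, `PAC[i,k] = Σ_j (a_ij/A_i·)(a_kj/A_·j)`, summed over selected
   acting plants and divided by the full-network sum.

The species-level metrics are normalised degree (ND), interaction strength
(ST, the sum of bee dependencies `a_ij/A_·j`), closeness and betweenness
centrality on the one-mode plant projection, and functional
complementarity (FC, the leave-one-out contribution to the total branch
length of a UPGMA dendrogram over plant visitor profiles). Specialization
uses the standardized Kullback–Leibler measures d′ (species) and H2′
(network).

Because comprehensive tropical visitation datasets are scarce, the package
ships a first-class synthetic-data generator (`pollinet.synthetic`) that
reproduces the statistical structure these analyses assume — lognormal,
supergeneralist-dominated abundances, a sparse specialization term, family
structured ultrametric phylogenies, and an optional Brownian
(phylogenetically conserved) generalism trait — so every stage is testable
without downloads.

## Worked example

```python
from pollinet import indices, restoration, phylo
from pollinet.synthetic import SyntheticConfig, gen_tree, gen_conserved_scenario

tree, fams = gen_tree(n_families=8, species_per_family=5, seed=11)
net, trait = gen_conserved_scenario(tree, 1.0, SyntheticConfig(
    n_bees=20, total_visits=1200, plant_abundance_sigma=1.3,
    specialization=0.3, seed=11, network_id="demo"))

m = indices.species_metrics(net)
print(m.sort_values("strength", ascending=False).head(3).round(3))
res = restoration.run_strategy(net, "ST", "bee_richness", 0.8, metrics=m)
rnd = restoration.run_strategy(net, "random", "bee_richness", 0.8)

dist = phylo.cophenetic_distances(tree)
top10 = list(m.sort_values("strength", ascending=False).index[:10])
out = phylo.ses_phylo(top10, list(dist.index), dist, stat="MNTD",
                      n_null=10_000, seed=0)
```

Output:

```
            normalized_degree  strength  closeness  betweenness  functional_complementarity  total_visits
Fam06_sp04               0.95     2.308        1.0        0.006                      49.817           161
Fam06_sp01               0.90     2.060        1.0        0.006                      11.745            99
Fam06_sp03               0.85     1.553        1.0        0.006                      13.999            67
ST: 2 of 40 plants (5%) reach 80% bee richness
random: 6 plants (15%)
top-10 strength plants: negative NTI = -2.137, rank p = 0.0153
```

Reading this: the three strongest plants all come from one family
(`Fam06`), ranking by interaction strength reaches the 80% bee-richness
target with 5% of the flora versus 15% under random selection, and with a
fully conserved generalism trait the ten strongest plants are
significantly phylogenetically clustered (negative NTI, rank p < 0.025).

A full pipeline over a directory of networks runs from the command line:

```bash
pollinet synth --out demo --seed 0          # write a synthetic dataset
pollinet run-all --config config.yaml       # metrics, simulations, phylo,
                                            # families, evaluation, manifest
```

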