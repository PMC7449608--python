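# ecoassembly

Null-model quantification of stochastic versus deterministic community
assembly in replicated microbial communities.

## The problem

When replicate bioreactors (or plots, ponds, hosts) are run under identical
conditions, their microbial communities still diverge. How much of that
between-replicate turnover is ecological drift — random birth, death and
sampling of individuals — and how much is deterministic selection by the
environment? `ecoassembly` answers this for feature-by-sample count tables
(ASVs, genera, or functional genes; one read = one individual) using two
complementary null models, plus the diversity partitioning and abundance
partitioning they depend on.

## The models

**Hill-number diversity and the β-partition.** α-diversity is measured as
Hill numbers ^qD (q = 0 richness, q = 1 Shannon exponential, q = 2 inverse
Simpson). Between-replicate diversity is the multiplicative β-partition

    β = 1 − ᾱ/γ

with ᾱ the mean within-replicate ^qD and γ the ^qD of the pooled community;
β runs from 0 (identical replicates) toward 1 − 1/n (n fully distinct
replicates at q = 0).

**Deterministic strength (DS).** The null hypothesis is ecological
equivalence: all reads of a treatment group's replicates are pooled and
redistributed uniformly at random into samples of the original sizes
(preserving per-reactor totals, pooled relative abundances, and γ). After
10,000 such shuffles,

    DS = |βobs − β̄exp| / βobs,   SI = 1 − DS,   ratio = β̄exp / βobs.

DS near 0 means observed turnover is what random placement produces
(stochastic assembly); DS near 1 means strong deviation (deterministic
assembly). A ratio below 1 says observed β-diversity exceeds chance.
DS is also computed separately for the *common* (top 90% of each sample's
accumulated reads) and *rare* fractions, after rescaling the common matrix
to the rare matrix's sampling effort without losing any community member.

**βMNTD / βNTI.** Phylogenetic turnover between two communities is the
abundance-weighted β-mean-nearest-taxon distance; its standardized effect
size against 1,000 random tip shuffles is the β-nearest taxon index.
|βNTI| > 2 indicates significantly deterministic turnover (βNTI < −2:
homogeneous selection; βNTI > +2: variable selection). The method's
assumption — niches conserved at short phylogenetic distances — is checked
with a 50-bin Mantel correlogram of taxon niche differences against
phylogenetic distance (1,000 permutations, 5% FDR).

A synthetic replicated-bioreactor generator (lognormal metacommunity,
Yule tree, Brownian niche trait, neutral / divergent / convergent
filtering regimes) makes every stage testable end to end without
external data.

## Worked example

```python
from ecoassembly import ScenarioConfig, simulate_scenario, ds_time_series

neutral  = simulate_scenario(ScenarioConfig(seed=101, n_days=5))
filtered = simulate_scenario(ScenarioConfig(seed=102, n_days=5,
                                            filter_mode="divergent",
                                            filter_strength=1.5))
for name, b in [("neutral", neutral), ("divergent", filtered)]:
    ds = ds_time_series(b["table"], b["design"], q=0, n_reps=1000, seed=201)
    print(name, round(ds["DS"].mean(), 3), round(ds["ratio"].mean(), 3))
```

prints

```
neutral 0.064 1.044
divergent 0.635 0.365
```

Four replicate reactors drawn neutrally from one metacommunity have mean
DS ≈ 0.06 — their β-diversity is almost exactly the random-placement
expectation (ratio ≈ 1). When each replicate applies its own environmental
filter, DS rises to ≈ 0.64 and the ratio drops to ≈ 0.37: observed
turnover is nearly three times the chance expectation, a deterministic
signature.

The same workflow is available from the shell:

```sh
ecoassembly simulate --s 100 --depth 10000 --seed 101 --outdir sim
ecoassembly ds-null sim/counts.tsv --design sim/design.tsv --out ds.tsv
ecoassembly run-all --simulate-seed 101 --outdir results/pipeline
```

## The analysis

Numbered drivers under `analysis/` run the full study on the synthetic
scenarios and write their tables under `results/`:

1. `01_simulate_scenarios.py` — neutral, divergent and convergent scenarios
2. `02_diversity_profiles.py` — Hill-number profiles and β-partitions
3. `03_ds_null_model.py` — DS time series and the filter-strength sweep
4. `04_common_rare_partition.py` — common/rare split and fraction-resolved DS
5. `05_phylo_turnover.py` — βMNTD/βNTI per time point
6. `06_phylo_signal.py` — niche values and Mantel correlograms

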