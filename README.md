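# trophonet

Automated reconstruction and analysis of trophic (food-web) networks from
trait-annotated species lists.

Ecologists rarely get to observe who eats whom. What they do have — for
thousands of protected sites such as wetland inventories — are raw species
lists. `trophonet` turns such a list into an ensemble of plausible binary
trophic networks and analyses their structure, so that theoretical network
ecology (modularity, key "bridge" species, robustness to sampling loss) can
be applied to the actual species conservation policies care about.

## The model

Each species *i* gets a **trophic position** on a [0, 1] niche axis from its
relative log body mass among the community's consumers:

```
n_i = (log10 m_i − log10 m_min) / (log10 m_max − log10 m_min)
```

with primary producers pinned at *n* = 0. Each consumer draws a **feeding
optimum** `c_i ~ U[r_i/2, n_i]` and a **feeding range** `r_i` (classic mode:
`r_i = n_i·x`, `x ~ Beta(1, 1/(2C) − 1)`, so the expected connectance is the
target `C`; a literal `Beta(1, 2C)` mode is kept for fidelity experiments).
A directed link *i → j* ("*i* consumes *j*") requires

1. **allometry** — `n_j ∈ [c_i − r_i/2, c_i + r_i/2]`;
2. **diet compatibility** — one of *i*'s coarse-grained diet categories
   (herbivore, insectivore, piscivore, …) must match *j*'s resource class
   derived from its taxonomy (Insecta → insect, fish clades → fish, …);
3. **producers** — eaten with probability `C` by any grazer irrespective of
   size (herbivores rarely consume the whole plant, so the allometric
   relationship vanishes).

A staged relaxation then guarantees that every consumer eats something and
every producer is eaten. Because `c` and `r` are redrawn per replicate, an
ensemble of replicates samples the *potential* diet of each species; the
number of replicates scales as `K / log10(N)`.

Around this core the package provides: missing-trait enrichment (allometric
mass-from-length plus nearest-taxonomic-relative inference), the full
descriptor suite (connectance, generality/vulnerability distributions,
Cohen chain statistics, loops, nestedness, modularity, clustering,
topological consistency, model error against the pure niche-model
baseline), Louvain partitions with participation-coefficient bridge-species
ranking, rarefaction experiments (taxonomic collapse, random and
functional removal), 2-layer × 2-stage multilayer builds, link-by-link
validation against reference webs, and a synthetic wetland-community
generator so everything runs without downloads.

## Worked example

```python
import numpy as np
from trophonet import (
    BuildParams, CommunityConfig, build_ensemble, compute_descriptors,
    generate_community, louvain_partition, bridge_species,
    topological_consistency,
)

table = generate_community(CommunityConfig(n=60, seed=42))
print(f"site {table.site_id}: {table.n_species} taxa, {len(table.producers)} producers")

ens = build_ensemble(table, BuildParams(C=0.12, seed=7), n_replicates=10)
net = ens.networks[0]
ds = compute_descriptors(net, table, max_chains=50_000, max_loops=5_000)
print(f"links={net.n_links} CON={ds['CON']:.3f} TOP={ds['TOP']:.2f} "
      f"BAS={ds['BAS']:.2f} INT={ds['INT']:.2f} NEST={ds['NEST']:.2f}")

part = louvain_partition(net, seed=0)
print(f"MOD={part.modularity:.3f} PART={part.n_modules}")
top_id, score = bridge_species(net, part)[0]
print(f"top bridge species: {top_id} (participation {score:.2f})")

tc = topological_consistency(ens)
stable = sum(1 for v in tc.link_tc.values() if v >= 0.9)
print(f"{len(tc.link_tc)} distinct links observed, {stable} in >=90% of replicates")
```

prints

```
site synthetic_42_n60: 60 taxa, 18 producers
links=257 CON=0.071 TOP=0.15 BAS=0.30 INT=0.55 NEST=0.61
MOD=0.253 PART=4
top bridge species: magngen7_sp8 (participation 0.75)
1113 distinct links observed, 1 in >=90% of replicates
```

Read: the first replicate of this 60-species wetland has 257 links
(connectance 0.071); 30% of species are basal, 15% top predators. Louvain
finds 4 modules at modularity 0.25, and the highest-participation species —
the one whose links spread most evenly across modules — is an omnivorous
plant-guild taxon bridging compartments. Across the 10 replicates most
links are facultative (appear in few replicates) while a small core is
nearly obligate, mirroring the specialist/generalist split in the diets.

The same pipeline is scriptable from the shell:

```
trophonet synth --n 45 --seed 3 --out site.csv
trophonet validate site.csv
trophonet build site.csv --seed 7 --out ens/
trophonet describe ens/ --out descriptors.csv
trophonet modules ens/replicate_000.csv --seed 1 --out mod/
trophonet rarefy site.csv --kind taxonomic --rank genus --seed 2 --out rarefy.csv
trophonet multilayer site.csv --seed 4 --out ml_edges.csv
```

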