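# nnc — niche-neutral metacommunity simulation and diagnostics

`nnc` is a spatially explicit, individual-based metacommunity simulator with
its full diagnostic battery.  Local communities of fixed size `J` sit on a
torus lattice with an environmental gradient `E` in one of three structures
(random, linear wave, periodic humps).  Every time step each individual
founds a new species with probability `ν` (point-mutation speciation with
niche conservatism); remaining slots are refilled from a mixture of local
birth and environment-filtered immigration from the 8 torus neighbors
(dispersal rate `m`).  Guilds — groups of species sharing a Gaussian
environmental niche — are the unit of ecological difference.

Runs started from *monodominance* (one species per guild) and from
*infinite diversity* (one species per individual) share all randomness;
once every guild's initial lineages have coalesced or been annihilated the
two runs agree up to a species relabeling, which defines the convergence
time to the dynamic equilibrium.  The diagnostic battery analyzes the
centered window of model communities at that point: Simpson/Rao effective
numbers and functional uniqueness/redundancy, Hellinger-based RDA variation
partitioning with forward-selected orthogonal environmental polynomials and
PCNM spatial eigenfunctions, component classification, k-means guild
structure with the simple-structure-index criterion, hierarchical
within/among-habitat spatial models, and Moran's I correlogram / Mantel
autocorrelation analysis.

## Layout

| module | contents |
| --- | --- |
| `nnc.landscape` | torus grids, 1/8 Moore dispersal weights, environmental gradients, central window |
| `nnc.species_pool` | guild niches, guild size splits, the two coupled initializations |
| `nnc.engine` | the per-step update, lineage tracking, convergence detection, coupled runs |
| `nnc.diversity` | Gaussian niche overlap, Simpson, Rao's Q, uniqueness/redundancy |
| `nnc.ordination` | Hellinger, orthogonal polynomials, (partial) RDA, permutation tests, forward selection |
| `nnc.spatial_stats` | PCNM, Sturges classes, Moran's I correlograms, Mantel tests |
| `nnc.diagnostics` | variation partitioning, component classification, guild structure, hierarchical model, autocorrelation analysis |
| `nnc.workbench` | experimental-design enumeration (825 scenarios), presets, batch runner, summaries |

## CLI

```sh
nnc landscape --seed 1 --out landscape.csv
nnc simulate --seed 1 --mode coupled --out run/
nnc experiment --preset reduced --seed 1 --out records.json
nnc report --records records.json --out summary.csv
```

Configuration files are flat YAML (keys like `grid.width`, `J`, `nu`, `m`,
`env.structure`, `guilds.g`); every stochastic stage takes an explicit
seed, and scenario records are byte-identical across reruns of the same
seed.

The `reduced` preset (8×8 lattice, J = 8, ν = 0.01) shrinks the full
design to 21 scenarios that converge in seconds each; `paper_full` runs
the complete 825-scenario design at full lattice scale (compute-heavy).

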