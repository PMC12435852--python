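# gczone

Spatial analysis of germinal-center (GC) zonation for single-cell spatial
transcriptomics. Given one GC — cell positions in micrometers plus a
cells × genes count matrix — `gczone`:

1. scores the 169-gene dark-zone (DZ) and 201-gene light-zone (LZ) spatial
   signatures per cell and classifies each cell by the combined score
   `dzlz = dz − lz` (DZ if `dzlz > 0.3`, LZ if `dzlz < −0.3`, intermediate
   otherwise);
2. smooths the phenotypes into contiguous DZ/LZ *regions* by iterative
   neighbor-majority reannotation on a 30-μm radius graph, gated by a ≥70%
   per-region purity requirement, and extracts the DZ–LZ boundary polyline;
3. profiles T-cell subtype enrichment in 10-μm bins of signed boundary
   distance (−100 μm DZ side … +100 μm LZ side), fits the OLS slope, and
   calls the trend (increasing / decreasing / random) against a Monte-Carlo
   envelope built by reassigning the subtype to random subsets of the
   observed cell positions (count fixed, default 10,000 permutations,
   95% envelope);
4. tests immune exclusion between two cell sets by comparing observed
   nearest-neighbor distances against label-permuted controls with a
   two-sided Wilcoxon rank-sum test.

A synthetic-tissue generator (`gczone.synthetic`) produces disc-shaped
two-zone GCs with negative-binomial counts, logistic T-cell gradients and
complete-spatial-randomness controls, so the full pipeline runs and is
tested without any external data. Bulk matrices can additionally be
stratified into DZ-like / LZ-like / intermediate groups from the same
signatures. See `docs/methods.md` for the underlying models and defaults.

## Worked example

Run the whole pipeline on a simulated GC (2,000 cells, signature effect 1.5,
10% label noise — the generator defaults):

```sh
gczone run --simulate --seed 1 --n-sim 1000 --out-dir demo
```

This writes `regions.csv`, `boundary.geojson`, `profile.json`,
`report.json` and `manifest.json`. For seed 1 the report contains:

```
phenotype_counts  {'DZ': 982, 'LZ': 1018}
region_counts     {'DZ_region': 1074, 'LZ_region': 926}
purity            DZ 0.822   LZ 0.893   (11 sweeps to convergence)
Tfh        slope=0.00133   envelope=[-0.000223, 0.000227]  -> increasing
naive_CD8  slope=-0.000141 envelope=[-0.000223, 0.000213]  -> random
```

Reading: both regions comfortably pass the 70% purity gate. The simulated
Tfh subtype (logistic gradient toward the LZ) has an enrichment-vs-distance
slope of 1.3 × 10⁻³ per μm, far above the 95% Monte-Carlo envelope, so its
enrichment significantly *increases* from DZ to LZ; the uniformly placed
naive-CD8 control falls inside the envelope and is called random.

The same stages are available as subcommands (`simulate`, `score`,
`segment`, `gradient`, `exclusion`) and as library functions
(`gczone.run_pipeline`, `gczone.analyze_gradient`,
`gczone.nn_exclusion_test`, …).

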