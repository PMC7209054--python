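# paleodiv

Spatially standardized regional palaeodiversity estimation from fossil
occurrence data.

## The problem

Counting fossil species per time interval across the whole world does not
measure global diversity, because the spatial footprint of the sampled fossil
record changes drastically between intervals — in the terrestrial record it
expands roughly exponentially toward the present.  Sampling-intensity
standardization (rarefaction, extrapolators) cannot fix this: new *places*
contribute new species no matter how evenly each place is sampled.

`paleodiv` implements the alternative: estimate diversity only for
palaeogeographical regions of approximately equal spatial extent.  Fossil
localities are binned into ~100-km equal-area grid cells; an accretion
algorithm enumerates, for each time bin, *all* nested sets of adjacent
occupied cells; each candidate region is characterized (minimum-spanning-tree
length over cell centres as the measure of spatial extent, occupied-cell
counts, literature references, sample-coverage statistics, richness
estimates); regions are filtered to a target MST length (±10 %) plus
quality criteria, de-duplicated into clusters of overlapping regions, and
cluster-median richness through time is compared across diversification
models (constrained vs expansionist) by AICc.

Richness estimators: face-value species counts; coverage-based rarefaction /
shareholder quorum subsampling (SQS) with analytic interpolation and
extrapolation at quorums 0.4/0.6/0.8; Chao 2 on collection incidences; the
'squares' extrapolator; optional grid-cell rarefaction (subsampling occupied
200-km cells to a quota proportional to MST length).

A synthetic fossil-record generator with known true diversity and
controllable spatial-sampling bias makes every stage verifiable without any
external download; see `docs/methods.md` for the model.

The intended users are palaeobiologists and macroecologists analysing
occurrence databases (e.g. Paleobiology Database exports) or testing
sampling-standardization methodology.

## Worked example

Generate a synthetic record with *flat* true diversity but an exponentially
growing sampled area, run the pipeline, and contrast the biased worldwide
curve with the spatially standardized one:

```python
from paleodiv import (make_scenario, simulate_world, sample_fossil_record,
                      PipelineConfig, run_pipeline,
                      first_difference_fit, interval_slope_test)

wcfg, scfg = make_scenario("bias_demo", seed=1)
world = simulate_world(wcfg)
table = sample_fossil_record(world, scfg)

cfg = PipelineConfig(bins=world.bins, spacings=(100.0, 200.0, 500.0),
                     mst_targets=(1000.0,), quorums=(0.6,), seed=1)
res = run_pipeline(table, cfg)

ts = res.timeseries.set_index("bin_id")
fit = first_difference_fit(ts["face_value"], ts["occupied_cells_500"])
print(f"face value ~ occupied cells (first differences): "
      f"r2={fit.r_squared:.2f}, slope={fit.slope:.2f}")

pts = res.diversity_points[1000.0]
slope, p, n = interval_slope_test(pts, 115, 5)
print(f"standardized SQS trend: slope={slope:.4f}/Myr, p={p:.2f} ({n} clusters)")
```

Output:

```
face value ~ occupied cells (first differences): r2=0.58, slope=0.44
standardized SQS trend: slope=-0.0005/Myr, p=0.69 (59 clusters)
```

Although true regional diversity is constant, 58 % of the bin-to-bin change
in the worldwide face-value species count is explained by change in the
number of occupied 500-km grid cells — the spatial-sampling artefact.  The
spatially standardized series (median SQS at quorum 0.6 for 1000-km regions,
59 region clusters) shows no significant trend, recovering the truth.

The same pipeline runs from the shell:

```bash
paleodiv simulate bias_demo --seed 1 --outdir data/
paleodiv run data/bias_demo_occurrences.csv --seed 1 --outdir results/
```

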