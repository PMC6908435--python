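# patchkit

Quantitative analysis of clathrin-mediated endocytosis (CME) imaging in
budding and fission yeast: stage detection on centroid particle tracks,
ensemble alignment and averaging, ratiometric molecule counting against a
120-copy sfGFP nanocage standard, and STORM structure-length measurement —
plus a synthetic-data generator that emulates the motion and intensity
structure the analysis assumes, so every stage is testable without any
imaging data.

It is written for cell biologists quantifying diffraction-limited endocytic
patches from live-cell movies (ImageJ Particle Tracker output) and
super-resolution localization lists.

## The analysis

**Stage detection.** An endocytic patch trajectory `(t, x_t, y_t, I_t)` has
three motion phases: stationary assembly, directed inward movement during
membrane invagination, and diffusive wander of the released vesicle. Two
per-track references anchor ensemble alignment:

* the **inflection point** `t_inflection` — the stationary→directed
  transition, located by least-squares changepoint fitting of the
  flat/ramp/release shape on the distance-from-origin series
  `d_t = |r_t − r_0|`, refined by a continuous flat→drift fit on the 2D
  positions (the published regression-residual rule
  `argmin(d_t − d_t,linear)` is available as `method="residual"`);
* the **half-max time** `t_0.5` — the first rising crossing of
  `0.5 · max(I_t)`, used for actin markers (Abp1/Fim1).

Aligned tracks are rescaled (intensity to each track's maximum,
displacement measured from the position at the reference) and averaged on a
uniform relative-time grid. **Scission** is inferred from the jump in the
across-track displacement SD: the first bin beyond the early directed phase
where the SD exceeds `k` × its baseline median for `m` consecutive bins
(defaults k = 2, m = 3). The **invagination speed** is the OLS slope of the
mean displacement between the reference and scission, after subtracting the
stationary-phase noise floor in quadrature.

**Molecule counting.** Absolute copy numbers come from the intensity ratio
to an extracellular standard (a 60-subunit protein nanocage carrying 120
sfGFP):

```
count = 120 · (I_patch / exposure_patch) / (I_cage / exposure_cage) · brightness correction
```

with mEGFP counted as 14% brighter than GFP. Proteins never imaged against
the standard are resolved through a **ratio chain**: measured pairwise
peak-intensity ratios form a graph; anchored nodes (scSla1 = 168,
scLas17 = 102, scMyo5 = 199) propagate counts along edges, multiple anchor
paths combine by geometric mean, and cycle products deviating from 1 by
more than 20% raise consistency warnings.

**STORM lengths.** A localization cloud is rotated so its principal axis is
horizontal; the structure length is the largest pairwise distance among
points whose y-coordinates differ by at most 0.01 px (160 nm/px), and the
vesicle rule (`longest_axis`) drops the y constraint.

## Worked example

Resolve the bundled measured ratio table into absolute copy numbers:

```python
from patchkit import resolve_ratio_chain, datasets

resolved = resolve_ratio_chain(datasets.yeast_ratio_graph())
for p in ("spPan1", "scSla2", "spEnd4", "scSac6", "spMyo1", "spArc5"):
    path = " > ".join(resolved.provenance[p]["path"])
    print(f"{p:8s} {resolved[p]:7.1f}  via {path}")
```

prints

```
spPan1     218.4  via scSla1 > spPan1
scSla2     132.6  via scLas17 > scSla2
spEnd4     123.3  via scLas17 > scSla2 > spEnd4
scSac6     546.3  via scSla1 > scAbp1 > spFim1 > scSac6
spMyo1     171.3  via scMyo3+scMyo5 > spMyo1
spArc5     302.4  via scSla1 > spArc5
```

— e.g. fission-yeast Pan1 peaks at ~218 molecules per endocytic site,
reached from the nanocage-anchored scSla1 count through one measured ratio.

Simulate a fission-like track set and run the full stage pipeline:

```python
from patchkit import EventParams, generate_track_set, run_stage_pipeline

tracks, truth = generate_track_set(50, EventParams(), seed=7)
stage, ensemble = run_stage_pipeline(tracks)
print(f"scission at {stage.t_scission:.2f} s, "
      f"speed {stage.speed:.1f} ± {stage.speed_stderr:.1f} nm/s")
```

prints `scission at 4.67 s, speed 51.7 ± 0.3 nm/s` — the pipeline recovers
the generator's 4.5 s invagination window and 51.8 nm/s speed from noisy
tracks.

The same stages are available from the shell:

```bash
patchkit simulate --n 50 --seed 7 --out sim/
patchkit dynamics --tracks sim/tracks.csv --out dyn/
patchkit count --out counts/
```

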