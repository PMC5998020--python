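# netlyze

Network analysis of 3D single-molecule localization microscopy (SMLM)
point clouds. The pipeline turns a raw blink event list into quantified,
classified nanoscale structures:

1. **merge** — iterative merging of blinks within the 20 nm resolution
   limit corrects fluorophore multi-blinking; surviving nodes are the
   predicted molecule localizations.
2. **partition** — tiling into fixed-size ROIs (default 3 × 3 × 1 µm³)
   for independent, parallelizable per-ROI analysis.
3. **roi_analysis** — 32 weighted/unweighted network measures on
   proximity graphs at 24 thresholds (20–250 nm) per ROI; two-population
   discrimination via Mann–Whitney tests, L2-norm p-value aggregation
   with Bonferroni correction, and seeded random-forest
   leave-one-cell-out validation.
4. **filtering** — noise removal by comparing node degree at 80 nm
   against a matched random-graph null (uniform XY, Gaussian-fitted Z),
   retaining nodes with degree > α · mean(null), α = 4.
5. **blobs** — mean-shift segmentation into blobs and a 28-feature
   descriptor per blob (size, shape, hollowness, network structure,
   including Newman leading-eigenvector modularity).
6. **identify** — unsupervised group discovery per population (X-means
   BIC), cross-population group matching on centroid distances with
   threshold β = 30, and nearest-centroid labeling of new blobs.

A built-in simulator (`netlyze.simulate`) generates blinking event lists
from ground-truth structures (10 nm rods, 60 nm spheres, custom point
sets) with configurable localization precision, labeling efficiency and
blink statistics, so the whole pipeline is testable without microscope
data. `netlyze.calibration` reproduces the single-antibody calibration
analysis (gating, K-means single-vs-cluster split, blink-spread
statistics).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (merge oracle,
structural counts, simulator fidelity, exhaustive-search modularity
oracle, filter behavior, end-to-end hollow-sphere reconstruction,
classification of planted populations, gate robustness).

## CLI

Every stage is a subcommand of `netlyze`:

```sh
netlyze simulate --spec sphere60.yaml --seed 1 --out sim/
netlyze merge    --in sim/events.csv --T 20 --out locs.csv --stats merge.json
netlyze tile     --in locs.csv --roi-size 3000,3000,1000 --out tiled.csv
netlyze filter   --in locs.csv --T 80 --alpha 4 --measure uwDeg --seed 7 --out kept.csv
netlyze blobs    --in kept.csv --bandwidth 80 --out blobs.csv
netlyze identify --train blobsA.csv blobsB.csv --beta 30 --out model/
netlyze assign   --model model/model_a.json --blobs blobsC.csv --out labeled.csv
netlyze calibrate --in antibody_events.csv --out calib.json
netlyze roistats --pop-a dirA --pop-b dirB --out stats/
netlyze run      --config cfg.yaml --cells manifest.csv --out results/
```

`netlyze run` drives the full pipeline over a manifest CSV
(`path,cell_id,population`) with a YAML config (all stages seeded;
provenance snapshot written next to the outputs).

## Library use

```python
import numpy as np
from netlyze import merge, filtering, blobs, simulate

spec = simulate.PopulationSpec(
    structures=[simulate.sphere(60.0, center=(1500, 1500, 500))],
    extent=(3000, 3000, 1000), background_count=800)
events, truth = simulate.make_test_cell(spec, seed=1)

locs = merge.merge_blinks(events, T=20.0)
kept = filtering.degree_filter(locs, seed=1).retained
found, _ = blobs.segment_blobs(kept, bandwidth=100.0)
descriptor = blobs.blob_descriptor(max(found, key=len))
print(descriptor.as_dict())
```
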