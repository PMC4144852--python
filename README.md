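# tjmetrics

Quantitative analysis of epithelial cell–cell junction shape and
tight-junction barrier function, exercised entirely on synthetic data with
exact ground truth.

The package covers four stages:

1. **`tjmetrics.simulate`** — synthetic confocal-like monolayer images
   (Voronoi cell mosaic with sinusoidal junction tortuosity, optional
   "two-row" punctate myosin decoration), simulated dilution-potential/TER
   records, and tracer-flux time series. Every generator attaches the exact
   ground truth (junction polyline network, true permeabilities) used to
   score the analysis stages.
2. **`tjmetrics.morphometry`** — segmentation of junction ridges,
   skeleton-graph extraction into a vertex/side network with sub-pixel ridge
   refinement, per-side path (L_TJ) and chord (L_St) lengths, the windowed
   **zigzag index** (ratio of sums ΣL_TJ/ΣL_St over the sides contained in
   randomly placed 840-µm² windows), and line-scan intensity profiling with
   single/double-peak classification.
3. **`tjmetrics.barrier`** — blank-subtracted transepithelial resistance
   (TER), charge selectivity P_Na/P_Cl from dilution potentials via the
   Goldman–Hodgkin–Katz relation (closed-form inversion), absolute P_Na and
   P_Cl via the conductance–permeability (Kimizuka–Koketsu) relation, linear
   fluorescence calibration, and tracer apparent permeability
   P_app = (dQ/dt)/(A·C0).
4. **`tjmetrics.stats` / `tjmetrics.pipeline`** — pooled-variance Student's
   t-test comparisons and an end-to-end orchestrator
   (simulate → measure → barrier → compare) driven by one JSON config.

## CLI

```bash
# render a monolayer image + ground-truth network
tjmetrics simulate monolayer --config monolayer.json --out out/

# windowed zigzag index of an image (five 840-µm² windows)
tjmetrics measure zigzag --image out/monolayer.tif --windows 5 --area 840 --seed 1

# intensity profile across a junction
tjmetrics measure linescan --image out/monolayer.tif --channel myosin \
    --from 10,12 --to 14,12 --width 0.3

# simulated electrophysiology -> TER, P_Na/P_Cl, P_Na, P_Cl
tjmetrics simulate electro --config electro.json --out out/
tjmetrics barrier selectivity --in out/electro.csv

# tracer flux -> apparent permeability
tjmetrics simulate flux --config flux.json --out out/
tjmetrics barrier flux --in out/flux.csv --standards out/standards.csv

# full two-clone comparison pipeline
tjmetrics report run --config pipeline.json --out report/
```

Config files are plain JSON mirroring the dataclass fields (see
`MonolayerSpec`, `ElectroSpec`, `FluxSpec`, and `run_pipeline` docstrings).

## Data formats

- Images: multi-page float32 TIFF (`CYX`) plus a sidecar `.json` with pixel
  size, channel names and the generator spec.
- Truth networks: JSON with `vertices` (id, x_um, y_um) and `sides`
  (id, v1, v2, polyline, border), origin top-left, µm units.
- Electro records / flux series / standards: CSV with documented, stable
  column names (see `tjmetrics.io`).
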