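# dbscanmaps

Cluster-parameter DBSCAN maps, process windows and gliding-box lacunarity
for single-molecule localization microscopy (SMLM) point clouds.

SMLM reconstructions (dSTORM, PALM, ...) are lists of emitter coordinates,
and nanoscale structure in them is usually quantified by clustering —
most often with DBSCAN, whose two inputs, the neighborhood radius ε (nm)
and the minimum point count *N*, strongly shape the result. This package
implements a characterization method that embraces that sensitivity instead
of hiding it: DBSCAN is run over a whole (ε, *N*) grid and five statistics
of the resulting clusters are recorded per grid cell,

* AV(area), SD(area) — mean and standard deviation of the convex-hull
  cluster area (nm²),
* AV(n_loc), SD(n_loc) — mean and standard deviation of the per-cluster
  localization number,
* the cluster count,

giving five *cluster-parameter maps*. The maps need no ground truth, so
they apply directly to measured data. On top of them the package provides

* **process windows** — each map is min-max normalized, its gradient taken
  on grid-index units, and the gradient lengths summed over five maps (or
  the three most stable: both SDs and the cluster count). Regions where the
  summed gradient length stays below a threshold are (ε, *N*) choices whose
  clustering output is insensitive to the inputs; windows can be combined
  over treatments (the limit scales with the treatment count);
* **edge-line fits** — the onset edge of the cluster-area map (its ε-axis
  intercept tracks the nanofocus size) and the background-affected band
  edge of the localization-number map (its slope, in nm⁻¹, tracks the
  nonspecific localization density), each as an ordinary least-squares line
  *N* = slope·ε + c;
* **cluster-area filtering** — removal of clusters below a minimum hull
  area (e.g. 5000 nm², ≈ 80 nm diameter) before the statistics, which
  suppresses background-induced small clusters in all five maps;
* **gliding-box lacunarity** — Λ(b) = B·Σm²/(Σm)² over box masses m for
  log-spaced box sizes b, normalized against uniform-random references with
  the same count to give the lacunarity difference curve (LDC), whose peak
  marks the dominant cluster scale; log-log linear ranges of Λ flag
  self-similar scale bands;
* a **synthetic generator** for the standard benchmark structure: nine
  560 nm disks on a 3×3 grid (2500 nm pitch), 4 nanofoci/µm² per disk,
  ~150 labels per nanofocus on a spherical linker shell (55/99/143 nm),
  imaged through a stochastic detection → geometric blinking → Gaussian
  precision chain, plus volumetric nonspecific background.

## Worked example

Simulate the default disk pattern (99 nm linker, no background), map it on
the fine simulation grid with the 5000 nm² area filter, and fit the onset
edge:

```sh
$ dbscanmaps simulate --seed 7 --out demo.csv
$ dbscanmaps maps --in demo.csv --eps-min 1 --eps-max 90 --eps-step 1 \
      --n-min 2 --n-max 20 --n-step 1 --min-area 5000 --out demo_maps.csv
$ dbscanmaps edgefit --maps demo_maps.csv --mode onset
slope_per_nm=1.2837
intercept_eps_nm=20.0626
r_squared=0.984173
n_edge_points=19
```

`demo.csv` holds 1947 localizations in ThunderSTORM-style columns
(`x [nm], y [nm], frame, uncertainty [nm]`). The onset edge — the smallest
ε at which a nanofocus-scale cluster appears, per *N* row — is close to a
straight line (R² = 0.98); its ε-axis intercept of **20.1 nm** measures the
effective nanofocus size of the 99 nm-linker pattern. With 55 and 143 nm
linkers the intercept moves down and up, respectively.

A process window from the same dataset (unfiltered maps, three-map sum
gradient, threshold 0.02):

```sh
$ dbscanmaps maps --in demo.csv --eps-min 1 --eps-max 90 --eps-step 1 \
      --n-min 2 --n-max 20 --n-step 1 --out demo_maps_unf.csv
$ dbscanmaps window --maps demo_maps_unf.csv --use-maps three \
      --threshold 0.02 --out demo_window.csv
```

marks 539 of the 1710 grid cells as parameter-insensitive. And the
lacunarity comparison:

```sh
$ dbscanmaps lacunarity --in demo.csv --seed 7 --out demo_ldc.csv
peak_box_size_nm=172.698
```

the LDC of the clustered pattern peaks near the nanofocus scale.

Every command writes a `<output>.manifest.json` capturing the resolved
configuration and seed; `dbscanmaps rerun <manifest>` reproduces the run
bit-for-bit. The same functionality is available as a library
(`dbscanmaps.simulate_pattern`, `scan_grid`, `onset_edge_fit`,
`band_edge_fit`, `process_window`, `ldc_curve`, ...); see `docs/methods.md`
for the model details and design choices.

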