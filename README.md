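# hydromig

Quantitative analysis of 3D cell migration in bicontinuous hydrogels —
trajectory statistics under the anisotropic persistent random walk (APRW)
model, two-phase microstructure morphometrics, spheroid-outgrowth and
tissue-infiltration measures, and Hertz nanoindentation fitting — together
with seeded synthetic-data generators for every input the pipeline consumes.

## Who this is for

Bicontinuous hydrogels are two-phase biomaterials in which a gelatin-rich
(GR) and a gelatin-poor (GP) domain each form a connected, interpenetrating
3D network; cells migrate rapidly along the GR/GP interfaces. Characterising
such a material and the migration it supports requires a stack of small,
well-defined computations that are usually scattered across ad-hoc scripts:
MSD model fits on tracker exports, connectivity and interfacial-area
morphometrics on confocal stacks, ray-based outgrowth measures on spheroid
masks, depth quantiles for infiltrating cells, and contact-mechanics fits on
AFM force curves. `hydromig` packages these as tested library functions with
a thin CLI.

## The core model

Cell trajectories (projected to 2D) are treated as two independent
persistent random walks along a cell-specific primary axis **p** and the
orthogonal non-primary axis **np**. For each cell the time-averaged MSD is
computed along each axis (axes from SVD of the velocity matrix) and fitted
jointly to

    MSD_p(τ)  = S_p² P_p² (e^(−τ/P_p) + τ/P_p − 1) + 2σ²
    MSD_np(τ) = S_np² P_np² (e^(−τ/P_np) + τ/P_np − 1) + 2σ²

with a shared positional-noise variance σ². Speeds S (μm/hr) and
persistence times P (hr) yield per-axis diffusivities D = S²P/4, total
diffusivity D_t = D_p + D_np, and the anisotropy index φ = D_p/D_np ≥ 1.
The same model, simulated through the exact transition kernel of the
integrated Ornstein–Uhlenbeck velocity process, serves both as a
verification stage and as the synthetic data source for parameter-recovery
tests.

Microstructure metrics operate on binary (GR/GP) voxel volumes with
anisotropic voxel sizes: per-phase volume fractions, *connectivity* (volume
share of a phase's largest connected component, ×100%), internal
interfacial surface area per ROI volume by exact face counting, discrete
object counts, and intensity coefficient of variation. Indentation curves
are fitted with the spherical Hertz relation
F = (4/3)·E_ind/(1−ν²)·√R·δ^(3/2) (ν = 0.49 for swollen hydrogels), and
force maps are summarised after IQR outlier removal.

## Worked example

```sh
hydromig simulate-tracks --out demo_tracks.csv --n-tracks 60 \
    --duration 40 --sample-dt 0.1 --seed 11
hydromig analyze-tracks demo_tracks.csv --out demo_summary.json --t-start 0
```

prints

```
wrote 60 tracks to demo_tracks.csv (seed=11)
alpha=1.059  S_p=39.22 um/hr  P_p=0.668 h  phi=2.92  (written to demo_summary.json)
```

The simulator's defaults are the motility parameters of a 3% guest-host
bicontinuous gel (primary-axis speed 38.47 μm/hr, persistence 0.56 hr).
`alpha` is the log–log slope of the population MSD (≈1: diffusive at long
lags); `S_p` and `P_p` are the population means of the per-cell fitted
primary-axis speed and persistence — close to the generating values, with
the persistence time carrying the largest scatter at this sample size;
`phi` is the population mean of per-cell D_p/D_np (its upward bias relative
to the generating ratio is quantified in `docs/methods.md`). The full JSON
summary additionally carries the population MSD curve, the
velocity-orientation profile, and a provenance block.

```sh
hydromig simulate-volume --out demo_vol.tif --size 96 --length-scale 8 --seed 3
hydromig analyze-volume demo_vol.tif --out demo_vol.json
```

prints

```
GR fraction=0.500  connectivity GR=100.0%  GP=100.0%  SA/V=0.0849 1/um
```

— a half-fill thresholded random field is bicontinuous: both phases are
fully connected, with ~0.08 μm⁻¹ of internal interface.

Other subcommands: `outgrowth` (eight-ray spheroid outgrowth from a mask),
`infiltration` (95th-percentile depth and depth-bin fractions),
`indent-fit` (Hertz fits and force-map statistics), `report` (render JSON
results as text).

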