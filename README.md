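# mcart — membrane charting toolkit

Quantitative analysis of protein-complex organization on membrane surfaces in
cryo-electron tomograms:

- **Membranograms** — tomographic density sampled on a segmented membrane
  surface at a signed normal offset ("grow/shrink"), with thresholding and
  edge cropping for quantitative maps.
- **Surface geometry** — binary voxel segmentations to smooth oriented
  triangle meshes (marching cubes, decimation to a target triangle fraction,
  Laplacian smoothing with fixed boundaries), continuous normal offsets,
  best-fit-plane flattening, areas.
- **Structure models** — atomic structures (PDB/mmCIF) low-pass filtered to
  25 Å as sums of Gaussians, core/antenna partition of supercomplexes,
  placement into one-voxel-thick membrane models at picked positions and
  in-plane angles, occupied-area fractions.
- **Lateral analysis** — per-class concentrations and totals, PSII/PSI
  stoichiometry, within-class nearest-neighbor distances with exclusion
  masks, intermembrane overlap (white/green/magenta counting) for both
  thresholded density maps and placed-structure models.
- **Random packing null model** — collision-resolving random placement
  (random position + angle, rotate-then-relocate on overlap), replicate
  overlap distributions, Welch's t-test.
- **Synthetic scenes** — ground-truthed synthetic tomograms of stacked
  membrane sheets (9 nm lumen, 3 nm stromal gap) decorated with
  class-specific protrusions at stated concentrations, plus a protrusion
  detector and recovery reports, so the whole pipeline is testable without
  external data.

## Conventions

- Volumes are `data[z, y, x]` (x fastest, MRC order); physical positions are
  `(x, y, z)`. Analysis APIs use **nanometres**; file I/O uses ångströms
  where the format dictates (MRC, PDB). Voxel (0,0,0) centre sits at
  `origin`; position = origin + index · voxel_size.
- Surface normals point from the membrane toward the stromal side.
- One seed (counter-based Philox) reproduces every stochastic pipeline
  bit-exactly.

## CLI

```sh
mcart info volume.mrc                 # header / mesh / structure summaries
mcart convert particles.csv out.json
mcart surface mask.mrc out.obj --grow-voxels 2 --smooth-iters 50 \
      --smooth-lambda 0.4 --decimate 0.1
mcart membranogram tomo.mrc membrane.obj --offset-nm 2 --out map.png
mcart model --structure 6KAD.cif --particles picks.csv --resolution 25
mcart synth --preset table1 --out-mrc scene.mrc --out-particles truth.csv
mcart null --replicates 100 --seed 17
mcart analyze concentrations picks.csv --area-um2 0.05
mcart analyze nn picks.csv --mesh membrane.obj
```

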