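# mixcount

Dual-population fluorescence image cytometry for yeast/bacteria mixed
cultures: a synthetic counting-chamber micrograph simulator with known
ground truth, a size-exclusion detection and counting pipeline, and the
statistics layer used to compare image-cytometry concentrations against
colony plate counts.

The counting method mirrors chamber-based image cytometry of
*Saccharomyces cerevisiae* (large round cells) and *Lactiplantibacillus
plantarum* (small rods) stained into the same green channel: objects are
segmented, touching cells are declustered on the distance transform, and
populations are assigned purely by equivalent-diameter gates (yeast
6.0–50.0 µm, bacteria 0.5–5.0 µm in mixed mode). Counts become
concentrations via the chamber geometry (field area × depth) and the
staining/sampling dilution bookkeeping, and are validated against
(simulated) serial-dilution plate counts with log-scale difference tables,
titration regressions, t-tests and a method-factor ANOVA.

## Layout

- `mixcount.profiles` — optics, chamber (SD100/SD025), staining-plan, and
  counting-parameter data model with the built-in parameter sets.
- `mixcount.simulate` — synthetic field truth (Poisson loading), 16-bit
  frame rendering (supersampled disks and capsule rods), experiment
  designs (titrations, constant-plus-titration, ratio mixes, chamber
  comparison, fermentation time courses), simulated plating.
- `mixcount.detect` — background estimate, contrast-relative threshold,
  8-connected labeling with a centroid-interior border policy,
  distance-transform declustering, feature measurement, gate filtering.
- `mixcount.counts` — pooled counts → concentrations, mixed-culture dual
  counting, viability.
- `mixcount.stats` — CFU back-calculation, countable-plate selection,
  log conversion, difference tables, percent difference, titration
  regression, Welch t-test, method ANOVA.
- `mixcount.cli` — the `mixcount` command.

## CLI

```sh
mixcount list-builtins
mixcount simulate --design titration --organism bacteria --stock 1e8 \
    --staining bacteria_sytobc --seed 1 --out runs/sim
mixcount count --manifest runs/sim/manifest.csv --profile bacteria_sytobc \
    --staining bacteria_sytobc --out runs/counts
mixcount validate --results runs/counts/results.csv --plates plates.csv \
    --out runs/validation
mixcount ferment-demo --seed 1 --out runs/demo
```

Every run writes a `provenance.json` (config + seed + versions) next to
its outputs; all outputs are plain TIFF/CSV/JSON.

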