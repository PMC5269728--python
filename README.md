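# pymsp

Analysis pipeline for single-cell microspectrophotometry (MSP) of
vertebrate photoreceptors:

* **templates** — vitamin-A1 visual pigment absorbance templates
  (Govardovskii et al. 2000, α + β bands), their long-limb inversion, and
  oil droplet cut-off transmittance filters.
* **msp** — paired-scan merging (outward 750→350 nm / return 351→749 nm,
  2 nm steps), baseline normalization with template-assisted density
  refinement, the 20-point long-limb λ_max estimator, the 50-point
  peak-centred second estimate, bleach verification, and the selection
  criteria (transverse density > 0.01, right-limb SD < 12 nm, inter-method
  difference < 6 nm; relaxed bleach-based retention for the rare UVS/SWS
  classes).
* **droplets** — oil droplet λ_cut by the Lipetz tangent construction and
  per-type summaries.
* **stats** — random-intercept (bird) linear mixed models fit by REML with
  a profiled variance ratio, type-III F tests with Satterthwaite (or
  containment) denominator df, estimated marginal means, and ICC from
  intercepts-only fits.
* **eyemodel** — predicted single-cone sensitivity curves (pigment ×
  droplet transmittance, LWS–R / MWS–Y / SWS–C / UVS–T pairing).
* **synth** — a hierarchical synthetic-study generator
  (population → bird → cell) that emits the exact scan/manifest text
  formats the pipeline reads, plus single-violation QC fixtures.
* **pipeline / cli / config / io** — orchestration, CLI, YAML
  configuration, delimited-text formats.

## CLI

```sh
pymsp synth generate --seed 1 --out study/
pymsp msp estimate --manifest study/cells_manifest.tsv --out est/ [--mask-populations]
pymsp droplets cut --manifest study/droplets_manifest.tsv --out drops/
pymsp stats compare --cells est/cell_estimates.tsv --droplets drops/droplet_cuts.tsv --out report/
pymsp eyemodel build --pigments report/pigment_comparison.tsv --droplets report/droplet_comparison.tsv --out eye/
pymsp run-all --manifest study/cells_manifest.tsv --droplet-manifest study/droplets_manifest.tsv --out results/
```

All subcommands accept `--config config.yaml`; unknown keys are rejected
and the resolved configuration is written next to every output.

## Data formats

Scans are two-column TSV (`wavelength_nm`, `absorbance_od`). The cell
manifest columns are `cell_id, bird_id, population, putative_class,
morphology, outward_path, return_path, postbleach_path`; the droplet
manifest uses `droplet_id, bird_id, population, droplet_type,
spectrum_path`. Paths are relative to the manifest.
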