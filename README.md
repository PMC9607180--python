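# facedev

Surface-deviation analysis for paired facial meshes: a reference "shell"
(e.g. segmented from volumetric imaging) is compared against a
lower-resolution depth-sensor scan by rigid superimposition, absolute
point-to-surface deviation mapping with a 3 mm clinical display cap,
aggregation over a named facial-region atlas, and sex-stratified cohort
statistics (Fisher exact / Friedman).

Because no real scan data ships with the package, a first-class synthetic
generator produces paired shell/scan meshes with fully known ground truth
(per-region injected deviations, rigid misalignment, forehead-crop and
eyelid artifacts, concavity-dependent sensor noise), so every stage of the
pipeline is testable end to end.

## Modules

| module | what it does |
|---|---|
| `facedev.mesh_core` | triangle-mesh model, binary/ASCII STL and ASCII PLY I/O, exact closest-point queries (KD-tree pruned, numba-accelerated), vertex normals, rigid transforms |
| `facedev.synthetic_faces` | parametric face generator (Gaussian features on a dome), region atlas (23 named locations), pair derivation with ground truth, cohort simulation |
| `facedev.registration` | landmark Kabsch coarse fit + trimmed point-to-point ICP restricted to expression-stable regions, operator-stability check |
| `facedev.deviation_map` | absolute deviation fields, 3 mm display cap, PLY/CSV heatmap export, planar profile sections |
| `facedev.regional_analysis` | clinical interval classifier (>3 mm = relevant), per-region summaries and flags, cohort inclusion filter |
| `facedev.cohort_stats` | 2x2 contingency tables, self-implemented two-sided Fisher exact test (min-likelihood), tie-corrected Friedman test, report tables |
| `facedev.pipeline_cli` | `run_all` orchestration, external-pair comparison, YAML config, `facedev` CLI |

## CLI

```sh
facedev write-config config.yaml        # dump defaults (19 men / 41 women,
                                        # 3 mm cap, 95th-percentile flags...)
facedev run-all --config config.yaml --seed 1 --out run/
facedev simulate --seed 1 --out cohort/ --bundles
facedev filter cohort/manifest.csv --out cohort/
facedev compare shell.stl scan.stl --atlas atlas.csv --landmarks lm.json
```

`run-all` writes, per run: `manifest.csv`, `exclusions.csv`, per-subject
transforms / ICP traces / heatmaps (`subjects/*/`), the pooled
`region_table.csv`, the sex-stratified `table2.csv` (counts, percentages,
Fisher p, significance at alpha = 0.05) and the rank-ordered `table3.csv`.
Runs are byte-deterministic for a fixed seed.

## Notes

- Units are millimetres throughout; meshes may be open (facial shells are
  not watertight).
- Deviation is measured from scan vertices to the shell surface; the raw
  (uncapped) value drives classification, the cap affects display only.
- Scan vertices whose closest shell point lies on a boundary edge, or is
  farther than 10 mm, are treated as non-overlap (crop artifacts) and
  excluded rather than counted as deviation.
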