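# lsmpipe

Lesion-symptom inference pipelines for post-stroke depressive symptoms,
driven entirely by synthetic cohorts with known ground truth:

- **SVR-LSM** — multivariate support-vector-regression lesion-symptom mapping
  with dual-coefficient β-map back-projection, permutation voxel-level
  inference (one-tailed, damage → higher score) and cluster-level FWE
  correction from the null distribution of maximum cluster sizes.
- **SVR-SDSM** — the same machinery on binarized structural-disconnection
  maps built from lesion masks and a normative tractogram set
  (streamline–lesion segment traversal, percent-of-subjects overlap,
  binarization at ≥ 60%).
- **LNSM** — lesion network-symptom mapping on a normative resting-state
  set: smoothing, nuisance regression (motion / WM / CSF / global signal),
  zero-phase band-pass (0.01–0.08 Hz), FD > 0.5 mm censoring, first-
  eigenvariate lesion seeds, Fisher-z connectivity maps averaged over all
  subjects/runs, and a mass-univariate GLM with permutation cluster FWE.
- **NDS** — a "depression circuit" t-map seeded from a 9 mm sphere, the
  network damage score (sum of circuit t-values under the lesion),
  lesion-size residualization and a permutation group test (exhaustive
  enumeration when feasible).

The `synthetic_data` module generates every input with planted ground truth:
blob lesions with a region → score effect, community-structured normative
time series with motion traces and tissue maps, and bundle-shaped
tractograms. No external data are required.

## CLI

```bash
# materialize a synthetic dataset directory
lsmpipe simulate --out data/demo --n-patients 60 --effect-size 10 --seed 1

# individual stages (or `report` for all of them)
lsmpipe svr-lsm       --dataset data/demo --perms 200 --seed 1
lsmpipe disconnectome --dataset data/demo --cutoff 60
lsmpipe svr-sdsm      --dataset data/demo --perms 200 --seed 1
lsmpipe lnsm          --dataset data/demo --seed 1
lsmpipe nds           --dataset data/demo --seed 1
lsmpipe report        --dataset data/demo --perms 200 --seed 1
```

Outputs per stage: β/z/p (or t) NIfTI maps with the config echoed in a JSON
sidecar, a cluster table CSV (id, size, p_FWE, peak voxel), a JSON summary
and a consolidated exclusion report (`exclusions.csv`) plus `summary.md`.

Analysis thresholds live in `AnalysisConfig` (YAML-serializable; see
`lsmpipe.io_model`): voxel p < 0.005 one-tailed for SVR mapping, p < 0.001
for the LNSM GLM, cluster FWE α = 0.05, 5000 permutations, ≥ 5-patient
lesion-overlap minimum, ≥ 60% disconnection cutoff, ≥ 10% gray-matter
probability, FD ≤ 0.5 mm, 5 mm FWHM, 9 mm seed sphere. SVR hyperparameters
default to C=30, γ=5, ε=0.1 (RBF); a linear kernel is available and is used
throughout the oracle tests. Note that with the 0.005 voxel threshold at
least 200 permutations are required for any voxel to pass.

## Tractogram format

Plain whitespace-delimited text: one `x y z` world-mm point per line, a blank
line between streamlines, `#` for comments. Written/read by
`lsmpipe.disconnectome.write_tractogram` / `read_tractogram`.

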