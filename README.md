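# chondroquant

Quantitative MRI analysis of femoral condylar cartilage: per-voxel T2
relaxometry, mesh-based cartilage thickness, condylar volume-of-interest
(VOI) aggregation, and longitudinal repeated-measures statistics — backed
by a synthetic knee phantom so that every stage of the pipeline is testable
without clinical imaging data.

## What it does

- **phantom** — generates bi-condylar knee geometry (two smooth lobes with
  an intercondylar notch), a spatially varying cartilage thickness field, a
  depth-dependent T2 field, multi-echo magnitude volumes with Rician noise
  on an anisotropic acquisition grid (0.313 × 0.446 × 3 mm by default,
  TE 10–70 ms in 10 ms steps), and three-timepoint progressing cohorts with
  per-region multiplicative effects. Fully seeded and reproducible.
- **meshmodel** — triangle meshes and cartilage thickness as the per-vertex
  minimum point-to-triangle distance from the subchondral bone surface to
  the cartilage surface (k-d-tree accelerated, provably identical to brute
  force), with coverage flags and per-VOI means.
- **relaxometry** — log-linear monoexponential T2 fitting (first echo
  excluded by default to avoid stimulated-echo bias; optional nonlinear
  refinement), robust per-VOI medians with a two-step exclusion rule
  (negatives, then values above median + 3·IQR), medial/lateral ratios and
  annualized %/year changes.
- **voiatlas** — header-based registration plumbing, partitioning of the
  condylar surface into six VOIs (medial/lateral × anterior/central/
  posterior) plus six anterior sub-VOIs (external/central/internal), voxel
  → VOI assignment via nearest bone vertex, relative cartilage depth and
  deep/superficial layer splitting at 50% depth.
- **longstats** — the gated statistical ladder per measure: Friedman +
  Wilcoxon signed-rank (exact p-values by full enumeration where feasible)
  for non-normal families, one-way within-subject ANOVA + paired t for
  normal families; omnibus at α = 0.05, pairwise post-hoc only when the
  omnibus is significant, judged strictly at the Bonferroni α = 0.017, with
  effect sizes (Cohen's d_z / r = |Z|/√n).
- **io / config / pipeline / cli** — NIfTI (4D multi-echo + sidecar),
  ASCII PLY/OBJ, CSV, DICOM geometry-tag extraction, a single-JSON run
  configuration with strict key checking, and an end-to-end driver with a
  reproducibility manifest.

## CLI

All subcommands accept `--config <json>` (see `chondroquant.config.RunConfig`
for the schema) and exit non-zero with the failing stage named.

```bash
# simulate a cohort: volumes (NIfTI), meshes (PLY), ground-truth CSV
chondroquant simulate --n-knees 19 --seed 1 --outdir scratch/cohort

# fit a T2 map from a 4D multi-echo NIfTI
chondroquant fit-t2 --input scratch/cohort/knee00_KL1_msme.nii --out-t2 scratch/t2.nii

# per-vertex thickness and per-VOI means
chondroquant thickness --bone bone.ply --cartilage cart.ply \
    --out-vertex-csv thickness.csv

# VOI labels for a bone mesh
chondroquant vois --bone bone.ply --out-csv vois.csv

# statistics on a long-format cohort table
chondroquant stats --table cohort_table.csv --out stat_results.csv

# everything: simulate -> fit -> thickness -> VOIs -> statistics
chondroquant run-all --config config.json --seed 1 --outdir results/
```

A minimal `config.json`:

```json
{
  "seed": 1,
  "n_knees": 19,
  "phantom": {"noise_sigma": 8.0},
  "progression": {"t2_multipliers": {"KL2": {"M": 1.1}}},
  "stats": {"alpha": 0.05, "bonferroni_alpha": 0.017}
}
```

## Conventions worth knowing

- Voxel indices are zero-based with the voxel center at the index
  coordinate; `world = direction @ diag(spacing) @ index + origin`.
- The VOI boundaries (anterior/central/posterior thirds of each condyle's
  arc; medial-lateral thirds for the anterior sub-VOIs, "external" farthest
  from the notch) are declared, configurable conventions.
- Relative depth is `d_bone / (d_bone + d_cart)`; a voxel is "deep" when
  depth < 0.5.
- The Bonferroni threshold is the printed 0.017, applied strictly
  (p < 0.017).
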