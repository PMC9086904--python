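# morphnet

Single-subject gray-matter (GM) morphological network analysis in Python.

Each subject's brain is represented as a network whose nodes are atlas
regions (116-region AAL-style parcellation by default) and whose edges are
Kullback-Leibler-divergence-based similarities (KLS) between the regions'
voxel-value distributions. The package implements the full analysis chain:

1. **synthetic_cohort** — generate a fully synthetic three-group cohort
   (ET with poor sleep / ET with normal sleep / healthy controls): per-ROI
   voxel samples from latent-factor-driven Gaussian mixtures (so thresholded
   networks are small-world), clinical scores (TRS, PSQI, MMSE, HAMA, HAMD),
   and plantable effects — edge-level similarity shifts, a group-level
   global-integration effect, and a node-degree ↔ tremor-severity
   correlation.
2. **roi_io** — NIfTI-1 GM-map + atlas extraction, TSV round-trips for ROI
   samples, networks and cohort tables.
3. **kls_network** — Gaussian-kernel density estimation per ROI on shared
   per-pair grids and the symmetric 116×116 KLS matrix per subject
   (`exp(-[KL(p||q)+KL(q||p)])`, in (0,1], 1 iff identical).
4. **graph_metrics** — sparsity thresholding (0.10–0.35, step 0.01),
   global metrics (Eglob, Eloc, Cp, Lp), normalized metrics (γ, λ, σ = γ/λ)
   against Maslov–Sneppen degree-preserving nulls, nodal metrics (degree,
   betweenness, efficiency), and trapezoidal AUC over the sparsity range.
5. **group_inference** — permutation ANOVA / pairwise t tests on AUC
   metrics with Benjamini–Hochberg FDR.
6. **nbs_stats** — network-based statistics: edgewise F/t, suprathreshold
   connected components, max-component permutation inference.
7. **clinical_analysis** — PSQI/MMSE/HAMA/HAMD screening rules and
   covariate-adjusted partial correlations.
8. **pipeline / cli** — one seeded, configured, logged run of all stages.

Performance-critical inner loops (pairwise KDE/KLS, rewiring, BFS/Brandes
graph measures) are numba-compiled; the test suite checks every compiled
kernel against independent brute-force, networkx, scipy, statsmodels and
pingouin references.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (KLS identity and
range, 116×116 matrix contract, small-worldness of the default synthetic
cohort, screening boundaries, brute-force oracle equivalence of all graph
metrics, type-I calibration of the permutation ANOVA and NBS, planted-effect
recovery, analytic AUC values). The full suite takes ~15–20 min on one CPU;
the Monte-Carlo-heavy tests state their scaled-down sizes inline.

## CLI

```bash
morphnet simulate --spec spec.yaml --seed 42 --out run/
morphnet extract  --gm subj.nii.gz --atlas aal116.nii.gz --out subj_samples.tsv
morphnet build    --samples run/cohort --grid-points 512 --out run/networks
morphnet metrics  --run-dir run --smin 0.10 --smax 0.35 --sstep 0.01 --nulls 100 --seed 7
morphnet compare  --run-dir run --nperm 10000 --fdr 0.05 --seed 7
morphnet nbs      --run-dir run --f-threshold 4.64 --t-threshold 2.64 --nperm 10000
morphnet clinical --run-dir run --group SleET --metric degree --vars TRS,PSQI
morphnet run      --config run.yaml --seed 42          # all stages end to end
```

`morphnet run` writes a JSON run report (per-stage record counts, seeds,
output paths); replaying the embedded config reproduces the outputs
byte-for-byte.

Example `run.yaml`:

```yaml
out_dir: run
seed: 42
cohort:
  group_sizes: {SleET: 45, NorET: 59, HC: 66}
  n_rois: 116
  voxels_per_roi: [100, 300]
  planted_global_effect: 1.0
  plant_trs: {target_roi: 76, rho: -0.35}   # Thalamus_L (0-based index)
grid: {n_points: 512}
thresholds: {s_min: 0.10, s_max: 0.35, s_step: 0.01}
metrics: {n_nulls: 100}
inference: {n_perm: 10000, fdr_q: 0.05}
nbs: {f_threshold: 4.64, t_threshold: 2.64, n_perm: 10000}
```

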