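# cbgrad

Intrinsic-coordinate gradient analysis of folded cortical regions of
interest, exercised end to end on a synthetic folded phantom.

The pipeline re-implements a laminar-style analysis for lobulated, highly
folded anatomy (e.g. cerebellar lobules):

1. **phantom** — generates a two-hemisphere, sinusoidally folded grey-matter
   sheet around a white-matter core, plus block-design BOLD runs
   (20 s ON / 10 s OFF, TR 3.3 s) with activation blobs planted at chosen
   intrinsic coordinates and AR(1)-optional Gaussian noise.
2. **segmentation** — builds the six boundary masks per lobule that seed the
   gradient directions: deep (WM probability > 0.99), superficial (dilated
   lobule minus the cerebellum mask), anterior/posterior (dilated overlap
   with the neighbouring lobules), medial (dilated overlap with the
   contralateral homologue) and lateral (remaining outline).
3. **gradients** — K iso-distance steps (default 7) between an origin and a
   destination boundary: per-voxel ratio `d_org / (d_org + d_dst)` of
   geodesic distances inside the ROI, binned into equal-width steps.  A pure
   Dijkstra implementation (`brute_force_steps`) serves as an independent
   test oracle.
4. **glm** — per-run voxelwise OLS on HRF-convolved boxcars with Legendre
   drift terms; contrast t-maps are converted to z through a tail-stable
   probability round-trip; runs combine with inverse-variance (fixed-effects)
   weighting; activation masks use strict `z > 3.1`.
5. **stepstats** — mean z per gradient step, grey-matter mean z, activation
   overlap counts, paired t-tests, one-way repeated-measures ANOVA with
   Mauchly's sphericity test and Greenhouse–Geisser correction, and
   Holm-adjusted pairwise post-hocs.
6. **cog** — quadrant-ROI z-weighted centres of gravity of supra-zero
   activation and per-axis paired t-tests of the between-condition shift.

Axis convention throughout: axis 0 = left→right, axis 1 =
posterior→anterior, axis 2 = inferior→superior.  Positive COG Δx is a
rightward shift; medial/lateral interpretation flips between hemispheres.

## CLI

Every stage is a subcommand of `cbgrad`; `run` executes the whole pipeline:

```bash
cbgrad run --seed 0 --out out/                 # full pipeline, default config
cbgrad run --config my.yaml --n-steps 7 --z-threshold 3.1 --out out/
cbgrad phantom --seed 0 --out phantom/         # anatomy + BOLD + design TSVs
cbgrad segment --labels L.nii --wm-probability wm.nii \
    --cerebellum-mask cb.nii --lobule 2 --hemisphere left --out seg/
cbgrad gradients --roi roi.nii --origin deep.nii --destination sup.nii \
    --direction fissure_depth --n-steps 7 --metric geodesic --out grad/
cbgrad glm --bold run0.nii --design design_run0.tsv --mask cb.nii --out glm/
cbgrad stats --profiles out/step_profiles.tsv --out stats/
cbgrad cog --cogs out/cog_per_subject.tsv --out cog/
```

The config is a YAML file mirroring `cbgrad.config.AnalysisConfig`; every
analysis constant (step count, WM threshold 0.99, z threshold 3.1, alpha,
lobule lists, phantom scenario, master seed) lives there and is recorded in
the run manifest (`manifest.json`) together with SHA-256 checksums of every
product.  Two runs with the same config and master seed produce identical
checksums.

Pipeline outputs (NIfTI + TSV): anatomy volumes, per-direction step maps and
voxel counts, per-subject combined z-maps, `step_profiles.tsv`,
`rm_anova.tsv`, `posthoc_holm.tsv`, `overlap_counts.tsv`, `mean_gm_z.tsv`,
`cog_per_subject.tsv`, `cog_shifts.tsv`.

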