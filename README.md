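# nucleofoci

Per-nucleus quantification of nuclear protein inclusions in multi-channel
fluorescence microscopy.

Neurodegenerative-disease tissue (and chronically stressed cultured cells)
accumulates punctate nuclear inclusions of RNA-binding proteins such as
RBM45. These puncta are related to nuclear stress bodies (NSBs), and their
formation is accompanied by depletion of diffuse nuclear signal of NSB
scaffold proteins such as SAFB. Quantifying this pathology means answering,
per microscope field: how many cells are there, how many inclusions does
each nucleus carry, and how does nuclear immunoreactivity co-vary with the
inclusion burden? `nucleofoci` implements that pipeline as a tested,
reusable library and CLI for imaging scientists, together with a
ground-truthed synthetic field generator so every stage can be validated
without access to the original micrographs.

## The analysis

For a field with channels DAPI (nuclei), an inclusion channel (e.g. RBM45)
and an optional reference channel (e.g. SAFB):

1. **Nuclei segmentation** — the DAPI channel is binarised at a fixed
   fraction *f* of its dynamic range (foreground iff
   `I ≥ min + f·(max − min)`), connected components are labelled, and
   false positives are rejected by area (μm², via the pixel calibration),
   circularity `4πA/P²`, and border contact. The surviving label map is the
   overlay mask for everything downstream; its size is the per-field cell
   count.
2. **Foci detection** — the inclusion channel, masked to nuclear pixels, is
   thresholded by Robust Automatic Threshold Selection (RATS): a recursive
   quadtree in which each leaf's threshold is the gradient-weighted mean
   intensity `T = Σ w·I / Σ w`, `w = g^p`, with weights zeroed at gradients
   below `λσ_g` and low-weight leaves inheriting their parent's threshold.
   Particles are size-gated to the published NSB range (default
   0.2–3.0 μm²) and assigned to the nucleus owning their pixel majority,
   giving each nucleus an inclusion count.
3. **Intensity quantification** — mean and integrated intensity of every
   channel over every nucleus, standardised per channel to Z-scores
   `z = (x − x̄)/s` over a common pool so different proteins and conditions
   share a scale.
4. **Group statistics** — Table-style per-group aggregation (total cells,
   mean ± SEM cells/field and inclusions/cell); all-pairs Mann–Whitney U
   tests on per-cell counts (exact by full permutation enumeration for
   n₁+n₂ ≤ 12, tie-corrected normal approximation otherwise) with
   Bonferroni correction; one-way ANOVA + Tukey HSD; OLS regression of
   reference-channel immunoreactivity on inclusion count; and a pooled
   two-proportion z test (Fisher fallback) for nuclear- vs
   cytoplasmic-inclusion-bearing cells.

The synthetic generator renders fields of non-overlapping elliptical nuclei
with per-nucleus inclusion counts drawn from a zero-inflated Poisson capped
at 17 and a reference channel whose level decreases linearly with the count
— the statistical structure the analysis is designed to detect — and
records the exact ground truth for agreement scoring against the pipeline's
output (the 95 % automated-vs-reference agreement criterion).

## Worked example

```python
from nucleofoci import PipelineConfig, group_spec, generate_study, run_pipeline

specs = {g: group_spec(g, image_shape=(512, 512), n_nuclei=20, n_nuclei_sd=2.0)
         for g in ("control", "FTLD")}
bundle = generate_study(specs, {"control": 2, "FTLD": 2}, seed=11)
study = bundle.save("demo/study")
results, summaries, stats = run_pipeline(PipelineConfig(), study,
                                         out_dir="demo/results")
```

prints per-field progress to stderr and yields:

```
FTLD     cells= 323 cells/field=20.19 (SEM 0.40) inclusions/cell=2.124 (SEM 0.103)
control  cells= 315 cells/field=19.69 (SEM 0.50) inclusions/cell=0.378 (SEM 0.053)
FTLD vs control U=79052.5 p_adj=1.21e-40
SAFB ~ inclusions: slope=-9.72 R2=0.808 p=4.91e-230
```

Two subjects × 8 fields per group were simulated with a control-like
(mean 0.44 inclusions/cell) and an FTLD-like (mean 2.38) burden. The
pipeline's per-cell counts separate the groups decisively (Bonferroni-
adjusted Mann–Whitney p ≈ 10⁻⁴⁰), and the regression recovers the
generative SAFB coupling (true slope −10 per inclusion; fitted −9.72,
p ≪ 0.001). Result tables (`nuclei.csv`, `foci.csv`, `intensity.csv`,
`zscores.csv`, `group_summary.csv`, `stats.json`) are written to
`demo/results` with deterministic ordering and formatting.

The same workflow is available from the shell:

```bash
nucleofoci simulate --out study --seed 11 --groups control,FTLD --subjects 2
nucleofoci quantify study --out results
nucleofoci stats results
nucleofoci validate --seed 1 --fields 20
```

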