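# prosegvar

Inter- and intra-observer variability of manual versus semi-automatic 3D
prostate-surface segmentation.

When several experts segment the same prostate on 3D transrectal
ultrasound (TRUS), how much do they disagree — and does a semi-automatic,
shape-prior-driven method disagree less than purely manual point
placement? The answer decides what should serve as the reference standard
("ground truth") for training segmentation AI. This package implements the
full comparison methodology as a tested, reusable pipeline:

* mesh reconstruction from sparse expert points by two methods — a
  **strict statistical-shape-model fit** (`manual_SSM`: the closest mesh
  confined to the model subspace) and a **soft fit** (`manual_soft-SSM`:
  the strict solution plus a B-spline free-form deformation attracted to
  the points);
* the three comparison metrics — **ASD** (average surface distance),
  volumetric **Dice** at 0.46 mm voxels, and **Hausdorff** distance;
* a **STAPLE-like mesh consensus**: an EM fixed-point on mesh vertices
  with rater weights ∝ 1/(d²+ε²), robust to outlier segmentations;
* **effect-size statistics**: Cohen's d from summary statistics with
  σ ≈ IQR/1.35 and pooled SD √((σ₁²+σ₂²)/2), Wilcoxon tests with
  Bonferroni correction;
* **spatial variability maps**: manual-point density and kernel-averaged
  ASD on a common mean shape, exposing the apex/base regions where sparse
  annotation coincides with high disagreement;
* a **synthetic multi-expert cohort generator** (prostate-like surfaces,
  plane-constrained noisy annotations, per-expert systematic bias fields,
  repeat "bis" sessions) so that every stage is testable without any
  clinical download.

The clinical cohort behind the emulated study design is not deposited, so
absolute medians are not reproducible; the pipeline reproduces the
published *cross-study effect sizes* exactly from printed summary
statistics, and the study's *qualitative findings* as orderings on the
synthetic cohort.

## Worked example

```python
import numpy as np
from prosegvar import (CohortConfig, generate_cohort,
                       run_variability_study)

cfg = CohortConfig(n_patients=6, n_experts=4, seed=1,
                   shared_subset_size=6, bis_subset_size=2)
cohort = generate_cohort(cfg)          # ~2 min: 40 manual sessions,
                                       # 28 semi-automatic sessions
results = run_variability_study(cohort)
for key in ("manual_inter_manual_SSM", "manual_inter_manual_soft_SSM",
            "semiauto_pairwise_asd", "semiauto_staple_asd"):
    print(results.summaries[key])
print(f"density-ASD rank correlation: {results.density_asd_rho:+.2f}")
```

prints (ASD in mm, median with IQR):

```
manual inter ASD manual_SSM: 1.33 (1.28-1.37), n=72
manual inter ASD manual_soft_SSM: 1.32 (1.27-1.37), n=72
semiauto_pairwise_asd: 0.62 (0.50-0.77), n=36
semiauto_staple_asd: 0.51 (0.45-0.56), n=24
density-ASD rank correlation: -0.36
```

Reading the output: the soft meshing method yields lower inter-observer
ASD than the strict subspace fit; comparing each expert against the
STAPLE-like consensus of the others tightens the semi-automatic table
relative to raw pairwise comparison; and regions with sparse manual
annotation (apex/base) carry the higher local ASD — the negative rank
correlation. On the reduced synthetic cohort these orderings, not the
absolute magnitudes, are the reproduction target.

The numbered scripts under `analysis/` run the same steps as a narrative
sequence and write their tables under `results/`:

```bash
python analysis/01_effect_sizes.py       # cross-study Cohen's d table
python analysis/02_simulate_cohort.py    # cohort -> scratch/cohort
python analysis/03_variability_study.py  # all comparison tables
python analysis/04_spatial_maps.py       # density/ASD maps + regions
```

For example, `01_effect_sizes.py` prints the eight cross-study effect
sizes (d = +0.36, +0.13, −2.47, −2.29 for manual-vs-semi-automatic
agreement against four earlier studies; +0.28, −0.30, −0.29 for manual
inter-observer variability; +1.38 for semi-automatic inter-observer
variability), each classified on the 0.2/0.5/0.8 scale.

## Layout

```
src/prosegvar/      library: geometry, metrics, shape_model, soft_ssm,
                    consensus, stats, spatial, synthetic, pipeline
analysis/           numbered narrative drivers (write results/)
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     model assumptions, parameter choices, limitations
```
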