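# mitomorph

Quantitative analysis of mitochondrial network morphology and label-free proteomics for
cellular models of Parkin (PARK2) loss-of-function — fibroblasts from patients versus
controls, with and without CCCP-induced mitochondrial depolarization.

The package is aimed at imaging and proteomics analysts who need the full measurement
chain to be reproducible and testable: every stage runs on synthetic data with known
ground truth, and every statistical operator is checked against an independent oracle.

## What it computes

**Morphology arm** (fluorescence micrographs → distributional statistics):

1. per-slice unsharp mask, automatic Huang threshold, cleanup → binary masks;
2. per-particle shape descriptors — Area, Perimeter, Major/Minor axis, Angle, Aspect
   ratio, Circularity (4πA/P²), Roundness (4A/π·major²), Solidity (A/A_hull);
3. skeleton metrics — branches, junctions, individuals, networks, mean branch length,
   mean network size, footprint;
4. for each sample unit and parameter, the two-sample Kolmogorov–Smirnov distance

       D = sup_x | F̂_unit(x) − F̂_ref(x) |

   to the pooled CTRL/DMSO particle reference (leave-one-out for units inside the
   pool), followed by a balanced two-way ANOVA of D on mutation × treatment with
   interaction; Wilcoxon rank-sum tests for skeleton summaries;
5. marker quantification per μm² of mitochondrial area (IsoData mask of the
   max-projected mitochondrial channel) and cell-normalized whole-image fluorescence.

**Proteomics arm** (replicate-level log2(P/C) tables → differential results):
median/variance summaries over technical replicates, isoform collapse to root
accessions, a summary-statistics t test (t = ratio/√(variance/n), df = n−1), the filter
chain *detected in ≥ 2 of 3 replicates* → *|log2 ratio| ≥ |log2 1.30| = 0.38* → *p ≤ α*
(condition-unique proteins bypass ratio/p but count as altered), volcano table, ranked
list, and pre-ranked permutation gene-set enrichment (weighted running-sum ES,
gene-label permutations, Benjamini–Hochberg).

A synthetic-data module generates the 2×2 study (filamentous vs fragmented mitochondria,
Gaussian PSF, Poisson noise, marker enrichment) and PLGS-style quant tables with planted
effects, missingness, uniques and isoforms. See `docs/methods.md` for model details and
conventions.

## Worked example

```python
from mitomorph.synthetic import ImageSimConfig, StudyDesign, simulate_population
from mitomorph.pipeline import MorphologyParams, analyze_study

base = ImageSimConfig(image_shape=(96, 96), n_slices=1, n_filaments=8,
                      filament_length_um=(2.5, 0.8), fragment_fraction=0.2)
# depolarization fragments the network; mass conservation raises object count
ov = {("CTRL", "CCCP"): {"fragment_fraction": 1.0, "n_filaments": 24},
      ("MUT",  "CCCP"): {"fragment_fraction": 1.0, "n_filaments": 24}}
design = StudyDesign(n_subjects_per_group=3, n_fov_per_sample=3,
                     base_config=base, overrides=ov, seed=42)
res = analyze_study(simulate_population(design),
                    MorphologyParams(parameters=("circularity",), with_skeleton=False))
print(res.distances["circularity"].groupby(["group", "treatment"])["D"].mean().round(3))
print(res.anova["circularity"].table.round(4))
```

prints

```
group  treatment
CTRL   CCCP         0.505
       DMSO         0.362
MUT    CCCP         0.553
       DMSO         0.272
                 SS    df      MS        F       p
mutation     0.0039   1.0  0.0039   0.7161  0.4037
treatment    0.4040   1.0  0.4040  73.7046  0.0000
interaction  0.0434   1.0  0.0434   7.9186  0.0083
error        0.1754  32.0  0.0055      NaN     NaN
```

CCCP-treated cells sit much farther from the CTRL/DMSO reference distribution (mean
D ≈ 0.51–0.55 versus ≈ 0.27–0.36), and the ANOVA attributes the variance to the
treatment factor (F = 73.7, p < 10⁻⁴) rather than the genotype (p = 0.40) — the planted
configuration only fragmented the network under treatment.

On the proteomics side:

```python
from mitomorph.synthetic import ProteomeSimConfig, simulate_proteome_table
from mitomorph.pipeline import run_proteomics

tab = simulate_proteome_table(ProteomeSimConfig(
    n_proteins=1000, frac_changed=0.2, effect_size_log2=2.0,
    replicate_cv=0.1, frac_unique=0.05, seed=42))
print(run_proteomics(tab, alpha=0.05)["diff"].counts)
```

```
{'n_input': 1000, 'n_after_replicate_filter': 992, 'n_after_fc_filter': 249,
 'n_after_p_filter': 246, 'n_unique_included': 50}
```

Of 1000 simulated proteins, 992 pass the 2-of-3 detection rule, 249 the ±0.38 log2
fold-change gate and 246 the significance gate; the 246 retained ≈ the 200 planted
changed proteins plus the 50 condition-unique ones, with a handful lost to missingness.

A command line wraps the same pipelines: `mitomorph simulate`, `mitomorph morphology`,
`mitomorph proteomics` (see `--help`).

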