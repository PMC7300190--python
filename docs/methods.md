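# Methods

`mitomorph` re-implements, as a tested pipeline, two quantitative workflows used to
characterize fibroblasts carrying loss-of-function mutations in the gene encoding the
Parkin E3 ubiquitin ligase: (i) morphometry of the mitochondrial network in fluorescence
micrographs, with a distributional test of whether genotype or chemical depolarization
(CCCP) shifts particle shape, and (ii) a label-free quantitative (LFQ) proteomics
differential-abundance workflow with ranked-list gene-set enrichment.  A synthetic-data
generator supplies images and quantification tables with known ground truth, so every
stage is testable without the original micrographs or mass spectra.

## Image analysis

### Segmentation

Each z-slice is sharpened with an unsharp mask, `(I − w·G_σ(I)) / (1 − w)` with Gaussian
blur `G_σ` (reflective boundary) and defaults σ = 1 px, w = 0.6 — the common tool
convention; neither value is prescribed by the morphology protocol itself, so both are
recorded in output provenance.  The result is clipped to the valid intensity range.

Automatic thresholds operate on 256-bin gray-level histograms (real-valued images are
min–max binned; the chosen level maps back to intensity units; foreground is *strictly
greater* than the threshold):

* **Huang threshold** (mitochondrial channel): minimizes Huang–Wang fuzziness.  For each
  candidate level t, class means μ₀, μ₁ give memberships u(g) = 1/(1 + |g − μ| / C) with
  C the occupied gray range; the minimizer of the Shannon entropy −Σ h(g)[u ln u +
  (1−u) ln(1−u)] is returned.  When the minimum is a plateau (e.g. two well-separated
  spikes), the plateau midpoint is used, which splits separated modes symmetrically.
* **IsoData threshold** (immunofluorescence quantification): iterative intermeans,
  T ← (mean below T + mean above T)/2 from the global mean until an integer fixed point.

Cleanup removes 8-connected components below a minimum area (default 5 px, exposed as
configuration — the protocol's "aberrant object" removal is otherwise unspecified) and,
optionally, components touching the border.  Thresholds are computed per slice on stacks
by default; a global threshold is a configuration option.

### Shape descriptors

Per 8-connected component: area (pixel count × pixel size²); perimeter; an
area-preserving moment ellipse (axes from the second central moments, rescaled so the
ellipse area equals the particle area; the major-axis angle is reported versus the image
x-axis, y up, in [0, 180)); aspect ratio; circularity 4πA/P²; roundness 4A/(π·major²);
solidity A/A_convex.  Circularity and roundness are capped at 1 because digitization can
push them above the theoretical range.  Z-stacks are measured slice-wise and particles
pooled into one distribution; there is no 3-D linking.

**Perimeter convention.**  Digitized perimeters are estimator-dependent, and the original
tool's corrected estimator is undocumented, so the convention here is explicit: the
length of the crack (pixel-edge) boundary, with *staircase* corners — a convex corner
adjacent to a concave or diagonal-contact corner, i.e. a digitization jog — smoothed by a
√2 chord (each smoothed corner shortens the walk by 2 − √2).  Isolated right angles are
preserved.  Consequences, asserted in the tests: axis-aligned rectangles measure their
exact edge length (a 10×10 px square at 0.1 μm/px has perimeter 4.00 μm and circularity
π/4), while rasterized disks approach the true circle perimeter (circularity and
roundness in [0.95, 1] for a radius-50 px disk).  An uncorrected chain or crack walk
cannot satisfy both: the pure crack boundary of a disk is 8r (circularity ≈ 0.62) and the
pixel-center chain of the square is 36 steps, so some smoothing rule is unavoidable;
smoothing only digitization jogs is the smallest one.  Divergence from other tools'
perimeters is expected and documented rather than chased.

### Skeleton metrics

Masks are thinned (topology-preserving, per max projection by default).  Skeleton pixels
are classed by 8-neighbor count: endpoints (< 2), slab (2), junctions (> 2).  Branches
are maximal slab paths between anchors; lengths accumulate 1 / √2 steps × pixel size.
Components without junction pixels are *individuals* (one branch each); components with
junctions are *networks*; "mean network size" is interpreted as mean branches per network
(the term is not formally defined in the protocol; the interpretation is stated in the
output docs).  `n_junctions` counts raw junction pixels, matching the pixel-count
definition; adjacent junction pixels are additionally merged into nodes for branch
tracing and the merged count is reported alongside.  Branch tracing visits neighbors in
a fixed scan order, so counts are reproducible under ties.

### Distance statistics

For every morphology parameter, the particle values of each sample unit (field of view by
default; subject-level pooling is a configuration option) are compared with the pooled
reference of all control/vehicle (CTRL/DMSO) particles by the two-sample
Kolmogorov–Smirnov distance D.  When the unit itself belongs to the reference pool, its
particles are excluded from the pool for its own comparison (leave-one-out, default on):
comparing a unit partly against itself biases its D toward zero and would masquerade as a
group effect.  D is computed on raw values; the KS statistic is invariant under strictly
increasing transforms, so the log transform used for circularity density plots never
changes D.  Kernel density estimates (Gaussian kernel, bandwidth 0.9·min(sd, IQR/1.34)·
n^(−1/5), 512-point grid spanning the data ± 3 bandwidths) are computed for plotting
only.

The per-unit distances enter a balanced fixed-effects two-way ANOVA (mutation ×
treatment, with interaction; closed-form sums of squares, F = MS/MS_error).  All
distances enter the ANOVA; per-unit KS p-values are reported alongside rather than used
to pre-filter responses, since selecting responses by their own significance before an
ANOVA is indefensible.  Skeleton summaries are compared with the two-sided Wilcoxon
rank-sum test (exact enumeration for n + m ≤ 12 without ties, otherwise the normal
approximation with continuity and tie corrections).

### Marker quantification

The mitochondrial area is the IsoData mask of the max-projected mitochondrial channel;
the marker channel (similarly projected) is integrated inside that mask and divided by
the mask area in μm².  No background subtraction is applied by default (the protocol does
not state any); a flag is provided.  Whole-image fluorescence is normalized by an
externally supplied cell count or cell area — nuclei segmentation is out of scope, and
the simulator provides the truth denominator.

## Synthetic image generator

Filamentous mitochondria are cubic-spline-smoothed bounded-curvature random walks
(length ~ N(4, 1.5²) μm by default, width 0.4 μm, one side branch with probability 0.3);
fragmented mitochondria are filled ellipses (axes ~ 0.8 × 0.5 μm).  The
`fragment_fraction` dial converts the population from network-like to punctate.  Objects
are rendered into a binary truth mask, optionally spread over z-slices with Gaussian
z-weights (the acquisition uses 0.2 μm stepped stacks but analysis is per-slice), blurred
with a Gaussian PSF (σ = 0.15 μm) and corrupted with Poisson shot noise on
(background + photon_scale · signal); defaults background = 50, photon_scale = 150 give a
foreground:background ratio ≈ 4:1, a typical confocal regime in which both automatic
thresholds are stable.  There is no read noise, photobleaching or 3-D PSF.  The marker
channel multiplies the signal by `marker_enrichment` inside the truth mask, so
marker-per-area recovers a known ratio.  The default study design mirrors the experiment:
2 groups × 2 treatments × 5 subjects × 5 fields of view, balanced, with per-cell
configuration overrides; every image draws an independent child seed, and identical
configurations are bit-reproducible.

What the generator does *not* emulate — cell boundaries, spatially varying background,
optical sectioning cross-talk, or genuine biological heterogeneity between subjects —
bounds what passing tests show: they validate the statistical machinery and its
calibration, not performance on real micrographs.

### Simulated-study calibration

Repeated-study simulations use scaled-down conditions chosen once: 96 × 96 px fields
(0.1 μm/px), single slice, 8 filaments, fragment_fraction 0.2, 3 subjects × 3 fields of
view per cell.  Under the null (identical configuration in all cells) the ANOVA on
circularity distances rejects each factor at α = 0.05 in ~4.5–5.5% of 400 studies.  For
power, CCCP cells are simulated fully fragmented; because depolarization fragments
existing filaments, total mitochondrial mass is conserved and the object count rises
(8 filaments → 24 fragments).  The treatment factor is then detected in > 80% of studies
while the (unplanted) mutation factor stays at its nominal rate — the qualitative
structure reported for the original experiment, where treatment, not genotype, was the
significant source of variance.

## Proteomics workflow

Input is a replicate-level table of log2(patient/control) ratios over three technical
replicates (missing values = not detected).  Per protein: summary ratio = median of
detected replicates, variance across them, detection count.  Isoforms (`ACC-2` suffixes)
collapse to the root accession with median ratio and variance and maximum detection.
The summary p-value is a two-sided one-sample t test computed from the summary statistics
alone (t = ratio / √(variance/n), df = n − 1, with n the detection count) — the canonical
test expressible in "variance, ratio and sample size".  The filter chain retains proteins
detected in ≥ 2 of 3 replicates with |log2 ratio| ≥ |log2 1.30| = 0.3785… (stored exactly,
displayed as 0.38; inclusive comparison) and p ≤ α.  α is a required configuration value
(default 0.05); the upstream software's significance call is not documented.
Condition-unique proteins carry no ratio: they bypass the ratio/p filters, must satisfy
the detection rule, count among the retained "altered" proteins, and are excluded from
the volcano plot and the ranked list.  The upstream "automatic normalization" is not
replicated; optional median-centering of log2 ratios is provided and off by default.

The ranked list (log2 ratio descending, ties broken by accession) feeds a pre-ranked
permutation enrichment: running sum with hit increments |metric|/Σ_hits|metric| and miss
decrements 1/(N − N_hit); ES is the maximum absolute deviation (signed); the null
permutes gene labels (default 10,000 permutations); two-sided permutation p with the
+1 correction; Benjamini–Hochberg adjustment across sets.  Gene sets are user-supplied
(GMT); no pathway database is bundled or fetched.

The proteome simulator plants a fraction of changed proteins at ± effect log2 units,
per-replicate noise sd log2(1 + CV), per-replicate missingness, condition-unique
proteins, and isoform groups.  At effect 2.0, CV 0.1, n = 3, the filter chain recovers
changed proteins with sensitivity ≥ 95% at false-positive rate ≪ α (the fold-change gate
dominates, making the chain conservative for null proteins).

## Numerical and design notes

* Degenerate inputs: constant images have no threshold (error); constant samples have no
  density estimate (error); all-equal ANOVA responses report SS = 0 with F = NaN and a
  degeneracy flag; variance-zero proteins get p ∈ {0, 1} by the sign of the ratio.
* Blinded analysis is supported in software form: sample identities can be scrambled to
  anonymous codes before image analysis and restored from a key table at the statistics
  stage; since the measurement stages never read the labels, blinded and open runs are
  verified to produce identical numbers.
* All randomness flows through seeded NumPy generators; study-level seeds spawn
  independent child seeds per image.  Pipeline outputs are byte-reproducible given the
  same configuration and inputs, and a provenance JSON records all parameters.
* Known limitations: no 3-D morphometry or skeleton graphs; no deconvolution or learned
  segmentation; the perimeter convention (above) will not numerically match other tools;
  unbalanced designs are rejected rather than approximated; enrichment uses gene-label
  permutation, not phenotype permutation.
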