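# Methods

This note documents the models, conventions and design choices behind the
two analysis arms, what the synthetic data do and do not emulate, and the
problem sizes the test-bed uses.

## Imaging arm

### Background model and positivity rule

Each atlas subregion is assumed to have its own scalar background offset per
channel.  Background statistics are the mean and SD of the channel intensity
over all pixels of a subregion that belong to no detected nucleus and no
detected cell body.  A subregion left without any object-free pixel is
flagged and may not be consumed downstream (this surfaces as an error rather
than a silent NaN).

A cell is called positive for a marker when its raw mean intensity is at
least `μ_bg + k·σ_bg` of its own subregion (default `k = 2`, configurable).
The upstream protocol this formalizes states only that the threshold is
"based on the channel background noise"; the mean-plus-k-sigma form is the
simplest rule with a tunable stringency, and every run carries the realized
per-subregion thresholds in its background table.  Background-subtracted
intensities (`raw − μ_bg`) are recorded for reporting but deliberately not
clamped at zero, so intensity distributions keep their shape for
distribution-level comparisons (e.g. Kolmogorov-Smirnov between age
groups); classification always uses raw values, so clamping could never
change a class.

### Measurement of boundary-straddling objects

Objects are attributed to the subregion under their centroid pixel.  A cell
whose mask straddles a subregion boundary would mix the neighbouring
subregion's background offset into its mean intensity, biasing both its
normalized intensity and its classification.  Intensity means are therefore
computed over the object's pixels *within its own subregion* (falling back
to the full mask for the degenerate case of an object with no pixel in its
centroid's subregion).  This makes classification exactly invariant to
adding a constant to any one subregion's channel, a property the test suite
asserts.

### Nucleus–cell association

Two rules mirror the two acquisition workflows:

* `centroid2d` (slide-scanner): a nucleus is assigned to the cell whose
  mask contains its rounded centroid pixel;
* `halfvolume3d` (confocal z-stacks): a nucleus is assigned to a cell when
  at least half of its voxels — inclusive at exactly 50 % — lie inside the
  cell mask.

Each cell keeps at most one nucleus; when several qualify, the largest
mask overlap wins, with ties broken by the lowest nucleus id so the
assignment is deterministic.  Cells without an assigned nucleus are
discarded and reported in a discard list; they appear nowhere else.
Intensity means in 3D are taken over the full 3D mask, not a single plane.

### Detection

The deep-learning segmenters used on real acquisitions (StarDist for
nuclei, Cellpose for cell bodies) are external pretrained models and are
deliberately out of scope.  The package exposes:

* a built-in classical segmenter (Gaussian smoothing, Otsu threshold,
  distance-transform watershed, connected components) that is sufficient
  for synthetic images — a constant image yields an empty label map rather
  than an error;
* a file-based adapter contract (input intensity TIFF → output label TIFF,
  arbitrary command template) for plugging in any external tool, with model
  hyperparameters passed through untouched.

Detection may run on an integer-downscaled image; label maps are rescaled
back by nearest neighbour, which preserves label identities exactly and
scales per-label pixel counts by the square (2D) or cube (3D) of the
factor.  Object filters (size window, background-derived intensity floor)
are idempotent and log the violated criterion per removed object.
Detection quality is scored as `AP = TP/(TP+FP+FN)` after greedy
descending-IoU matching with lexicographic tie-breaks; at the conventional
0.5 threshold and disjoint instances this matching coincides with the
maximum-cardinality matching (asserted against an independent graph
matcher on random instances).  Empty-vs-empty scores AP = 1 by convention,
predictions against an empty ground truth score 0.

### Region roll-ups

Areas are exact unit conversions (`pixels × (µm/px)² / 10⁶` → mm²;
volumes analogously in mm³).  Parent-region and brain-wide summaries sum
counts and areas and pool per-cell intensity lists; densities are always
recomputed from pooled counts and never averaged across children.

## Genomics arm

### Locus annotation QC

Full-length coding LINE-1 loci (UIDs) carry three quality annotations:

* **family** (L1HS / L1PA2) — carried by the fixture or input BED;
* **genic context** — a locus overlapping any gene body by ≥ 1 bp is
  *intronic* with the longest-overlap gene as host (ties broken by gene
  id); otherwise *intergenic*.  No exon model is consulted: the partition
  is the binary genic/intergenic one used in locus-level repeat QC.
* **mappability score** — the number of unique-50mer genomic regions
  overlapping the locus interval by at least 45 bp (inclusive), a proxy for
  how much of the locus is reachable by uniquely mapping short reads.

Intervals are 0-based half-open internally; GTF input/output is converted
at the boundary.

### Count filtering, normalization, group tests

Low-count rows are filtered by the rule *count above a threshold in at
least `n` samples*, with `n` defaulting to the size of the smaller age
group.  Two variants exist in upstream practice — a strict keep-rule
(`> 3` reads, locus-level default) and an inclusive gene-level rule
(`≥ 10` reads); both are exposed as `(threshold, strict)` configuration
rather than silently merged.

Size factors are median-of-ratios against a geometric-mean pseudo-reference
over zero-free rows.  Factors are identifiable only up to a common scalar,
so all checks are on factor ratios.  Locus panels are far too small to
anchor the median, so factors should be (and in the benchmarks are)
estimated on a large gene + repeat matrix and applied to the locus
submatrix.

Differential locus expression uses a two-sided Mann-Whitney test per locus
on normalized counts with Benjamini-Hochberg adjustment across loci and a
pseudocount-1 log2 fold change of group means.  A negative-binomial GLM
(DESeq2-style Wald test) is deliberately not reimplemented; the rank-based
test is the documented surrogate and is also the test the headline
locus-level comparisons use.  Constant rows get p = 1 by convention and are
logged.  Global trends are summarized two ways: per-locus group means
paired across the locus axis (Wilcoxon matched signed-rank; requires ≥ 6
loci so the exact null is non-degenerate) and per-sample totals over loci
(two-sided Mann-Whitney).  Regulator relationships are tie-corrected
Spearman correlations, with entities failing the expression threshold
(> 3 normalized reads in > 6 samples) excluded and listed.

Age grouping is fixed at young ≤ 65 y < aged.

## Statistical procedures

* **Mann-Whitney** — exact enumeration when both groups have ≤ 10
  observations and no ties; otherwise the tie-corrected normal
  approximation.  Identical samples report p = 1.
* **Wilcoxon signed-rank** — zero differences dropped (the mainstream
  software default), exact enumeration up to 12 untied nonzero differences,
  tie-corrected normal approximation otherwise.
* **Chi-square** — Pearson statistic without continuity correction (cell
  counts in the imaging comparisons are in the hundreds to thousands).
* **FDR** — Benjamini-Hochberg step-up and the two-stage sharpened
  Benjamini-Krieger-Yekutieli procedure; output order matches input.
* **Nested comparison** — conditions with animals nested inside and cells
  nested in animals.  Balanced designs use the classical nested ANOVA
  `F = MS(condition)/MS(animal within condition)`; unbalanced designs fall
  back to one-way ANOVA on animal means (flagged in the result), which is
  algebraically identical in the balanced case.  The animal, not the cell,
  is the experimental unit.
* **Post-hoc power** — noncentral-t power of the two-sided two-sample
  pooled-variance t test; zero effect returns exactly α.
* **Representation factor** — `k·N/(n1·n2)` with an exact upper-tail
  hypergeometric p-value, symmetric in the two set sizes.
* **Interactor selection** — a protein is *enriched* with ≥ 3 peptides in
  every target-IP replicate AND ≥ 10-fold enrichment AND adjusted p ≤ 0.05
  (a strict conjunction: one replicate at 2 peptides rejects), or *unique*
  with ≥ 3 peptides in every target replicate and zero control detection.

Where a procedure is backed by scipy/statsmodels, the test suite verifies
it against independent enumeration or closed-form oracles computed in the
tests themselves, so the convention choices above (not the library) define
the behaviour.

## Synthetic data: what it emulates, and what it does not

* **Images** — cells are disks (2D) or spheres (3D) with a concentric
  nucleus; the neuronal marker is a cytoplasmic annulus (nucleus excluded),
  the target marker fills the whole body of target-positive cells.  Signal
  amplitudes are log-normal and added on top of an i.i.d. Gaussian
  per-subregion background clipped at zero.  Counts are Poisson in density
  × area; class flags are Bernoulli with programmed fractions; an
  `age_effect` factor multiplies target amplitudes, and because placement
  and amplitude draws come from a stream independent of the background
  noise, two cohorts generated from the same seeds differ *only* by that
  factor (common random numbers), which is how the fold-change recovery
  benchmark isolates the programmed 13 % effect.  Non-overlap is enforced
  by bounded rejection sampling (100 retries per cell; saturation is an
  error naming the subregion).  The generator does not attempt
  photorealism: no point-spread blur, no autofluorescence (e.g.
  lipofuscin), no shading fields by default, no out-of-focus structure.
  Passing recovery tests therefore demonstrates correctness of the
  quantification logic, not robustness to real microscopy artifacts.
* **Locus fixtures** — ≥ 6 kb elements placed without overlap on a small
  synthetic genome (2 × 5 Mb by default), exact family allocation by
  largest remainder, a programmed intronic fraction placed strictly inside
  generated gene bodies, and unique-mer regions of ≥ 50 bp scattered at
  ~2 regions/kb (the approximate genome-wide density of the real
  unique-50mer track).  Sequence content is not modelled — only interval
  structure.
* **Counts** — negative-binomial with mean
  `baseline × size_factor × fold^[aged]` and variance `μ + αμ²`; donor ages
  are drawn uniformly inside each group's range (38–65, 66–97).  Library
  composition effects and gene-length biases are not modelled.
* **Protein tables** — spiked interactors satisfy every selection
  criterion; background proteins each violate at least one, with nonzero
  control signal so the uniqueness branch cannot rescue them.

## Benchmark problem sizes and calibrations

Chosen to pin the statistical targets while keeping the full suite fast:

* *Imaging parameter recovery*: 4 equal subregions on a 1024² image at
  1 µm/px (≈ 1.05 mm²), density 300 cells/mm², target fractions
  0.10/0.17/0.24/0.31, 20 seeds pooled; recovery asserted within 3
  percentage points (fractions) and 3σ of the Poisson expectation
  (counts).  Ground-truth masks are injected so the check isolates the
  quantification, not the segmenter.
* *Aging fold change*: 20 seed-paired cohorts at 512², `age_effect = 1.13`;
  the pooled mean-intensity ratio must land in [1.10, 1.16].
* *Differential locus pipeline*: an 8-locus panel with one programmed
  2-fold locus (baseline 100, NB dispersion 0.1, n = 6 young vs 35 aged),
  normalized against a 200-row background matrix.  The panel size was fixed
  by a design-time power analysis of the implemented test convention
  (expected detection ≈ 0.92 at adjusted p < 0.05, measured over
  6/8/10/12-locus panels); the suite asserts ≥ 80 % detection over 100
  seeds, a type-I fraction in [0.03, 0.07] over 200 null panels, and a mean
  log2 fold-change bias below 0.1 over 50 seeds.
* *Oracle suites*: 200–500 random instances per oracle (greedy matcher vs
  maximum matching; interval arithmetic vs brute force; exact rank tests vs
  enumeration at n ≤ 8–12).

## Known limitations

* The built-in segmenter is a testing vehicle; real acquisitions need the
  external-adapter route and a trained model.
* Centroid attribution assigns a boundary-straddling cell wholly to one
  subregion; sub-pixel splitting is not attempted.
* The rank-based locus test does not model NB mean-variance structure and
  is conservative for very small groups; exact enumeration is limited to
  untied small samples.
* Mappability scoring depends entirely on the supplied unique-k-mer track;
  reproducing published per-locus scores requires the original external
  track and locus coordinates, which are not bundled.
* The two-stage BKY procedure is implemented in its sharpened linear
  step-up form; other adaptive variants are not offered.
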