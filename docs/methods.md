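# Methods

This note documents the models, estimators and numerical choices behind
pchquant, and what the synthetic generators do and do not emulate.

## Ratio model and normalisation

Each sample is light-labelled and mixed with one pooled medium-heavy
reference, so the measured quantity per protein and sample is H/L =
(reference abundance)/(sample abundance × multiplicative error). Quotients
of two samples' H/L values cancel the reference exactly, which is why all
comparisons (PCH/nuclei within a tissue, brain-PCH/liver-PCH across
tissues) are formed as H/L quotients.

Ratios supported by fewer than `min_ratio_count = 2` peptide-level
measurements are treated as missing *per sample* (stricter than a per-row
rule, and stated as such); rows flagged as reverse decoys or potential
contaminants are removed first. Filtering precedes normalisation. Missing
values propagate; there is no imputation.

**Mode normalisation.** Each sample's ratios are divided by the sample's
most frequent ratio so unchanged proteins centre at 1. The mode is the
argmax of a Gaussian kernel density of the log2 ratios (Silverman
bandwidth, 512-point grid spanning the data). The grid construction is
shift-equivariant, so re-estimating the mode on normalised data returns
exactly 0; the contract "post-normalisation mode within ±0.02 log2 units"
holds with margin. The estimator requires ≥ 10 non-missing ratios per
sample and falls back to the common value for constant samples.

**Replicate summary.** Ratios are multiplicative, so replicate values are
combined by geometric mean; the per-protein replicate count and the log2
standard deviation (ddof = 1, undefined for singletons) are carried along.

## Hit selection

1. *Replicate intersection*: a protein must yield all three comparison
   ratios (PCH/nuclei per tissue, brain/liver) in every replicate
   (`n_required` defaults to the replicate count; 1 degenerates to the
   union).
2. *Common enrichment*: strict `e_brain > 1 AND e_liver > 1`. Proteins
   quantified in only one tissue are excluded — commonality is the point
   of this stage.
3. *Percentile classification*: sort by the brain/liver log2 ratio
   descending with protein id as a deterministic tie-break;
   `k = round(0.10·n)` (half away from zero) per tail. The tail counts are
   count-based, not intensity-weighted.
4. *Reference cut-off*: threshold = the reference protein's (gene `Atrx`)
   brain PCH/nuclei enrichment; retention is inclusive (≥) so the boundary
   protein survives its own cut-off. Anchoring is brain-side only. The
   cut-off is scale-invariant under per-sample normalisation error because
   the reference is measured in the same samples.

The abundance coordinate for plot-ready output is log10 of the mean
PCH-fraction intensity across tissues and replicates. Tail classification
is reported both before and after the cut-off (the post-cut-off
classification requires ≥ 10 validated proteins).

## Term enrichment

Two-list over-representation: enrichment `(b/n)/(B/N)` and upper-tail
hypergeometric `P[X ≥ b]`, X ~ Hypergeometric(N, B, n), per term with at
least one background gene. Genes missing from the annotation count toward
`n` and `N` but hit no term. **No multiple-testing correction is applied**
— results are filtered at a raw p < 5×10⁻⁵, so p-values must be read as
descriptive screening scores, not error-controlled inferences. Redundancy
removal is automatic: terms with identical target hit sets collapse to the
one with the smallest background count (most specific), ties broken by
term id. There is no ontology-graph propagation; the annotation is taken
as given.

## Image quantification

Axis order is (z,)y,x, voxel coordinates 0-based; 2D images are handled by
the same dimension-agnostic code paths. All physical quantities use the
per-axis voxel size (µm), so anisotropic stacks (e.g. 0.3 µm z-steps with
~0.1–0.2 µm pixels) are handled.

* *Nuclei*: global Otsu threshold, hole filling, removal of objects below
  10 µm² (2D) / 50 µm³ (3D), full-connectivity labelling; optional
  distance-transform watershed for touching nuclei.
* *Foci*: per-nucleus threshold mean + 1.5·sd of in-nucleus DNA intensity
  (`k_sd` configurable), connected components of ≥ 2 voxels, globally
  unique labels. The k = 1.5 default assumes foci occupy a modest fraction
  of the nucleus (≲ 15% of its area); dominant-focus nuclei would push the
  mean and sd up and need a lower k.
* *Statistics*: accumulation = mean focus intensity / mean nucleoplasm
  intensity, where the nucleoplasm excludes a 1-voxel dilation of the foci
  so partial-volume halos cannot inflate the denominator; fraction in PCH
  = 100 × (summed focus fluorescence / summed nucleus fluorescence); mean
  PCH size = total focus volume / focus count. Nuclei without foci or
  without nucleoplasm report accumulation as missing.
* *Particles*: Gaussian smoothing (σ = 1 px) then local maxima above an
  absolute threshold (Otsu of the smoothed image when unset) with a 3 px
  minimum separation — closer peaks merge into one detection. Densities
  are counts per physical region size for three region kinds: all foci,
  foci inside nuclei, whole nuclei.

**Group tests.** The rank-sum (Mann-Whitney) test uses exhaustive
enumeration of all group labelings when the total sample size is ≤ 12
(midranks under ties; the two-sided p counts labelings whose rank-sum
deviation from its mean is at least the observed one, so identical groups
give p = 1), and the tie- and continuity-corrected normal approximation
otherwise. The t-test is the classical pooled-variance unpaired Student's
test (not Welch). The H1×MeCP2 cross-level summary bins cells into
quantile bins (tertiles by default; the bin rule is a package choice) of
total H1 and total MeCP2 signal and reports per-bin mean accumulations and
mean compartment size, with empty bins reported missing.

## Synthetic generators

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical configs are byte-stable, asserted by
hashing in the tests.

**Proteomics.** Six planted classes (30 proteins each by default):
conserved PCH-enriched, brain- and liver-upregulated (both at a 4-fold
PCH/nuclei enrichment; tissue classes additionally 4-fold more abundant in
their tissue, split symmetrically between tissues), general chromatin
background (fold exactly 1), and two contaminant classes whose folds are
drawn log2-uniformly between 1 and the reference fold with abundances in
the bottom third of the 10⁶–10⁹ intensity range — they pass the plain > 1
filter but fall below the validation cut-off, exercising it. The reference
protein (gene `Atrx`) is planted as a conserved-class protein at exactly
the boundary fold (2 by default, the minimum among enriched classes).
Measurement noise is multiplicative log-normal (0.2 log2 units per
replicate by default — a free parameter, not an estimate from real data).
Missingness has two channels: whole-replicate dropout (default 0.1 per
protein and replicate) and low peptide evidence (default 5% of quantified
cells get ratio count 1, which the standard filter removes). Decoy rows
(5% each reverse/contaminant) are appended outside the planted truth. The
pooled reference is the equal mix of the four light samples; its level
cancels in all quotients.

The generator starts at the protein-group table: no spectra, peptide
evidence or search-engine behaviour are simulated, and per-protein
variance/dropout defaults are design choices, not estimates of the
deposited data set.

**Imaging.** Nuclei are disks/spheres of nucleoplasm-level intensity
(default 100 on a background of 20) with circular foci at a 3× DNA
contrast; protein channels repeat the geometry at their own planted fold.
Placement is rejection sampling (1000 retries; failure raises a
"placement failure" error) with a minimum boundary gap between nuclei and
non-touching foci kept off the nuclear rim. Noise is additive Gaussian,
clipped at zero. Real images differ in every optical respect — no PSF
blurring, photon statistics, uneven illumination, or out-of-focus light —
so passing tests demonstrate correctness of the measurement operators, not
of segmentation robustness on microscope data; absolute counts from real
images are not expected to match any published figure.

**Cell populations.** The competition model plants
`accumulation_A = base_A / (1 + k·level_B)` and compartment size
`s0·(1 + a·MeCP2 − b·H1)` clipped positive (defaults: base 3, s0 2 µm²,
a = b = 0.3, levels uniform in [0.5, 2]); with k = 0 the proteins are
independent by construction.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 181–1801 simulated
proteins, image fields of ≤ 500×500 pixels with ≤ 20 nuclei, exhaustive
statistical enumerations up to total n = 12. These sizes were chosen so
that every planted effect is resolvable with wide margins while the whole
suite runs in seconds. Headline counts from the deposited tissue data set
(e.g. the size of a validated hit list) depend on the raw LC-MS/MS data
and the upstream database search and are out of scope; the package
verifies the selection *rules*, not those counts.

## Known limitations

* The mode estimator's KDE argmax is grid-quantised (≈ data-range/511
  log2 units); irrelevant at the contract tolerance but visible at 1e-3.
* Watershed splitting of touching nuclei uses a fixed 1 µm peak
  separation heuristic and is off by default.
* The unranked enrichment statistic ignores ranking information entirely;
  a ranked-list statistic is out of scope.
* Filtering precedes normalisation; if the upstream convention normalised
  first, sample modes could shift slightly (the contract tolerance of
  ±0.02 log2 units absorbs this at realistic sizes).
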