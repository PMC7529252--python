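# Methods

## Segregation model

One meiosis is modeled per homolog pair, independently across pairs.
After pre-meiotic S phase every pair consists of two homologs of two
sister chromatids each (four chromatids per pair).  The tetrad is laid
out as spermatids 0,1 (from meiosis I pole 0) and 2,3 (pole 1).

**Meiosis I.**  A *bivalent* sends one homolog to each pole.  Because
pole labels carry no physical meaning, the orientation of this 1:1
split is fixed by convention (homolog a → pole 0) rather than treated
as a random choice; all per-spermatid marginals are invariant under
pole relabeling, and the convention keeps the all-bivalent karyotype a
single certain outcome.  A *univalent pair* — the state after loss of
conjunction — sends each homolog, as one intact 2-chromatid unit, to
either pole with probability ½, independently.  Univalents are never
split at meiosis I: live imaging shows a univalent travels with a
single centromere signal.

**Meiosis II.**  `regular_sisters` places one chromatid of every
chromosome in each of its pole's two spermatids.  `random_chromatids`
tosses each chromatid independently (so 2:0 splits occur with
probability ½ per chromosome).  The independent-chromatid reading is
the one that yields the printed 0/RG prediction of 2.77 = ⌊100·25/9⌋/100;
a constrained 1:1 "random" split would collapse the prediction to 1 and
be indistinguishable from regular segregation by this assay.

All enumeration is carried out per pair over the elementary equiprobable
choices and combined as an outer product, using `fractions.Fraction`
throughout, so every probability and ratio is exact.  Scenarios are
capped at 8 pairs, and the joint enumeration additionally guards the
product support size (2×10⁶ states); the Monte Carlo twin
(`simulate_meioses`, one `numpy` generator per call, seed recorded on
the sample) covers anything larger.

**FISH classes** are presence-based: a spermatid shows a red (green)
signal if it carries ≥1 chromatid of the red- (green-) probed
chromosome.  Two chromatids of the same chromosome are not counted as
two spots, because such nuclei cannot be scored reliably in practice;
the scoring module routes observed ≥2-same-color nuclei to an
`unscored_multisignal` bin excluded from all fractions.  Ratios with a
zero denominator raise `UndefinedRatioError` rather than returning
inf/NaN — silent sentinels would corrupt cross-cyst aggregation.

**0/RG truncation.**  25/9 = 2.777… is displayed as 2.77 (truncation to
two decimals, not rounding); the acceptance script reports the
truncated value because that is the display convention of the quantity
it reproduces.

**DNA-content statistic.**  A cyst pools `spermatids_per_cyst / 4`
complete tetrads (64 spermatids by default, the biological cyst size).
Per-nucleus content is Σ chromatid count × per-chromatid DNA content;
contents are divided by the cyst mean and the sample (n−1) s.d. of the
normalized values is the statistic.  For 8 unit-content univalents with
regular meiosis II the spermatid content is Binomial(8, ½) (mean 4,
variance 2), so the statistic converges to √2/4 ≈ 0.3536; at cyst size
64 the per-cyst estimate scatters by ≈0.035, which sets the tolerances
used in the tests.

Default DNA contents for the *D. melanogaster* male karyotype are the
approximate chromosome sizes in Mb (X 42, Y 40, chr2 48, chr3 52,
chr4 4.3); `unit_contents=True` switches every chromatid to 1.0 for
closed-form checks.

## FISH scoring

Classification: (0,0) → none; (1,0)/(0,1) → red/green only; r≥1 and
g≥1 → both (presence-based, regardless of multiplicity); ≥2 of one
color with 0 of the other → unscored.  Cross-cyst aggregates use the
sample (n−1) s.d., appropriate for the 10–15 cysts a genotype
typically yields.  Cysts whose 0/RG is undefined are excluded from the
ratio aggregate and counted, never imputed.  Note one exact property
of the regular-sisters model: within a tetrad, `none` and `both`
nuclei arise in equal numbers, so at zero detection dropout every
cyst's 0/RG is exactly 1, not merely 1 on average.

## Image quantification

The chain mirrors the published ImageJ procedure as composable
operators:

1. maximum-intensity projection;
2. "reset histogram" implemented as min-max rescaling of intensities
   within the ROI (that is the operation's effect on the subsequent
   threshold);
3. local **Mean** auto-threshold: foreground where the rescaled pixel
   exceeds the mean over a circular radius-15 px neighborhood minus an
   offset C.  C is not specified in the source procedure; default 0.
   The neighborhood mean is computed by FFT convolution with a
   zero-padded border and the comparison uses a 10⁻⁹ guard so that
   flat background never becomes foreground through floating-point
   noise (a constant image yields zero objects);
4. watershed on the Euclidean distance transform.  Seeds are regional
   maxima after an h-maxima transform (h = 1 px) — the discrete
   distance transform of a round nucleus is a plateau-ridden cone, and
   raw local maxima over-seed it badly — followed by merging of seed
   centroids closer than a configurable minimum separation (default
   2 px).  h and the separation are exposed in `QuantConfig`;
5. particle filter: area 1–25 µm² (the size bound is read as area, the
   source program's convention) and circularity 4π·area/perimeter² in
   0.70–1.00, inclusive; discretization values >1 are clamped;
6. QC: an image missing more than 10% of its expected nuclei is
   flagged for discard (extra detections are not misses);
7. integrated intensity is summed on the *original* (unrescaled)
   pixels, so the statistic is invariant to the display normalization.

Pixel calibration defaults to 0.16 µm/px, typical for a 40×/1.4
objective on the cameras used for this kind of imaging; it is an
explicit config parameter, never silently assumed in outputs.  Manual
ROI drawing and manual deletion of cyst-cell nuclei are replaced by an
ROI mask and an exclusion mask input.

Trace normalization scales a dot-intensity time course so the mean of
its ten brightest frames is 100 a.u.; t = 0 is set at a caller-supplied
index (the last frame before nuclear envelope breakdown).  The output
is invariant to positive rescaling of the input.

## Motif scanning

Matches are exhaustive and may overlap; anchors ([E/D], R; [L/V/I/M],
P, E) must match literally, and an `X` in a sequence satisfies only the
"any residue" positions.  Coordinates are 1-based.  The non-cleavable
mutation sets both anchor residues of a cleavage hit to alanine and is
idempotent.  Conservation of a hit is computed per motif column as the
fraction of non-gap alignment rows carrying the reference residue,
after mapping the hit through the reference row's gaps;
`conserved_cleavage_hits` keeps hits whose columns are all at or above
a threshold (default 0.9), the criterion that singles out a functional
site inside a divergent linker.

## Synthetic data

The generators emulate the *statistical structure* of the real inputs,
not their optics or chemistry:

* FISH tables draw complete tetrads from a scenario (13 cysts × 64
  spermatids by default, the scale of the real experiments); signals
  are presence-based with optional chromatid-resolved mode and
  independent per-signal dropout (default 0).
* Cyst images render nuclei as uniform disks (radius 1.8 µm ≈ 10 µm²,
  inside the particle-filter band) on a jittered grid, with optional
  tangent pairs for the watershed, Gaussian blur, constant background
  and per-nucleus multiplicative lognormal intensity noise (σ = 0.05
  default; lognormal keeps intensities positive).  Each disk's pixel
  sum equals its content exactly, so zero-noise closure tests can
  demand exact recovery.  Not modeled: PSF shape, chromatic shift,
  uneven illumination, clustered or partially overlapping nuclei
  beyond tangent pairs — so passing tests certify the operators, not
  robustness to every real-microscopy artifact.
* Protein families have conserved terminal blocks (rejection-sampled to
  be motif-free), a linker diverged per position at a set rate, and the
  cleavage site written into every member at one position; without
  indels the family doubles as its own alignment.
* Intensity traces are plateau → linear decay to background (default
  decay 9 min, sampled at 45 s), with optional additive Gaussian noise.

Every generator is a pure function of (parameters, seed).

## Problem sizes and numerical choices

Exact enumerations used for the headline ratios involve ≤64 elementary
assignments and are instantaneous.  Statistical tests use 10⁵ Monte
Carlo meioses (4 s.e. bands), 10⁴ nuclei for pipeline closure, 200
cysts for the √2/4 limit (tolerance 0.01), and 10 synthetic cysts per
condition for the wild-type vs conjunction-null variability ordering —
sizes at which the checks are decisive yet the whole suite runs in
seconds.  Ties in watershed seed merging resolve toward the
lowest-index seed; degenerate inputs (empty ROI, zero dynamic range,
all-zero traces, zero cyst means) are either explicit errors or
logged-and-empty results as documented per operator.

## Known limitations

* The model ignores meiosis timing, spindle mechanics and chromosome
  bridging; those phenotypes are observational, not model outputs.
* FISH detection efficiency below 100% is available in the generator
  (`detection_dropout`) but not in the analytical predictions.
* The image operators assume round, well-separated or pairwise-tangent
  nuclei; heavily clumped cysts would need stronger shape priors.
* Scanning real conjunction-protein orthologs requires external
  sequence retrieval and is out of scope; the conservation machinery is
  exercised on generated families.
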