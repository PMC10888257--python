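# Methods

`beadmosaic` re-implements, at desk scale, the analysis stack of a
bead-emulsion amplification (BEA) digital-PCR assay for rare germline
variants: microbeads each clonally amplify one template molecule, are probed
with allele-specific fluorescent probes in two channels, imaged, stripped,
re-probed with the fluorophores swapped ("dye switch"), and re-imaged. Bead
images are turned into per-bead genotype calls, calls into Poisson-corrected
variant-allele frequencies (VAF), and VAFs into spatial (testis) and cohort
(sperm donor) mosaicism statistics.

## Partition model and VAF estimation

Each bead is a partition seeded by a Poisson number of single molecules.
With `m` mutant-called and `w` wild-type-called beads, the observed positive
fraction `p = m/(m+w)` underestimates the per-molecule mutant frequency
because multi-seeded beads collapse several molecules into one partition.
The corrected estimate is

```
lambda = -ln(1 - p)
```

exact under Poisson seeding, `lambda ≈ p` for `p ≲ 1e-3` (relative error
< 0.1%). We apply the formula to called bead counts directly. `m = 0` is
reported as `lambda = 0` with a non-zero upper confidence bound; a saturated
sample (`w = 0, m > 0`) is an error, never a capped value.

Confidence intervals are ours (the assay's original reports carry none): a
Clopper–Pearson interval on `p`, mapped through the (monotone) correction.
Coverage is therefore conservative (≥ 95% nominal; ≥ 90% asserted by a
Monte-Carlo test at VAF 1e-4).

The detection limit follows the same Poisson logic: a sample of `N` assayed
molecules at frequency `v` is positive with probability `1 − exp(−N·v)`;
at `v = 1e-5`, `N = 1e5` that is 63.2%, so "zero" measurements at such
frequencies are expected non-detections, not evidence of absence.

`n_molecules` defaults to 1e5 effective assayed single molecules. The wet
assay loads ~3e5 input genomes but assesses roughly 1e5 molecules after
losses; both are configuration fields, and the discrepancy is deliberately
surfaced rather than hidden.

## Image pipeline

* **Registration** — integer-pixel translation maximising the normalized
  cross-correlation of the two rounds' brightfield images. The FFT
  cross-correlation's circular ambiguity is resolved by re-scoring candidate
  shifts on the actual overlap. Pairs needing more than 500 px of correction
  are flagged and discarded, matching assay practice; no sub-pixel stage is
  attempted.
* **Segmentation** — à-trous (stationary B3-spline) wavelet background
  subtraction followed by thresholding at `threshold_k = 5` noise SD and
  4-connected labelling. The noise SD is estimated from the first-level
  detail coefficients via a robust MAD, rescaled by the exact white-noise
  gain of each detail filter — this keeps the estimate honest on densely
  covered fields where a global MAD is inflated by the beads themselves.
  A plain Otsu threshold is available as `method="otsu"`. Area bounds
  default to disks of 0.5× and 1.5× the configured bead radius.
* **Mask propagation** — the scan-1 label mask is translated by the
  registered shift and compared against the dye-switch round's own mask;
  beads overlapping by < 0.5 of their footprint are unmatched and dropped
  (edge beads, detachment, registration residue).
* Coordinates are 0-based `(row, col) = (y, x)`; TIFF origin top-left.

## Genotype calling

Intensities are log10-transformed and robustly standardized per
channel/round (median/MAD), which is monotone and invariant to per-channel
gain. Because empty beads always dominate (the assay targets ~10%
positives), the background sits at z = 0 by construction.

Per round, a 4-component full-covariance Gaussian mixture is fitted on the
(ch1, ch2) plane. All three parameter groups (weights, means, precisions)
are initialized from a per-channel threshold grid at `min_separation = 5`
robust z-units; unpopulated quadrants get nominal corner positions with
unit covariance. This matters at low VAF: without it, EM lets the component
meant for a handful of mutant beads drift onto the empty-bead blob and the
mutants are silently absorbed. Components map to code digits by the same
absolute rule (mean > 5 z-units above background ⇒ digit 1); intensities
far *below* background (edge artefacts) map low. The 5-z gate clears the
extreme tail of a pure-background blob (max of 1e4 standard normals ≈ 3.9)
while true clusters sit tens of z-units out. Beads with summed per-code
posterior below `conf_min = 0.95` are flagged; exact ties resolve toward
`00`. A degenerate fit falls back to the threshold grid (logged).

Codes combine as scan-1 digits then dye-switch digits, digit order
(ch1, ch2): `1001` ⇒ WT, `0110` ⇒ mutant, `0000` ⇒ empty, any round `11`
⇒ MULTI (both alleles on one bead, eliminated), anything else (including
low-confidence beads) ⇒ INCONSISTENT. MULTI and INCONSISTENT are excluded
from both numerator and denominator. Experiment QC fails runs with > 30%
positive beads (multi-seeding biases counts low) or with no WT/mutant
signal at all, and warns when the positive fraction strays more than 3×
from the 10% seeding target.

A 1-D per-channel variant of the cluster model is conceivable; we default
to the 2-D mixture and keep the threshold grid as the explicit alternative
(`method="threshold"`).

## Mosaicism statistics

* **Testis maps** — the dissection grid is 6 slices × 32 pieces (192
  addresses), pieces may be NA. Summaries (mean, median, IQR, max of
  per-piece `lambda`) use linear-interpolation (type-7) quantiles; printed
  third decimals of other quantile conventions are not chased.
  **MaxVAF/IQR** is the focal-expansion statistic: ≈ 1 under uniform
  spread, tens-to-hundreds when mutant spermatogonial clones expand
  locally. A zero IQR yields NA, not infinity — a perfectly uniform map is
  the null, not an infinite signal.
* **Age trend** — Spearman rank correlation (average-rank ties) between
  donor age and `lambda`, two-sided p from the t approximation, with an
  exact permutation mode used automatically for n ≤ 8. Zero-VAF donors are
  ranked like any other (their zeros are informative).
* **Variant comparison** — two-sided Mann–Whitney U with average-rank
  ties; the reported Z uses the tie-corrected variance and a 0.5 continuity
  correction; U is reported as the larger of the two statistics. An exact
  enumeration mode engages for combined n ≤ 14.
* **Positivity** — fraction of donors with ≥ 1 mutant molecule observed,
  reported as a rounded percentage with the raw counts retained.
* **Heat maps** — per-slice grids coloured on a banded quasi-log scale
  spanning 0 to > 1e-3, NA pieces grey.

## Synthetic data: what it emulates, what it does not

The generators replace per-sample raw data that exist only in the original
study's appendix. They are first-class, tested code with full ground truth.

* **Bead fields** — beads are uniform bright disks placed by rejection
  sampling with a minimum centre distance of `2r + 3` px (non-overlap plus
  a 2 px guard so adjacent beads stay separable); classes follow
  independent Poisson seeding of mutant and wild-type molecules at
  `seeding_rate = −ln(0.9)` (≈ 10% positive beads); the dye-switch round is
  the same field translated by an integer shift with channels swapped, plus
  fresh additive Gaussian noise. Defaults: 10,000 beads, 2048² px, radius
  4 px, gains 1000 over background 100, noise SD 20 (a 45-SD separation).
  Not modelled: optical PSF, illumination gradients, bead detachment,
  emulsion chemistry. A green image-pipeline test therefore certifies the
  algorithmic chain, not robustness to every microscopy artefact.
* **Testis maps** — log-normal background per piece (default median
  2.3e-5, sigma 1.0) with multiplicative focal clusters (single pieces by
  default) and binomial molecule sampling. No spatial spread model is
  claimed: the original data show focal pockets but no measured kernel.
* **Sperm cohorts** — ages uniform on 25–59; true VAF
  `exp(intercept + slope·age + N(0, dispersion))`; observed counts
  binomial. The model is invented plumbing calibrated once by large-sample
  Monte Carlo so the ACH-like defaults (slope 0.03/yr, median VAF 2.9e-5 at
  age 42, dispersion 0.7) give a *population* Spearman rho of 0.30 at 1e5
  molecules; a 10× lower intercept gives a TDII-like cohort (population
  rho 0.15, ~70% zero measurements). Single-cohort estimates at n = 56
  scatter widely (SD ≈ 0.13) — that is the point of the calibration tests.
* **Dilution series** — binomial draws at the 1:100 / 1:1000 / 1:10,000
  spike-in fractions, three replicates of 1e5 molecules.

All generators are bit-reproducible under a fixed seed; the end-to-end
runner derives every stage seed from one root via `SeedSequence` spawning.

## Numerical and degenerate-input choices

* `-log1p(-p)` rather than `log(1-p)` for small-`p` accuracy.
* Registration requires ≥ 16 px of overlap per axis to score a candidate
  shift; constant images are a hard error (correlation undefined).
* Normalization clips non-positive intensities to the column's smallest
  positive value before log10 (preserves gain invariance; affects only
  noise-floor beads) and errors on zero-MAD channels.
* GMM `reg_covar = 1e-4`; mixture fit failures fall back to the threshold
  grid rather than dying mid-pipeline.
* Empty bead tables, all-NA maps, constant cohorts, and saturated samples
  raise informative errors instead of propagating NaNs.

## Known limitations

* Integer-pixel registration only; sub-pixel shifts blur extracted means
  slightly (irrelevant at the 45-SD default separation).
* Beads overlapping the field edge in either round lose part of their
  footprint; they are usually dropped by mask matching, occasionally kept
  with diluted intensities and then typically fall out as INCONSISTENT.
* The two screened loci are treated as independent two-channel
  experiments; no four-probe multiplex deconvolution is attempted.
* MaxVAF/IQR is the only spatial statistic; no autocorrelation or formal
  cluster calling.
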