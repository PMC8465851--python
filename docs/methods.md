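# Methods

This note documents the statistical model and the design choices behind
`msimarker`, in the order the pipeline runs.

## Preprocessing

Every pixel spectrum is scaled so its total ion count (TIC) equals a
configurable target (default 1), which makes pixels comparable across and
within sections; all-zero spectra are rejected with the offending pixel
named. Peak picking then operates on the *mean* of all TIC-normalized
spectra of the dataset, not per pixel: this realizes alignment "across a
data set" and guarantees one common feature grid for every section.

The mean spectrum is smoothed with a Gaussian of sigma 0.75 axis bins
before maxima detection; per-pixel intensities are always extracted from
the unsmoothed spectra. (Vendor descriptions of this step are ambiguous —
"medium noise reduction and no smoothing (Sigma: 0.75)" — and we adopt the
reading that the sigma applies to detection only.) Local maxima whose
prominence exceeds 0.5 % of the smoothed maximum (a detection floor the
source pipeline does not document; it is exposed in `PreprocessConfig`)
become features. Each feature is an interval of full width 0.3 Da centered
on its apex; when two apexes lie closer than one interval width the higher
apex wins (ties: lower m/z), so intervals never overlap. A matrix entry is
the maximum normalized intensity of a pixel inside an interval ("maximal
interval" mode). No baseline subtraction, recalibration or deisotoping is
performed.

## Segmentation

Bisecting k-means: starting from one cluster, the leaf with the largest
within-cluster cost (sum of correlation distances of members to the leaf
centroid) is split into two until the requested number of leaves exists.
The split-selection criterion is our choice; the vendor tool does not
document its own. Rows are z-scored across features, after which squared
Euclidean distance equals `2·p·(1−ρ)` — a monotone transform of
correlation distance — so each bisection can run a plain seeded k-means
(k-means++ initialization, 10 restarts, best inertia kept) on the
standardized rows. Centroids are arithmetic means of standardized member
vectors. A zero-variance spectrum has an undefined correlation; its z-row
is the zero vector, which makes its assignment exactly the Euclidean
fallback, and it contributes zero cost. Assignments are invariant to
positive scaling of any spectrum, and total cost is non-increasing over
splits.

## Candidate discovery

For a comparison (group A vs group B within one wall layer), equally many
spectra are drawn per group without replacement (default cap 35,000 —
the scale used on full tissue sections; the cap truncates to the smaller
group). Equal pools are required because the AUC's sampling variability is
otherwise asymmetric between classes. Whether the original pipeline
subsampled spectra or individual m/z instances is not documented; we
subsample spectra (observations), since features are fixed by alignment.

Per feature:

* **AUC** — `P(a > b) + ½·P(a = b)` by the rank/Mann–Whitney identity.
  Orientation: the group named first is positive, so AUC > 0.5 means
  higher intensities in that group.
* **p-value** — two-sided Wilcoxon rank-sum; exact enumeration when both
  groups have ≤ 12 observations and the pooled values are tie-free,
  otherwise the normal approximation with tie and continuity corrections
  (scipy). An all-constant pooled sample returns p = 1.
* **peak correlation ratio** — the point-biserial (Pearson) correlation
  between intensity and the group-A indicator. The source pipeline never
  defines its "peak correlation ratio"; point-biserial is monotone with
  the AUC and reproducible, and we use it as a stand-in.

A feature is a candidate when AUC ≥ 0.6 or ≤ 0.4 (inclusive thresholds:
with two-decimal AUCs this is what reproduces the reference candidate
table, where rows at 0.40 must qualify), p < 0.001, and |r| > 0.5. No
multiple-testing correction is applied to the candidate gate (the
reference analysis reports raw p-values); a Benjamini–Hochberg column is
emitted for information only.

## Peptide matching and protein calls

Theoretical monoisotopic MH+ is the sum of residue masses plus water
(18.010565 Da) plus one proton (1.007276 Da), plus 15.994915 Da per
oxidized methionine (0–2 variable oxidations). The residue-mass table is
explicit in `msimarker.match` and cross-checked against pyteomics in the
test suite.

Each identification record is assigned to the imaging feature *closest* to
its MH+, accepted when |Δm| is strictly below the tolerance (default
1.0 Da; source texts state both 0.9 and 1 Da, and only the 1 Da reading
reproduces all 47 reference pairings — four of them exceed 0.9 Da). Within
a (feature, gene) group, duplicate sequences collapse to the best record
and candidates are ranked by MOWSE score (descending), then |Δm|, then
MH+; the rank is recorded as tie provenance. One feature may match several
genes (e.g. 976.43 → ACTA2 and PGAM2) and several sequences of one gene.
Identifications with MOWSE ≤ 13 are dropped at read time, mirroring the
search-engine acceptance rule. When ion images are available and a gene
has matched at least two features, a candidate whose image correlates with
the mean image of the gene's other features at |Pearson| ≤ 0.1 is dropped
(what the original macro correlated is unstated; this is our concrete
reading of "correlation coefficient > 0.1 or < 0.1" as |r| > 0.1).

A protein is called for a comparison when at least two distinct
(feature, sequence) pairs of its gene meet the AUC criterion (so two
sequences on a single m/z can validate a protein, as for CKM at 1508.678);
the direction follows the AUC side, and the call reports *all* matched
pairs of the gene, qualifying or not. Candidate tables that list only AUCs
for features that already passed the p gate may omit the p column, in
which case the AUC criterion alone is applied. Calls are invariant to
match order, and lowering the tolerance never adds matches.

The AAA-vs-EVAR reference counts (9 peptide values / 4 proteins) are not
exactly recoverable from two-decimal AUCs — several printed values round
to exactly 0.60 — so they are documented here but not asserted anywhere.

## Cohort statistics

Group summaries report arithmetic mean and n−1 sample SD, rounded half-up
to integers. Two-group comparisons use the exact rank-sum test, which
reproduces the reported diameter comparison (p = 0.0079 → 0.01); the
three-group age p-value is not reproduced because the original test is
unstated.

## Synthetic data

The generator emulates the study design: cohort groups TAA/AAA/EVAR with
five sections each by default, a 50 µm raster, an m/z axis spanning
600–3200 Da, and the media and adventitia as contiguous horizontal bands
of each section (mimicking annotated layers and making segmentation tests
spatially meaningful). Each panel peptide contributes a Gaussian peak
(SD 0.05 Da) at its theoretical MH+ plus per-pixel jitter
(SD 0.02 Da); its amplitude is
`base_intensity × effect(group, region) × LogNormal(0, σ)` with σ = 0.5 —
multiplicative log-normal effects keep intensities positive and give a
realistic dynamic range. Spectra additionally carry a slowly decaying
baseline (amplitude 2, decay constant 800 Da) and additive Gaussian noise
(SD 1), clipped at zero. No public intensity or noise figures exist for
the real spectra, so these levels are package choices, all exposed in
`SimulationConfig`. All randomness derives from a single seed via
per-section substreams, so outputs are bit-reproducible and sections are
independent.

The default panel plants a four-fold suppression of eight
contractile/ECM/energy-metabolism peptides in the EVAR media — the effect
direction the method is designed to detect — and includes two unaffected
negative controls. The generator does **not** simulate isotope envelopes,
matrix clusters, detector saturation, or FFPE chemistry artifacts; passing
tests therefore demonstrate statistical correctness of the pipeline under
a simplified peak model, not robustness to those instrument effects.

## Problem sizes used in tests

The test suite exercises the pipeline at desk scale: sections of 16×16 to
24×24 pixels (200 media pixels per group for the sensitivity checks, the
regime where a 4× effect is expected to be recovered at ≥ 90 %
sensitivity), 40,000 simulated null features for the type-I-error check of
the p < 0.001 gate, and 12-feature panels for the banded segmentation
checks (six peptides elevated per layer — far sparser than the hundreds of
aligned peptide values real sections provide, but sufficient for
correlation-distance clustering). Exact small-sample machinery (rank-sum
enumeration, pairwise AUC) is verified against brute-force oracles.

## Known limitations

* The imzML reader loads everything into memory; very large files should
  be tiled externally.
* The correlation-ratio and image-correlation definitions are stand-ins
  for undocumented vendor/in-house quantities; both are exposed as config.
* Peak shape, noise and baseline models are deliberately simple (see
  above).
* The segmentation tree does not re-merge leaves; like other bisecting
  schemes it is greedy and order-dependent by design.
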