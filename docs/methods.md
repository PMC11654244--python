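# Methods

This note records the models, defaults, and design choices behind
`degronscreen`, and what the synthetic-data generators do and do not
emulate.

## Growth screen

**Score.** For each strain, replicate colony sizes are averaged per
condition (arithmetic mean of sizes, *then* the ratio — not a mean of
ratios), and the relative growth is `mean(induced) / mean(uninduced)`.
Because induced and uninduced colonies occupy the same array position,
positional effects that multiply both conditions (edge colonies growing
larger, pinning gradients) cancel in the ratio; the simulator plants such an
edge boost precisely so tests can verify the cancellation. Scores are not
capped at 1 — faster growth under induction is reported as is.

**Presence.** A strain whose mean uninduced colony is not strictly above the
presence threshold (default 50 arbitrary units, the same convention used to
score colony survival after library construction) never formed a colony and
is *absent*, not essential: the ratio is NaN, and absence also guards the
division. The threshold applies to the uninduced condition only.

**Normalization.** Scores are divided by their plate/media group median
computed after outlier removal. The outlier rule is median ± 2 robust SDs,
with the robust SD taken as 1.4826·MAD; this is parameter-free, symmetric,
and with MAD = 0 degenerates gracefully (only values equal to the median
survive, so the factor is the median itself — a plate of unit ratios plus a
lethal zero normalizes by 1). The trim multiplier is configurable because
the exact outlier convention is a free choice; groups with fewer than three
scoreable strains are left unnormalized with a warning.

**Classification.** Strict inequalities against two thresholds: below 0.5
severe, below 0.1 stringent-severe (stringent ⊆ severe by construction).
An optional third "moderate" threshold exists but is off by default. Venn
partitioning of hits across media is exact set algebra; region sizes always
sum to the union cardinality, and per-media exclusive sets feed the GO-slim
ranking.

## Fluorescence screen

**Summary statistic.** Cells outside mean ± 2 SD — both moments computed on
the raw intensities — are removed in a single pass, then the geometric mean,
SD and count of the survivors are reported. Mixing an arithmetic trim with a
geometric summary is deliberate: the trim convention follows how screening
pipelines flag segmentation artifacts on the raw camera values, while the
geometric mean is the right location statistic for log-normal expression.
If trimming removes everything (possible only at aggressive trim
multipliers) the untrimmed summary is returned with a flag.

**Autofluorescence band.** Mean ± 2 sample SD (ddof = 1) of the control
strains' geometric means; a strain counts as fluorescent only when its
before-induction geometric mean exceeds the *brightest* control, which is
stricter than the band's upper edge and avoids calling marginal strains.

**Responsiveness.** The screen's "significant GFP reduction" is made
concrete as a one-sided two-sample Welch test on log intensities (unequal
variances; log scale because populations are multiplicative), adjusted
across the tested panel by Benjamini–Hochberg at α = 0.05, combined with an
effect floor: after/before geometric-mean ratio < 0.75. The floor exists
because at n ≈ 200 cells trivially small drops become significant; all
three knobs (α, floor, trim) are configuration. Death is called from a
collapse of the imaged cell count below 25% of the before count — the
quantitative proxy for the microscopy observation that some strains die
after 24 h of induction, making their fluorescence uninformative.

**Summaries.** Two library-level responsiveness percentages are emitted:
over surviving fluorescent strains, and counting induction-dead strains as
responders over all fluorescent strains. Which denominator a study quotes is
a convention, so both are reported.

## Kinetics

One-phase decay `y(t) = plateau + (y0 − plateau)·e^(−kt)` is fitted by
bounded least squares (scipy `curve_fit`, pooled replicates): y0 ∈ [0.8,
1.2] to absorb normalization noise rather than pinning the start at 1,
plateau ∈ [0, 1], k > 0. With this parameterization the half-distance
crossing between y0 and plateau occurs exactly at t50 = ln2/k, so the two
half-life conventions coincide and both are exposed. Immunoblot series are
first divided by their Act1 loading band, then each replicate by its own
t = 0 value, matching the microscopy normalization.

The 95% CI on t50 propagates the covariance of k through the delta method
(se(t50) = ln2/k² · se(k)) with a t-quantile at N − 3 degrees of freedom;
when the covariance is unusable and at least three replicates exist, a
replicate bootstrap (1,000 draws, percentile interval) substitutes, and the
method used is recorded on the fit. Series whose fitted amplitude
y0 − plateau falls below 0.1 are flagged non-degrading with an infinite
half-life sentinel instead of reporting a meaningless rate. In simulation at
the screen's conditions (t50 = 45 min, plateau 0.1, 5% multiplicative noise,
6 timepoints, 3 replicates) the delta CI covers the truth ~94–96% of the
time and the median relative error is ~8%.

Modality concordance is the microscopy/immunoblot t50 ratio plus a flag for
overlap of the two CIs; it is undefined (error) when either fit is flagged.

## Enrichment

Term recovery is a plain percentage, `100·|hits ∩ term genes|/term size`,
reported to one decimal; no hypergeometric test is attached by default
because the procedure reports counts, not enrichment statistics. Exclusive
ranking sorts terms by the number of exclusive hits annotated; ties break
toward the term with the larger exclusive recovery (exclusive count divided
by term size — the full-hit-list recovery is not available at ranking time)
and then lexically, making the ordering total and input-order invariant.
Library-presence and responsive-in-library counts are carried as metadata
only; they do not enter the percentage.

## Grouping

Compartment collapsing is a fixed, idempotent dictionary (early/late Golgi →
Golgi; nucleolus → nucleus; actin, endosome, ER-to-Golgi, microtubule,
spindle pole → punctate composite); unknown categories pass through with a
warning rather than failing, since localization atlases evolve. Rank
binning assigns equal-size bins in rank order with any remainder going to
the lowest-index (most abundant) bins, so bin sizes differ by at most one
and 650 genes split into quintiles of exactly 130. MitoTracker ranking is
dense and descending, ties sharing the better rank. Manually-curated
phenotype labels (mitochondrial morphology classes, cell-cycle arrest
classes) are accepted as optional metadata columns and never computed — they
require visual examination by design.

## Montage

Crops are half-open 65×65 windows centered on floored centroid coordinates
(0-based, origin top-left; odd box ⇒ the center pixel is the centroid
pixel), zero-padded at frame edges. Tiling is row-major in input order onto
a fixed canvas (20×20 tiles ⇒ 1,300×1,300) with intensities copied verbatim,
so tile extraction is the exact inverse and total intensity is conserved —
this is what keeps across-cell expression noise measurable on the montage.
Contrast adjustment is a pure function: a linear stretch clipping at the
(1 − f) upper quantile with the lower bound anchored at the image minimum
(top-only saturation, the natural convention for fluorescence; a split
top/bottom mode is available), so the saturated fraction is within one
quantization step of f = 0.35% on images with a dense intensity range. The
quantile is per image; cross-condition normalization is a separate concern
recorded in the contrast metadata. Brightfield montages are min–max scaled
to 8 bits with half-up rounding.

## Synthetic data

The generators reproduce the *statistical structure* the analysis relies
on, not the physics: colony sizes are unit-mean multiplicative log-normal
noise (positive, right-skewed, CV-parameterized) around a base size, lethal
strains draw induced sizes around `effect_size` × the uninduced mean, and
one multiplicative edge factor hits the outermost ring of both plates.
Default screen conditions — 1,536-format layout, 10% lethal fraction, 0.05
effect size, 10% colony CV — are the regime the recovery tests run in; the
colony-noise magnitude is a testing assumption, not a measured value.
Per-cell populations are additive near-Gaussian autofluorescence
(mean 100, SD 10 camera units) plus log-normal signal (geometric mean 1,000,
log-SD 0.25), with induction multiplying the signal component only.
Time courses multiply the clean decay curve by unit-mean log-normal noise
per observation. Cell images are uniform disks on a zero background.

None of this emulates optics (no PSF, no illumination gradients, no
photobleaching), cell morphology, segmentation error, plate-to-plate batch
structure, or the heavy-tailed contamination of real colony grids. Passing
recovery tests therefore demonstrates that the *computations* are correct
and well-calibrated under their stated assumptions — not that the pipeline
is robust to every artifact of real acquisitions.

Problem sizes used by the test suite and the acceptance script (1,000-strain
plate pairs, 200-strain fluorescence panels of 200 cells, 200 simulated
decay courses) were chosen as the smallest sizes at which the binomial noise
on the measured rates is well inside the tested bounds.

## Determinism

Every generator takes an explicit seed and is bit-identical given one; the
pipeline derives all stage seeds from the single run-config seed, and no
stage reads a clock or an unseeded generator. Run outputs carry a
configuration hash (output paths excluded) so mixing artifacts from
different configurations is detectable; reruns of one configuration are
byte-identical.
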