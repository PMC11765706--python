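# Methods

## Scope and data model

The package operates on three kinds of data: (1) per-fraction
monosaccharide yields from a three-step sequential extraction of cell-wall
material — ammonium-oxalate chelation (AO, pectin-enriched), 4 M KOH
(hemicellulose-enriched), and TFA hydrolysis of the cellulose-enriched
residue (RESIDUE) — expressed in mg per g of cell-wall dry mass;
(2) RGB micrographs of immunolabelled sections with a binary wall mask;
(3) gene × sample matrices of total gene reads (TGR) with an externally
computed adjusted p-value per contrast.  Chromatography, read mapping and
differential-dispersion modelling are upstream of this package and out of
scope; padj in particular is always consumed, never computed.

## Stoichiometric attribution

Whole-wall totals are the sugar-wise sums over the three fractions
(`merge_fraction_sums`); the attribution then runs in a fixed order
because later steps are defined on residual amounts.

**Xyloglucan.**  The XXFG unit contributes Glc:Xyl:Gal:Fuc = 4:3:1:1.
An anchor unit *u* is chosen and each sugar's consumption is *u*·coef.
Two anchor policies exist: `fucose` (default; *u* = Fuc/1, reduced to the
limiting sugar's mass/coef with warning `XYG_LIMITED_BY_<sugar>` when
fucose over-implies) and `limiting` (*u* = min over the four sugars of
mass/coef, the conservative choice).  Fucose is the default anchor because
among the modelled polymers fucose occurs only in xyloglucan's F side
chain, making it the most specific tracer.  Ties in the argmin break in
the fixed order Glc, Xyl, Gal, Fuc.

**Pectins.**  Backbone GalA = Rha × ratio (default 1.0, the alternating
Rha/GalA backbone), capped at measured GalA with warning
`RGI_GALA_CLIPPED`; HG is the GalA remainder; RG-I backbone mass is
Rha + backbone GalA.  Non-xyloglucan Ara and Gal are split between RG-I
side chains and a free arabinogalactan pool by the fractions `ara_to_rgI`
and `gal_to_rgI`.  These default to 1.0 (all side-chain) but are
deliberately exposed: studies of this design typically take
tissue-specific ratios from prior literature that are not part of the
data, so the split is a declared modelling input, not an estimate.

**Mannan, xylan, cellulose.**  Mannan is all mannose; xylan is the xylose
left after the XXFG draw.  Cellulose is computed strictly by difference
from the 1000 mg/g basis, never from measured glucose: glucose remaining
after the XXFG draw is reported as `unattributed` with warning `FREE_GLC`
(it may be callose, starch contamination, or xyloglucan backbone beyond
the fucosylated unit — the calculus cannot tell).  GlcA, if supplied, is
likewise unattributed.

**Closure and clipping.**  The ten output quantities always sum to the
basis to 1e-9 relative, enforced at construction.  Negative intermediates
are impossible by the min/cap rules; every cap emits a warning code so no
mass is ever silently truncated.  Input tables whose total sugar mass
exceeds the basis are rejected at validation, which is why the
`CLOSURE_EXCEEDED` branch of `cellulose_by_difference` can only fire when
that function is used standalone.

**Mass vs molar.**  Ratios are applied on the mg/g scale by default, since
the calculus is defined as a sum of monosaccharide masses.  An optional
molar mode divides by anhydro-residue masses (Rha/Fuc 146.14, Ara/Xyl
132.12, hexoses 162.14, uronic acids 176.12 g/mol) before attribution and
converts each class back to mass afterwards, preserving closure.  The two
modes answer slightly different questions (mass bookkeeping vs residue
stoichiometry); the default keeps the reported unit chain honest.

## Forward simulator

`simulate_fraction_set` inverts the calculus: each declared class emits
its constituent sugars (XXFG coefficients for xyloglucan, Rha+GalA per the
backbone ratio for RG-I backbone, Ara:Gal at a configurable 1:1 for the
arabinogalactan pool), the emission is distributed over AO/KOH/RESIDUE by
a per-class release matrix (rows sum to 1; cellulose releases nothing —
it is TFA-resistant and only ever quantified by difference), and replicate
noise is applied.  Default noise is multiplicative lognormal with unit
mean — yields are positive and the coefficient of variation is stable
across sugar abundances, which is how replicate scatter in this kind of
assay behaves; additive Gaussian is available.  The default release matrix
(pectins mostly chelator-extractable, cross-linking glycans mostly
alkali-extractable, a 10–25% residual tail) is a plausible extraction
pattern, not a fit to any measured partition; whole-wall totals are
invariant to it, so the deconvolution is unaffected by its choice.

With noise off, `deconvolve_sample(simulate_fraction_set(θ, cfg), cfg)`
recovers θ exactly provided cfg's Ara/Gal splits match the composition's
side-chain/pool partition; `config_for_composition` derives that matching
config.  This identity holds for any composition without free glucose —
the model family the calculus can represent.

Wall images are rings of declared thickness with the signal on the green
channel, clipped Gaussian noise, decoy gradients on red/blue, and
intensities on the 0–254 quantification scale.  Expression matrices are
lognormal-Poisson (negative-binomial-like) counts around a baseline of
200 TGR with a default biological CV of 0.3 — typical replicate
variability for bulk RNA-seq.  Planted fold changes shift group means;
planted correlated blocks share their biological variation (one latent per
sample per block, mixed at weight √r), so the target r is expressed on the
count scale where Pearson correlation is later measured, rather than on a
hidden log scale.  Truth padj for planted genes is 1e-4, and 1.0
elsewhere.  What the simulator does **not** emulate: chromatographic error
structure, library-size gradients, batch effects, zero inflation, or
spatial texture in micrographs — so passing tests demonstrate the
correctness of the arithmetic and decision rules under controlled
conditions, not robustness to every artefact of real data.

## Statistics

Group summaries are mean ± sample SD (n−1); a single replicate reports
SD 0 with warning `N1`.  The comparison test is the classical
pooled-variance Student's t (two-sided), with Welch behind a flag; zero
pooled variance with equal means is defined as t=0, p=1.  Significance is
flagged on two mutually exclusive tiers, `*` for p < 0.05 and `**` for
0.05 ≤ p < 0.1, with boundaries closed on the left of each interval.  The
second tier is reported as a weaker-evidence flag, not as significance at
a corrected level; no multiple-testing correction is applied to
composition comparisons, and this is a deliberate, visible property of
the method.

## Fluorescence quantification

Only the green channel is measured, clamped to [0, 254]; grayscale input
is rejected rather than guessed at.  Fragments are 4×4 px, fully inside
the mask, non-overlapping, at least 30 per parenchyma image and 50 per
collenchyma image (configurable upward only).  Placement is uniform
random over the valid anchor set with a seeded generator — random
placement is auditable and reproducible where manual region selection is
not — with a deterministic row-major grid mode as an alternative.  The
greedy non-overlap draw may terminate below the theoretical packing bound
on very tight masks; the error then reports the achieved count.  Images
are compared on per-fragment means (not pooled pixels) with the pooled
t-test at p < 0.05.

## Coexpression rule set

Normalization is the median-of-ratios scheme: reference = per-gene
geometric mean over samples (genes containing zeros are excluded from the
reference), size factor = per-sample median of value/reference, factors
rescaled to geometric mean 1 so that normalization is exactly idempotent.
A literal variant that only rescales each gene by its own geometric mean
is shipped (`method="gene_gm"`) for sensitivity analysis, because the
phrase "geometric mean for each gene" is genuinely ambiguous; the
median-of-ratios reading is the default since it is the scheme the
surrounding differential-expression tooling defines.

Thresholds are pure functions with inclusive boundaries tested explicitly:
expressed ⇔ normalized TGR ≥ 16 in ≥ 1 sample; DEG ⇔ expressed in the
contrast ∧ fold ≥ 2 (larger group mean over smaller, direction recorded)
∧ padj ≤ 0.01.  A zero group mean errors unless a pseudocount is supplied
(default 0; 1 behind a flag, with a warning when applied).

Clustering standardizes gene rows to zero mean and unit norm, making
squared Euclidean distance equal 2(1 − r); ordinary k-means (best of 10
seeded restarts) then minimizes within-cluster correlation distance
exactly.  Constant rows are excluded with a warning.

Networks use pairwise Pearson r with two-sided p-values from the exact
t transform at n−2 df, masked at α = 0.01 (at n = 8 samples the implied
critical |r| is ≈ 0.834).  Hub ranking raises |r| to a soft-threshold
power (default β = 5) and sums over significant partners; this
connectivity score is an explicit stand-in for the display rule of
interactive network tools, which do not document their ranking.  Ties
break lexicographically by gene id.

## Problem sizes and numerical choices

The shipped checks use 100 random compositions for the round-trip
identity, 1000 random inputs for closure, 1000 pairs for the t-test
oracle, 1000 null datasets of 12 genes × 8 samples for network type-I
error, 50 seeds × 10 planted genes for DEG recall, three 20-gene blocks
for cluster recovery, and 100 seeds of 200×200 px images for fluorescence
calibration — sizes chosen so each property is measured with comfortable
Monte-Carlo margin while the whole suite runs in seconds.  Floating-point
closure is asserted at 1e-9 relative; exact-arithmetic examples at 1e-12.
Seeds are threaded explicitly through every generator; no global state.

## Known limitations

The calculus cannot distinguish non-fucosylated xyloglucan (XXXG-type)
from other glucose sources, so walls of low fucosylation will
under-report xyloglucan into `unattributed`; the Ara/Gal split is an
input, not an inference; cellulose-by-difference absorbs every upstream
bias with opposite sign; the two-tier flagging makes no familywise
guarantee; and the fragment sampler assumes the mask is trustworthy —
no segmentation is attempted.
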