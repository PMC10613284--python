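# Methods

This note documents the models, estimators and numerical choices behind
`hemeascn`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real sequencing data.

## Data model and coordinate conventions

All positions are 1-based inclusive internally (the VCF/MAF convention);
BED is converted on read. Chromosomes are 1–22, X, Y; mitochondrial and
alternate contigs are rejected because the panel is nuclear. X/Y loci are
carried through I/O but excluded from purity/ploidy fitting and arm calls
by default (`include_sex_chroms` re-enables them); mixing sex-chromosome
dosage into the fit would distort ploidy for male samples.

A case is a `SnpMatrix` — per-locus ref/alt read counts for one tumor,
one matched (host baseline) normal, optional donor normals, and a pool of
unmatched normals — plus a table of candidate variants carrying
per-sample genotyping evidence.

## Coverage normalization and reference selection

Nail and saliva normals are prepared with different chemistry than marrow
or FFPE tumor tissue, so tumor/matched-normal coverage ratios are noisy.
The tumor is therefore normalized against a single unmatched normal
chosen from the pool: for each candidate we compute
`logR_i = log2((t_i+1)/(n_i+1))`, subtract a lowess trend of logR on GC
(span 0.3, the FACETS-style correction), median-center exactly, and keep
the candidate with the lowest sum of squared logR over autosomes. Ties
break to the earliest pool sample. The +1 pseudocount keeps zero-depth
loci finite. Insert-size criteria used when assembling a real pool are
not modeled; the pool is taken as given.

## Allelic imbalance

At SNPs heterozygous in the matched normal — depth ≥ 20 and alt fraction
within the inclusive band [0.25, 0.75]; the band is stated by the assay,
the inclusivity and depth floor are this package's choices — the log odds
ratio of alt:ref counts, tumor versus normal, is computed with
Haldane–Anscombe 0.5 pseudocounts, together with its asymptotic variance
`(1/(ta+.5)+1/(tr+.5)+1/(na+.5)+1/(nr+.5))/ln(2)²`. The sign of logOR is
arbitrary per locus (phase is unknown), so all downstream use is through
logOR². For post-transplant chimeras the het mask is the intersection of
host and all donor het masks: at such sites every non-tumor cell
population is heterozygous, so donor hematopoiesis enters the model
exactly like normal-cell contamination and the fitted "purity" remains
the tumor-cell fraction. The chimera-equivalence test verifies this
identity on simulated cases.

## Segmentation

A bivariate CUSUM-style recursive binary segmentation runs per
chromosome. At each candidate split the statistic `T = z_logR² + z_logOR²`
combines scaled mean differences of the logR track and of the
noise-corrected squared logOR track (`logOR² − var`, defined at het loci);
a split is accepted iff max T > cval, and accepted splits are recursed
into, which makes boundaries at a high cval a subset of those at a lower
cval by construction. Defaults follow the assay's two-pass scheme: a
coarse pass at cval 150 anchors the diploid logR level, a sensitive pass
at cval 75 defines the final segments. cval is a χ²-scale threshold on T;
its published values are adopted as-is and behave relationally (higher =
fewer segments).

Noise scales are estimated *locally* within each scanned stretch from
median absolute first differences (1.4826·MAD/√2). This matters: the
squared-logOR track is strongly heteroscedastic between balanced and
imbalanced regions, and a global scale produces spurious splits inside
imbalanced segments. Each flank of a candidate split must hold at least
`min_seg_marks` (10) markers and 5 het SNPs for the logOR term.

The diploid logR level (dipLogR) is the marker-weighted mean of the
heaviest cluster of allelically balanced segments (noise-corrected mean
logOR² ≤ 0.05, ≥ 10 het SNPs), clustered on mean logR by single linkage
with a 0.1 gap. With no balanced segment the weighted median of all
segments is used and a warning emitted. The balance threshold and gap are
set for panel-scale marker densities.

## Purity, ploidy and integer copy states

For segment total copy c and allele copies (m_major, m_minor) at purity ρ:

    expected_logr(c, ρ, ψ)  = log2((2(1−ρ) + ρc) / (2(1−ρ) + ρψ))
    expected_logor(m₁, m₂, ρ) = log2(((1−ρ) + ρm₁) / ((1−ρ) + ρm₂))

Observed logR is re-anchored at dipLogR, which fixes the reference level
to diploid, so residuals use the ψ-free difference
`expected_logr(c,ρ,ψ) − expected_logr(2,ρ,ψ)`; ploidy ψ is then the
marker-weighted mean tcn, and its fixed-point iteration converges in one
step. Divergent logOR expectations (ρ→1, m_minor 0) are capped at 10.

Purity is grid-searched over [0.05, 0.95] in steps of 0.01. Per segment
and candidate ρ, the integer state (tcn ≤ 10, lcn ≤ tcn/2) minimizes a
noise-standardized loss with (a) an allelic term on the logOR² scale —
the noise-corrected segment mean of logOR² is an unbiased estimate of the
true squared logOR, avoiding the positive bias a folded |logOR| estimate
has on balanced segments — with a delta-method variance
`(4·e²s² + 2s⁴)/n_het`, and (b) a coverage term standardized by the
measured per-locus logR standard deviation over `num_mark`. Both terms
carry a small systematic floor (tau 0.01) so very large segments cannot
claim unbounded precision, and the logR term keeps a 0.25 relative
down-weight. Standardization is what separates a genuine low-purity
solution from a high-copy state mimicking weak allelic imbalance: the
mimic always pays a many-sigma penalty on the coverage term. An earlier
unstandardized form of this loss was tested and is identifiably worse —
at tumor fractions near 20% the mimicking solutions win on a substantial
minority of random seeds.

Segments with fewer than 10 het SNPs get tcn from logR inversion alone
and a missing (never imputed) lcn. A genome whose informative segments
are all balanced with |logR − dipLogR| ≤ 0.1 is declared copy-number
quiet: purity is unidentifiable there and reported as NaN with
`quiet`/`low_confidence` flags, and all states set to (2, 1).

**Sensitivity floor.** The assay's validated detection floor is a 20%
tumor fraction. Fits with estimated purity below the floor are flagged
`below_sensitivity` and emit no gene- or arm-level calls. The comparison
uses a margin of two grid steps (flag iff ρ̂ < 0.18): the floor means
fractions *at or above* 20% are detectable, and with an unbiased
estimator a hard cut at 0.20 would suppress about half of the samples
sitting exactly at the floor through estimation noise alone.

**WGD and calls.** Whole-genome doubling is major copy ≥ 2 over more than
half the covered autosomal length (a common clinical convention; the
assay uses WGD in its thresholds without publishing a determination
rule). CN-LOH is lcn = 0 at tcn 2, or tcn 4 under WGD. Gene-level:
AMP at tcn ≥ 5 (no WGD) or > 6 (WGD) from the maximal overlapping
segment; HOMDEL at tcn 0; HETLOSS (tcn 1) only when a somatic SNV/indel
co-occurs in the gene; CN-LOH annotated per gene. Arm-level gains at
tcn ≥ 3 (no WGD) or > 5 (WGD) and losses at tcn < 2, generalized
symmetrically to tcn < 4 under WGD (the published thresholds cover gains
only); a state is called when it covers ≥ 50% of the arm's length.

## Variant filtering

Thresholds (all configurable, defaults are the assay's published values):
tumor VAF ≥ 5× unmatched-normal VAF, depth ≥ 20, alt ≥ 5, VAF ≥ 1%,
panel-of-normals fraction strictly < 20%; hotspot tier alt ≥ 8 and
VAF ≥ 2%; non-hotspot tier alt ≥ 10, VAF ≥ 5% and a matched-normal
check. The published phrasing of that last rule ("VAF in the matched
normal and tumor ≤ 35%") is ambiguous; the default reading is
normal:tumor VAF ratio ≤ 0.35 — the literal both-≤-35% reading would
reject legitimate high-VAF somatic events such as LOH-amplified drivers —
with the literal interpretation available behind
`FilterConfig.literal_matched_rule`. VAF comparisons run in exact
rational arithmetic (`Fraction(alt, depth)` against decimal thresholds),
so printed boundary values are deterministic.

Post-transplant mode adds provenance classification: BELOW_FLOOR under
tumor VAF 0.02; SOMATIC when undetected (alt < 2 *and* VAF < 1% — the
assay gives no numeric definition of "not detected") in host and every
donor; otherwise HOST_GERMLINE / DONOR_GERMLINE for a normal carrying the
variant at VAF ≥ 0.25 (the het lower bound reused; host takes precedence
when both carry it), else AMBIGUOUS. Raising the floor can only move
SOMATIC verdicts to BELOW_FLOOR, never to germline. Unmatched mode skips
the matched-normal rule and annotates population-database triage
(likely-germline iff any population AF > 0.01; missing AF retains the
variant); triage never runs in matched mode.

Contamination QC flags variants with matched-normal VAF > 2% and keeps
them somatic when tumor VAF ≥ 5× normal VAF — deliberately the same
ratio as the cascade's unmatched rule so matched and unmatched logic
agree.

## TMB and signatures

TMB = (synonymous + nonsynonymous SNVs and indels) / 1.0837 Mb. The
cohort TMB-high cutoff is median + 2·IQR with linear-interpolation
(type-7) quantiles — the quantile convention is not published, so it is
configurable — and classification is strictly greater-than; at least 4
samples are required. SBS96 spectra use the COSMIC channel order and
pyrimidine-strand convention (purine-reference substitutions
reverse-complemented). Refitting solves nonnegative least squares
`min‖v − Pw‖₂, w ≥ 0` against a column-normalized catalog, prunes
signatures contributing < 5% and re-solves once — a lightweight
approximation of the published practice of restricting each tumor to
signatures found de novo in its tumor type, which an `allow` list
reproduces exactly when such a restriction is known. De novo extraction
is out of scope.

## Simulator

The generator emulates the panel's data model with full ground truth:
SNP allele frequencies Beta(2, 2); host/donor/pool genotypes drawn
independently under Hardy–Weinberg; per-target capture efficiency as a
shared lognormal factor (log2 sd 0.4) multiplying every sample's expected
depth — shared because capture bias is a property of the probe, which is
why it cancels in coverage ratios — plus per-sample negative-binomial
noise (size 50, CV ≈ 0.15) and a sample-specific GC response (default
log2 amplitude 0.25 across the GC span) removed downstream by the lowess
correction; read counts binomial given depth and the expected allele
fraction implied by (ρ, δ, tcn, lcn) and the genotypes. SNPs are not
placed on acrocentric p-arms (13, 14, 15, 21, 22), where real panels have
no unique target sequence. Defaults: 6000 SNPs genome-wide, mean depth
500. Somatic variants are injected at non-SNP loci so provenance truth is
unambiguous; optional germline "tracer" variants are emitted from real
SNP loci to audit provenance calls. Dilution series scale purity by each
fraction with seeds derived as base + index.

Not modeled: read-level artifacts (FFPE damage, strand bias, mapping
error), allele-level overdispersion beyond binomial, subclonal copy
number, and the insert-size structure of real normal pools. Passing
recovery tests on these simulations therefore demonstrates correctness
of the estimators under the stated generative model — unbiasedness,
threshold behavior, chimera algebra, detection limits driven by counting
noise — not robustness to artifacts the model omits.

## Problem sizes in the test and acceptance runs

Unit and property tests run cases of 500–8000 SNPs. The recovery study
uses 20 tumors (purity 0.3–0.9, depth 400, 4–8 aberrant segments, 6000
SNPs); the dilution study uses 20 seeds × 5 fractions at depth 500 with
6000 SNPs; the signature study uses 50 spectra of 500 mutations from a
6-signature synthetic catalog (labelled synthetic; no COSMIC data is
bundled). These sizes were chosen to match the assay's validation designs
at panel scale.

## Known limitations

- Subclonal (fractional) copy number is explicitly unsupported; diluting
  a clonal event is not the same as fitting a genuinely subclonal one.
- The purity grid's lower bound (0.05) plus the quiet-genome rule means
  near-zero-purity samples are reported as quiet rather than fitted.
- Gene-level calls take the extremal overlapping segment; genes spanning
  a breakpoint inherit the more extreme state rather than a split call.
- The segmentation statistic is calibrated relationally against cval
  (monotone sensitivity, hierarchical boundaries), not against the exact
  FACETS T² distribution.
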