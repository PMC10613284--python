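# hemeascn

Allele-specific copy number, somatic variant filtering, tumor mutation
burden and mutational-signature refitting for paired tumor–normal targeted
sequencing of hematologic malignancies.

Blood cancers break the assumptions solid-tumor pipelines rely on: blood
itself is the tumor, so the matched "normal" must come from nails or
saliva (which bring library-chemistry biases and can carry contaminating
tumor DNA), and patients relapsing after allogeneic stem-cell transplant
are genomic chimeras of host and donor. `hemeascn` implements the
computational core of a clinical panel built for this setting:

- **Allele-specific copy number.** Tumor coverage is normalized against
  the best of a pool of unmatched normals (lowest sum-squared GC-corrected
  logR), while allelic imbalance comes from the log odds ratio of alt:ref
  counts, tumor versus the patient-matched normal, at SNPs heterozygous in
  that normal (alt fraction in [0.25, 0.75]). In post-transplant chimeras
  the logOR is restricted to SNPs heterozygous in *both* host and every
  donor, which makes donor hematopoiesis behave as normal-cell dilution.
  A two-pass segmentation (coarse cval 150 to anchor the diploid logR
  level, sensitive cval 75 for focal events) feeds a grid-search fit of
  tumor purity ρ and integer states (tcn, lcn) under the model
  `logR = log2((2(1−ρ)+ρc)/(2(1−ρ)+ρψ))`,
  `logOR = log2(((1−ρ)+ρ·m_major)/((1−ρ)+ρ·m_minor))`,
  detecting copy-neutral LOH (lcn = 0 at neutral total copy) and
  whole-genome doubling, with gene-level (AMP tcn ≥ 5, or > 6 with WGD;
  HOMDEL; HETLOSS only with a co-occurring mutation) and arm-level calls
  (gain tcn ≥ 3 / > 5 with WGD, covering ≥ 50% of the arm). Fits below
  the validated 20% tumor-fraction sensitivity floor emit no calls.
- **Somatic filter cascade.** Every candidate needs tumor VAF ≥ 5× the
  unmatched-normal VAF, ≥ 20 reads, ≥ 5 alt reads, VAF ≥ 1%, and presence
  in < 20% of the panel of normals; hotspots then need ≥ 8 alt reads and
  VAF ≥ 2%, non-hotspots ≥ 10 alt reads, VAF ≥ 5% and a matched-normal
  germline-ratio check. Post-transplant calls are additionally genotyped
  in host and donor(s) (somatic = tumor VAF ≥ 0.02 and undetected in every
  normal). Tumor-in-normal contamination is flagged at normal VAF > 2%
  and rescued when the tumor:normal VAF ratio is ≥ 5.
- **TMB and signatures.** TMB counts coding SNVs and indels over the
  1.0837 Mb panel footprint; the cohort TMB-high cutoff is
  median + 2·IQR with strict-greater classification. High-TMB spectra are
  decomposed on the SBS96 channels and refit against a signature catalog
  by nonnegative least squares with 5% pruning.
- **Simulator.** Every stage is testable without clinical data: HWE
  genotypes for host and donor individuals, shared per-target capture
  efficiency plus negative-binomial depth with GC bias, segmental integer
  copy states including CN-LOH, donor chimerism, injected somatic
  variants, contaminated normals, and serial-dilution series — all with
  full ground truth and byte-identical reproducibility per seed.

## Worked example

```sh
python examples/copy_number_fit.py
```

simulates a 60%-pure marrow sample with a 13q deletion and 9p
copy-neutral LOH and prints:

```
reference normal : UNMATCHED1
purity           : 0.60   (truth 0.6)
ploidy           : 1.97
dipLogR          : +0.012
WGD              : False

aberrant segments (chrom:start-end  tcn/lcn  CN-LOH):
  9:0-41 Mb   2/0   cnloh=True
  13:18-115 Mb   1/0   cnloh=False

arm-level calls:
  9p CNLOH (84% of arm)
  13q LOSS (100% of arm)
```

The fitted purity is the tumor-cell fraction; `tcn/lcn` are total and
minor integer copies per segment, so `1/0` is a one-copy loss and `2/0`
is copy-neutral LOH — normal total dosage but only one parental allele,
invisible to coverage alone. The other examples cover post-transplant
provenance (`posttransplant_provenance.py`), the filter cascade with its
per-rule reason trail (`filter_cascade.py`), and TMB/signature refitting
(`tmb_and_signatures.py`).

The same workflow is scriptable from a shell:

```sh
heme-ascn simulate --seed 5 --out case/
heme-ascn run-case --case-dir case/          # SEG + annotated MAF + JSON
heme-ascn filter --variants v.maf --roles roles.tsv --mode matched --out out.maf
```

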