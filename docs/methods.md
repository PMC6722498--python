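# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions.

## Metabolic ratio

The metabolic ratio of a plasma sample is the (Z)-endoxifen concentration
divided by the sum of the concentrations of the remaining 14 measured
compounds (tamoxifen, NDM-Tam, isomeric hydroxy- and glucuronide
metabolites). All concentrations are in ng/mL; the ratio is
dimensionless. The classification cutoff defaults to MR = 0.0146, the
value mapped by simple linear regression to the 6 ng/mL (Z)-endoxifen
efficacy threshold. Conventions:

- A sample exactly at the cutoff belongs to the MR ≥ cutoff (not-below)
  group, matching how the comparison groups are defined.
- Missing analytes are errors, never imputed as zero — a silently zeroed
  denominator term would bias MR upward.
- Cutoff calibration regresses MR on concentration and evaluates the
  fitted line at the target concentration. The direction is genuinely
  ambiguous (only "simple linear regression" is specified); the inverse
  regression is available via `invert=True` and agrees exactly on
  noiseless proportional data.

## CYP2D6 phenotype

Star alleles map to activity classes through a YAML-configurable table
(default: PM = \*3,\*4,\*5,\*6,\*7; IM = \*9,\*10,\*17,\*41; NM = \*1,\*2;
UM = \*1XN,\*2XN). A diplotype's group is the order-normalised pair of
classes; the binary modeling variable is *impaired* = carries at least
one IM or PM allele, so NM/NM and NM/UM are normal. Combinations outside
the seven in-cohort groups (UM/UM, UM/IM, UM/PM) are classified by the
same at-least-one-variant-allele rule and flagged `extrapolated`, since
their grouping is a convention rather than an observation. No activity
score arithmetic is performed; scoring systems vary across studies and
the binary grouping is what the downstream models consume.

## Association scan

Probes missing in more than four samples are dropped (a probe missing in
exactly four is kept — the rule is strictly "more than"). Sample QC runs
PCA on array theta values (column-centred SVD); a sample is an outlier
when its distance from the coordinate-wise median in the first two
components exceeds the median distance plus six times the MAD of the
distances. The 6×MAD rule is this package's choice of robust criterion —
only the *fact* of outlier removal is specified by the source analysis.

Per SNP, the scan cross-tabulates genotype counts by MR group and tests
for an additive allele effect with the Cochran–Armitage trend test
(scores 0/1/2, 1-df chi-square, two-sided p). Effect sizes are
allele-count odds ratios (two alleles per sample, matching how the
published panel ORs are framed) with Woolf normal-approximation 95% CIs;
tables with an empty cell get the Haldane–Anscombe +0.5 correction, and
tables with an empty margin (monomorphic SNPs) are undefined. Genotype
counts enter pairwise-complete per SNP; the modeling stage, by contrast,
is complete-case. Significance is judged against alpha/m for the m SNPs
actually tested. The genomic inflation factor is median(chi²)/0.45494,
and Hardy–Weinberg equilibrium is checked by the 1-df chi-square against
p², 2pq, q² expectations. Power for the extreme-subset design uses the
plain two-proportion normal approximation on 2n alleles per group (not
the arcsine transform), verified against Monte-Carlo simulation.

## Block selection

Candidate SNPs are those with p < 1e-3. Within a chromosome, candidates
are position-sorted and split into runs wherever the gap between
*consecutive candidates* reaches 30 kb (a gap of exactly 30 kb splits;
non-candidate SNPs physically between candidates are ignored, because
the rule is stated over associated SNPs). A run qualifies as a block if
it has ≥3 members and ≥2 below 1e-4. Reading "interval between all pairs
of adjacent SNPs" as consecutive-pair gaps is deliberate: an all-pairs
reading would forbid the reported multi-hundred-kb block regions. The
index SNP is the minimum-p member, ties broken toward the lower
position. Hand-picking several SNPs from one strong region (as done on
chromosome 22) is supported as an explicit allowlist in the pipeline
configuration, not as algorithm behaviour.

## Prediction modeling

The outcome is binary: 1 if MR < 0.0146. Predictors are SNP minor-allele
dosages coded additively, plus (Approach 1) the binary CYP2D6 impaired
indicator or (Approach 2) the CYP2D6-region tag SNP dosages. Only
complete cases are modeled. Logistic fits are maximum likelihood
(statsmodels, Newton iterations, tolerance 1e-8, 100 iterations);
quasi-separation is detected (failed Newton step or runaway
coefficients) and flagged on the fit rather than raised.

- **Selection**: pure forward stepwise. At each step the candidate with
  the smallest likelihood-ratio p against the current model enters while
  that p < 0.05; ties break toward the earlier candidate. The entry
  statistic is the LR test; the originally used software defaults to a
  score test for entry, which is asymptotically equivalent — the choice
  is documented here because the source does not state it.
- **Ranking**: each selected variable is ranked by the −2 log-likelihood
  of the model refit without it; the variable whose removal degrades the
  model most is rank 1. The trace reports both this reduced-model −2LL
  and the cumulative-model −2LL, since published tables are ambiguous
  about which is printed.
- **Cumulative metrics**: Nagelkerke R² = R²_CS / R²_max with
  R²_CS = 1 − exp((2/n)(LL₀ − LL₁)), clipped to [0, 1]; AUC is the
  Mann–Whitney concordance probability computed by rank summation with
  ties counted ½ (identical to trapezoidal ROC integration).
- **Gate**: variables are walked in rank order; one is retained only if
  it raises the model AUC by ≥0.005 over the carried model (the rank-1
  variable is compared against the 0.5 chance baseline), and excluded
  variables do not enter the carried model. The gate's AUC is
  cross-validated by default: the published rank-ordered AUC sequences
  *decrease* after the retained prefix, which cannot happen for
  in-sample AUCs of nested refit models on typical data and indicates an
  out-of-sample estimate. In-sample mode is available for comparison.
- **Cross-validation**: a random k=10 partition with fold sizes
  differing by at most one (re-drawn, with a shifted stream, if a
  training fold lacks a class); per-fold AUC, sensitivity, specificity,
  PPV and NPV on the held-out fold, reported as the mean over folds.
  Pooled out-of-fold confusion counts and pooled AUC are reported
  alongside, since the published counts could be either. Classification
  threshold is probability ≥ 0.5 (configurable; unspecified in the
  source). Display rounding: AUC 3 dp, percentages 1 dp.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
at the study's own operating conditions:

- **Diplotype groups** are drawn i.i.d. from the seven-group frequencies
  of the 287-patient cohort (NM/UM 0.063, NM/NM 0.314, NM/IM 0.153,
  NM/PM 0.345, IM/IM 0.010, IM/PM 0.042, PM/PM 0.073).
- **MR values** are per-group normal draws truncated at zero, with the
  published group means and SDs (e.g. NM/NM 0.0185 ± 0.0057, PM/PM
  0.0037 ± 0.0013). Only means and SDs are reported for the real cohort,
  so the within-group shape is an assumption; truncation is negligible at
  these parameter values (mean/SD ≥ 2.6 in every group). Under these
  defaults ~61% of samples fall below the 0.0146 cutoff, matching the
  real cohort's 175/287.
- **Metabolite panels** invert the MR formula: a total non-endoxifen
  denominator D is drawn lognormal (mean 400 ng/mL, shape σ = 0.4 —
  chosen as a realistic steady-state total dominated by tamoxifen and
  NDM-Tam), split across the 14 analytes by a fixed composition vector,
  and (Z)-endoxifen is set to MR·D, so recomputing MR from a panel
  returns the generating value to machine precision. Only the sum enters
  MR; the composition split matters solely for the activity ratio, whose
  two active metabolites make it monotone in MR by construction.
- **CYP2D6 tag SNPs** are deterministic: dosage = number of PM (resp.
  IM) alleles in the diplotype, mimicking variants that define the
  impaired alleles.
- **Linked SNPs** model long-range LD with the impaired-allele count by
  haplotype copying: each haplotype copies the sample's impaired-allele
  tag with probability φ and otherwise draws an independent background
  allele whose frequency preserves the target MAF. φ is solved
  numerically from the target r² using the cohort's realised tag-count
  moments; heterozygous-impaired samples place the impaired allele on a
  random haplotype so the two haplotype tags are exchangeable. The
  attainable r² shrinks as the SNP's MAF departs from the impaired-allele
  frequency (~0.374 under the default groups), so unreachable (r², MAF)
  pairs raise an explicit calibration error; the defaults (r² 0.75, 0.55,
  0.35 at MAFs 0.37, 0.32, 0.28) sit inside the feasible region with
  margin for sampling variation. The real long-range LD strengths are not
  published, so these are configurable study parameters, not estimates.
- **Effect SNPs** are drawn per sample conditional on below-cutoff
  status, with group allele frequencies solved (Brent root-finding) so
  that the population allele-count OR equals the target exactly given
  the realised below-cutoff prevalence, under HWE within each group.
  Default targets (0.51, 1.93, 0.28 at MAFs 0.45, 0.48, 0.33) are on the
  scale of the published independent-effect variants. In a retrospective
  sampling model like this, the per-dosage logistic coefficient equals
  ln(allele OR) exactly, which the parameter-recovery tests exploit.
- **Null SNPs** are binomial(2, MAF) under HWE with MAF uniform on a
  configured range.
- All randomness flows from one master seed through named substreams, so
  stages are independently reproducible.

What the generator does **not** emulate: population stratification and
batch effects (no structured confounding — the PCA QC will generally
find nothing), raw array intensities (theta values for QC are derived
from dosages), genotyping error, within-group MR covariates
(co-medication, adherence), and real LD beyond the single planted
proxy-to-tag structure. Passing tests therefore demonstrate calibration
and internal consistency of the machinery under the assumed generative
model, not robustness to those real-data complications.

## Test and acceptance problem sizes

Calibration checks use n = 10⁵ for point recovery (OR within 10%),
200 replicates at n = 2000 for CI coverage (expected 90–98% for a
nominal 95% interval), 10⁴ simulations for the trend test's type-I rate
([0.04, 0.06] band), and 50 seeds at n = 2000 for the planted-structure
end-to-end check; these sizes make the Monte-Carlo error comfortably
smaller than each acceptance band. The end-to-end rank-1 check plants
the CYP2D6 effect alongside the three independent-effect SNPs *without*
strong LD proxies in the candidate set: a proxy with r² ≳ 0.75 to the
impaired-allele count can legitimately absorb the CYP2D6 signal and take
rank 1 (collinearity), which mirrors the published observation that the
strongest chromosome-22 proxy was not selected as independent once the
CYP2D6 genotype was a candidate.

## Known limitations

- The stepwise entry test, PCA outlier criterion, probability cutoff and
  gate AUC mode are all documented choices where the source analysis is
  silent; each is configurable.
- Woolf CIs and the trend test are asymptotic; for very sparse tables
  (expected counts ≪ 5) the Haldane correction keeps estimates finite
  but the coverage guarantee degrades.
- The generator draws diplotype groups i.i.d.; it does not model
  allele-level population genetics (no star-allele haplotype
  frequencies, no HWE at the CYP2D6 locus itself).
- `calibrate_mr_cutoff` assumes an approximately linear MR–concentration
  relationship through the calibration range; it is a mapping tool, not
  a pharmacokinetic model.
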