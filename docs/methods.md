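# Methods

## Problem setting

Donor natural-killer (NK) cells express killer immunoglobulin-like receptors
(KIRs). Inhibitory KIRs (iKIRs) recognise HLA class-I epitope groups:
KIR2DL1 binds HLA-C group C2 (Lys80), KIR2DL2/3 bind C1 (Asn80), KIR3DL1
binds the HLA-B Bw4 public epitope (dimorphic at residue 80: 80I strong,
80T weak), and KIR3DL2 binds HLA-A3/A11. After haploidentical transplant,
donor NK cells that were *licensed* (educated on a self ligand in the donor)
but meet recipient cells lacking that ligand are predicted to be
alloreactive and may contribute to graft-versus-leukemia. This package
implements the prediction rules, the donor scoring systems built on KIR
haplotype gene content, and the outcome statistics needed to evaluate them.

## Prediction models

All models are pure functions of the donor KIR gene content and the donor
and recipient ligand profiles.

* **Ligand–ligand**: ALLO iff the donor carries an epitope group (C1, C2,
  Bw4, A3/A11) the recipient lacks. Ignores KIR typing entirely.
* **Receptor–ligand (missing ligand)**: ALLO iff some donor iKIR has no
  cognate ligand in the recipient. Ignores donor education.
* **Educational (licensing)**, per iKIR: ALLO iff donor KIR+ **and** donor
  ligand+ (licensed) **and** recipient ligand−. A KIR+/ligand− donor is
  unlicensed and calls Non-ALLO. KIR2DL2 and KIR2DL3 are pooled into one
  2DL2/3–C1 model (positivity = either gene); Bw4 means either dimorph at
  gene level.
* **KIR2DS1 education**: ALLO iff donor 2DS1+ and C1+ (educated activating
  receptor) and recipient C2+; 2DS1+/C1− donors are hyporesponsive.
* **Synthesis-iKIR**: the number of the four educational iKIR models firing
  (0–4); the binary call is ALLO iff ≥ 1. **Combined**: Synthesis-iKIR OR
  the 2DS1 model.

A model evaluated on a pair with a missing ligand profile returns an
explicit *NotEvaluable* status rather than Non-ALLO; Synthesis-iKIR counts
only evaluable sub-models and flags the pair. This keeps per-model
denominators honest instead of silently deflating ALLO rates.

## Ligand assignment

HLA-B and HLA-C epitope groups come from a packaged two-field lookup
snapshot (`data/hla_ligand_groups.tsv`, version recorded in the run
summary), mirroring the public KIR-ligand database convention. A3/A11
status is rule-based (HLA-A allele group 3 or 11). Unknown alleles raise a
lookup error by default; an optional user-supplied residue-80 annotation
(Asn → C1, Lys → C2) can resolve HLA-C alleles missing from the table, and
is off by default so results stay tied to the versioned snapshot. Bw4
derives from HLA-B only; the HLA-A Bw4 epitopes (A*23/24/32) can be counted
via `include_hla_a_bw4=True` for sensitivity analyses, since published
analyses in this area typically group only HLA-B.

## Donor scores

The KIR locus is split into centromeric and telomeric halves. Cen is Bx if
any of KIR2DS2/2DL2/2DL5B/2DS3 is present, Tel if any of
KIR3DS1/2DL5A/2DS5/2DS1. With presence/absence typing only, B/B
homozygosity cannot be observed directly; it is *inferred* from absence of
the A-motif anchor of that half (KIR2DL3 centromeric, KIR3DL1 telomeric).
This is an approximation of true haplotype phasing and is marked as such in
the motif call.

* **B content** = inferred B-motif copies over both halves (0–4); donor
  category neutral (≤ 1), better (≥ 2), best (≥ 2 with centromeric B/B),
  following the published donor-selection calculator convention.
* **ct-KIR** = 2 for CenB+/TelB−, 0 for CenB−/TelB+, 1 otherwise.
* **CF-iKIR** = (functional 2DL1) + (functional 2DL2 and/or 2DL3, one
  point) + (functional 3DL1), where *functional* means the donor gene is
  present and the recipient expresses the cognate ligand. Maximum 3.
* **Weighted inhibitory score** = 1·(functional 2DL1) + [1 if 2DL2 with
  recipient C1+, else 0.5 if 2DL2 with recipient C1−/C2+ (weak,
  cross-reactive recognition)] + 0.75·(functional 2DL3) + 1·(functional
  3DL1). Maximum 3.75 by exhaustive enumeration. The strong/weak 2DL2
  boundary is kept in an editable rule rather than hard-coded logic.
* **Genotype identifiers**: G2 = all 17 loci present except
  2DL2/2DS2/2DS3; G8 = all except 2DL2/2DS2/2DS5; otherwise otherBx or AA.

## Allele-level classifiers

KIR3DL1 allotypes are classed high/low/null from a packaged table
(`data/kir_allotypes.tsv`); unlisted alleles map to *unknown*, never
silently to high. KIR2DL1 residue-245 lookups (R weaker, C stronger) have
no default and raise for unlisted alleles. The KIR3DL1/Bw4 strength call is
*strong* only for a high-expression allotype with a Bw4-80I+ patient; a
high allotype meeting 80T-only counts weak, per the convention recorded in
the editable strength table. Allele mismatch between donor and recipient is
an undirected set comparison at two-field resolution (homozygous {x,x}
equals {x}); a directional (donor-not-in-recipient) mode exists because the
graft-versus-host direction is sometimes preferred, but the undirected form
is the default since mismatch tables in this field typically do not state a
direction.

## Survival statistics

Event coding: 0 censored, 1 relapse, 2 death without relapse (non-relapse
mortality, NRM); times in days; all intervals two-sided 95%.

* **Kaplan–Meier** (lifelines): product-limit estimator, exponential
  Greenwood (log(−log)) confidence bounds. All-censored input yields a flat
  curve with a warning.
* **Log-rank** (lifelines): K-sample chi-square, df = K−1.
* **Cumulative incidence**: Aalen–Johansen,
  `CIF_k(t) = Σ_{t_i≤t} S(t_i−) d_ki/n_i` with `S` the all-cause KM, so
  `1 − S(t) = Σ_k CIF_k(t)` holds to machine precision at every time.
  The pointwise variance is the delta-method estimator accumulated as
  `var_k(t) = Σ_u W(u)·(A(u) − F_k(t)/S(u))²` with
  `W = S(u−)²·d·(1−(d−1)/(Y−1))/Y²`, `A = (1−F_other(u))/S(u)` at cause-k
  death times and `F_k(u)/S(u)` at competing death times; this reproduces
  the canonical reference implementation exactly, tie corrections included.
  Interval bounds use the log(−log) transform.
* **Gray's test**: K-sample comparison of cause-specific cumulative
  incidence (rho = 0 by default). The score compares subdistribution hazard
  increments using the weighted at-risk process
  `R_k(t) = Y_k(t)(1−F̂_1k(t−))/Ŝ_k(t−)`. The covariance estimator accounts
  for the estimation of the group-specific weights through
  forward-accumulated correction channels and includes finite-sample tie
  corrections; the implementation reproduces the reference `cmprsk`
  chi-square to ~1e-12 across randomized datasets (2–4 groups, heavy ties,
  rho 0 and 1), and the test suite pins a 30-subject fixture at 1e-6.
* **Cox proportional hazards**: lifelines `CoxPHFitter` (Efron tie
  handling, the default of mainstream survival software) behind a guarded
  interface that refuses constant covariates, more covariates than events,
  and non-convergence. Relapse endpoints use *cause-specific* censoring
  (competing NRM censored at its event time): the multivariate analyses
  this package targets are cause-specific hazard models, with the
  subdistribution (Fine–Gray) framework used only for CIF estimation and
  Gray's test. A Breslow option routes through scikit-survival (with Wald
  errors from the observed information); without ties the two tie-handlers
  agree.

No multiple-testing correction is applied: model-by-model reporting is
deliberate and mirrors how these univariate tables are presented; treat
p-values accordingly.

## Synthetic cohort generator

The generator defines the study conditions for all calibration and recovery
checks.

* **HLA**: two haplotypes per subject, alleles drawn per locus from
  East-Asian-like frequency tables (defaults sum to 1; A*11:01 0.22 and
  A*03:01 0.03 give an A3/A11 carrier rate ≈ 0.44; the HLA-C table gives C1
  carriage ≈ 0.95). Haploidentity is simulated by the recipient inheriting
  the donor's first parental haplotype; the other haplotype is independent.
  No linkage disequilibrium between loci.
* **KIR**: genotype = union of two haplotypes drawn from a weighted pool
  (A haplotype 0.55; common B-haplotype contents with centromeric-B
  haplotype frequency 0.30 and telomeric-B 0.26, giving donor Cen-AA ≈ 0.49
  and Tel-AA ≈ 0.55; two rare recombinants make the G2/G8 genotype patterns
  reachable). KIR is drawn independently of HLA (chromosome 19 vs 6).
  Allele-level typing at KIR3DL1/2DL1/2DL3 is drawn from donor-cohort
  frequency tables (e.g. KIR3DL1*015 at 63.7%).
* **Outcomes**: cause-specific exponential hazards. Relapse hazard =
  1.6e-4/day × (model hazard ratios for pairs the configured model calls
  ALLO) × 3.35 for non-remission disease status; NRM hazard 1.5e-5/day;
  uniform administrative censoring on (85, 3193) days; death after relapse
  at 5e-4/day. At 189 pairs these defaults give ≈ 50 relapses, ≈ 4 NRM
  deaths, ≈ 26–30 deaths overall, a 5-year relapse incidence ≈ 0.30 and
  5-year OS ≈ 0.80 — the scale of a pediatric haploidentical cohort.
  Because hazards are constant, relapse times lack the early clustering of
  real cohorts (real median time-to-relapse is a few months); tests of
  *calibration* and *effect recovery* are unaffected, but time-pattern
  statistics should not be read off these cohorts. The generator uses
  cause-specific (not subdistribution) parameterisation, matching the
  cause-specific Cox analysis; a configured cause-specific hazard ratio
  therefore differs slightly, by construction, from the contrast a Gray's
  test targets.
* **Determinism**: `(config, seed)` fully determines the cohort;
  regenerating writes byte-identical files, plus a provenance sidecar JSON.

What passing tests on these cohorts shows: the pipeline's statistics are
calibrated (type-I error at nominal level, CI coverage ≥ 93% at n = 400,
unbiased log-HR recovery at n = 2000 including a strong protective 0.136
scenario) under the generator's assumptions. What it cannot show: robustness
to non-proportional hazards, time-varying effects, HLA–KIR linkage, or
typing error in real data.

## Numerical and design choices

* Percentages print with half-up rounding to one decimal (table
  convention), not banker's rounding.
* Five years is fixed at 1,826 days; horizon estimates are step-function
  values at the largest event time ≤ horizon, with degenerate
  before-first-event results flagged rather than silently reported.
* Jointly typed SSO columns (KIR2DL2/3, KIR3DL1/3DS1) map to both genes
  with a "jointly typed" flag, since motif logic needs per-gene presence.
* Event coding 0/1/2 with NRM = 2 follows the usual competing-risks
  convention.
* Groups with no deaths report "no events" for OS instead of a survival of
  1.000.
* Univariate tables report per-analysis n and exclusion counts; pairs with
  non-evaluable models are excluded from that model's rows only.

## Known limitations

* Motif B/B inference from anchor-gene absence misclassifies rare
  haplotypes that truly lack the anchor on one chromosome only.
* The ligand and allotype tables are snapshots covering the alleles common
  in the target populations; unusual alleles require the user to extend the
  TSVs (the lookup fails loudly rather than guessing).
* The weighted inhibitory score's printed maximum (3.75) is below score
  ranges occasionally quoted elsewhere; the implementation follows the
  formula as defined above and logs score components per pair.
* Fine–Gray subdistribution *regression* is deliberately out of scope;
  multivariate relapse analysis is cause-specific Cox.
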