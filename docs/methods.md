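# Methods

`assocmeta` synthesises case-control genetic association evidence for one
bi-allelic variant at a time. This note records the statistical model, the
decision thresholds, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Per-study effects

Each dataset contributes an allelic log odds ratio. Genotype counts
(hom-minor / het / hom-major) are collapsed to allele counts; the 2x2
allele table (cases x {effect allele, other}) gives

    log OR = log(ad / bc),    se = sqrt(1/a + 1/b + 1/c + 1/d)   (Woolf).

A zero cell triggers a +0.5 continuity correction on all four cells and is
flagged on the effect; the correction can be disabled, in which case
zero-cell studies raise and must be excluded upstream. Summary payloads
(log-OR, se), the form in which GWAS data enter a curated corpus, pass
through unchanged. 95% intervals use z = 1.959964 throughout.

Hardy-Weinberg equilibrium in controls is tested exactly (conditional
enumeration of heterozygote counts given the allele count, two-sided by
summing probabilities no larger than the observed outcome's) for up to
1000 controls, and by the 1-df chi-square goodness of fit above that;
departures at P < 0.05 mark a study as a potential genotyping problem.
Monomorphic controls return p = 1 with a note rather than an error.

## Eligibility

A variant is meta-analysed when at least 4 independent datasets exist and
the control minor-allele frequency reaches 0.01 in at least one study.
The frequency floor is evaluated on studies that expose counts; a
collection consisting solely of summary effects (quality-controlled GWAS)
satisfies it vacuously, since GWAS pipelines apply their own frequency
filters before summary statistics exist. Caucasian (C) and Asian (A)
strata are analysed separately when at least 3 datasets carry the code;
other ancestry codes (D, H, O) contribute to the overall scope only. The
minor allele is fixed once from the pooled case+control counts of the
whole collection so per-study orientation is stable; stratified analyses
keep the pooled orientation.

## Synthesis

The primary model is DerSimonian-Laird random effects: with
inverse-variance weights w_i = 1/se_i^2, Cochran's Q from the fixed-effect
fit yields the method-of-moments heterogeneity variance

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

and studies are re-weighted by 1/(se_i^2 + tau^2). tau^2 is truncated at
zero and no iterative estimator is offered. The fixed-effect fit is
retained as an exploratory companion; its se never exceeds the
random-effects se, with equality exactly when tau-hat^2 = 0.

Heterogeneity is reported as I^2 = max(0, (Q - (k-1))/Q) x 100 with a
test-based 95% interval on ln H (H = sqrt(Q/(k-1))), using the
large-sample standard error of ln H (one expression for Q > k, another for
Q <= k), mapped through I^2 = (H^2-1)/H^2 and truncated to [0, 100). For
k = 2 with Q <= k the standard error is undefined and the interval is
reported as (0, 100) — maximally uninformative, which is honest at two
studies.

P-values are two-sided normal on log-OR/se. Because summary p-values in
this setting reach 1e-65, every result also carries log10(p) computed from
the normal log-survival function; the linear-scale p is clamped at the
smallest subnormal double but ordering and serialisation use the log
scale.

Cumulative traces re-run the random-effects model on the first j studies
in publication order (year, then a curated order index, then study id) for
j = 2..k; a single study is not a meta-analysis, so traces start at j = 2,
and the final point is bit-identical to the full result by construction.

Sensitivity re-analyses drop (a) initial studies and (b) HWE violators at
P < 0.05; flags F and HWE record loss of nominal significance
(p crossing 0.05) in the respective re-analysis. GWAS-only evidence can
alternatively be combined as a sample-size-weighted Stouffer Z.

Allelic power uses a normal approximation on the difference in allele
frequencies implied by the odds ratio at the control MAF, with a
per-group variance convention of p(1-p)/n on subject counts, and the full
two-sided rejection probability (so power -> 1 exactly as alpha -> 1).

## Bias diagnostics

Small-study bias is tested with the modified funnel-asymmetry regression
for binary outcomes: per study the efficient score Z = a - E[a] and
hypergeometric variance V from the allele-table margins, then OLS of
Z/sqrt(V) on sqrt(V) with a t-test (k-2 df) on the intercept. The fit is
unweighted; the flag threshold defaults to alpha = 0.10, the usual
convention for asymmetry tests, and is configurable. Per the pipeline
contract the test runs only where the base meta-analysis is nominally
significant and at least 3 studies expose counts; summary-only studies
are skipped and counted.

Undetected sample overlap is handled as variance inflation: for an
assumed pair of shared case/control counts, the induced correlation
between two studies' estimates follows the shared-subject approximation,
and the summary variance becomes
(sum w)^-2 (sum w_i^2 se_i^2 + sum_{i!=j} w_i w_j rho_ij se_i se_j) under
the base random-effects weights. Scenario analysis assumes overlap
fractions {1%, 5%, 10%} of the smaller group between every same-country
pair, exempting GWAS-GWAS pairs (de-duplicated before synthesis). Zero
overlap reproduces the unadjusted se exactly, and any positive overlap
can only widen intervals.

## Credibility

The approximate Bayes factor contrasts a spike at no effect with a normal
smear of non-null log odds ratios whose standard deviation is ln(1.15) —
the log of a typical complex-disease effect size:

    logBF = log10(e) z^2/2 * W/(V+W) + 0.5 log10(V/(V+W)),
    z = logOR/se, V = se^2, W = (ln 1.15)^2.

Values above 0 favour association; above 5 is treated as strong support.
When only a p-value accompanies the OR, se is recovered as |logOR|/z(p).

Venice/HuGENet interim grading (applied to nominally significant results
only): amount of evidence A/B/C at >1000 / 100-1000 / <100 minor alleles;
replication consistency A/B/C at I^2 <= 50 / <= 75 / > 75 (cutoffs are
configurable; the 50/75 choice matches graded compendium rows where
I^2 in the low 40s still carries grade A, where the canonical 25/50 would
not); protection from bias C when any of the F, HWE, or regression flags
is raised, A otherwise. The composite is the worst component. An OR in
[0.87, 1.15) is annotated "LowOR" without demoting the grade. Population
attributable risk uses Levin's formula on the risk-allele frequency,
inverting protective ORs first.

Ranking orders results by p ascending on the log10 scale (so extreme
values remain distinguishable), ties by |log OR| descending, then variant
id; genome-wide significance is flagged at p <= 5e-8 (inclusive, and
configurable).

## Synthetic data

The generator emulates a curated corpus for one variant: per-study true
effects theta_i ~ Normal(true_log_or, tau2); control MAF fixed; case
allele frequency implied by exp(theta_i) through the odds transform;
genotype counts multinomial under HWE, with designated violator studies
distorted by an inbreeding coefficient of 0.2 (large enough to be
reliably detected at ~500 controls); GWAS studies enter as summary
effects; optional one-sided suppression drops small non-significant
non-GWAS studies with a configured probability — the classic funnel
mechanism. All randomness flows through a single seeded generator;
identical configs are byte-identical on disk.

Defaults (OR 1.15, tau2 0.01, k 10, MAF 0.2, 200-2000 subjects per arm,
ethnicity mix C/A/O = 0.7/0.2/0.1) describe a typical mid-size literature
meta-analysis. The generator does not emulate linkage disequilibrium,
real allele-frequency spectra, covariate adjustment, imputation
uncertainty, or correlated multi-variant structure — so passing tests
demonstrate the synthesis chain's statistical correctness, not robustness
to those real-data features.

Calibration checks run the full simulate-estimate loop: under the null
the base test rejects at ~5%; under truth logOR 0.15, tau2 0.01, k 50 and
per-study se ~0.05 (2000 subjects per arm at MAF 0.3), the mean estimate
is unbiased within Monte-Carlo error and 95% CI coverage falls in
[93%, 97%] over 2000 replicates — slightly below nominal is expected for
DerSimonian-Laird at high I^2, which is why the band is asymmetric around
95%.

## Numerical choices and limitations

- All intervals use z = 1.959964; printed two-decimal reproduction of
  published rows is insensitive to the 1.96-vs-exact choice.
- Continuity correction on/off is a config switch; the default (+0.5, all
  cells, only when a zero occurs) favours comparability of forest plots.
- The results TSV rounds ORs and CIs to 4 decimals, p to 3 significant
  digits; round-tripping through the reader preserves printed precision
  by construction.
- Problem sizes in the test suite (2000 replicates for calibration, k=20
  null regression corpora) were chosen to keep Monte-Carlo error around
  half a percentage point on rejection rates.
- Known limits: Harbord's weighted variants are not implemented; no
  trim-and-fill or selection models; no genotype-model (trend/dominant/
  recessive) association tests — the synthesis is strictly allelic.
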