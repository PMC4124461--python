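# Methods

## Cohort model and censoring

A participant is one woman: CGG repeat count of her largest FMR1 allele,
reproductive history, covariates, and effect-allele counts at the SNP
panel. Repeat groups are Normal (< 55), low PM (55–79), mid PM (80–100)
and high PM (101–200). The printed mid and high ranges overlap at 100;
we assign 100 to the mid group because the mid range is characterized as
"approximately 80–100", and the boundary is a keyword argument for
sensitivity analysis. Repeat counts above 200 are full-mutation alleles
and are rejected — full-mutation carriers are not at increased risk of
ovarian insufficiency and belong to a different clinical entity.

Age at natural menopause is cessation of menses for at least one year,
self-reported, without adjustment for hormone use (hormone use is
recorded but deliberately ignored; adjusting for it would require a
menopause-definition scheme outside this package's scope). Premature
ovarian failure (POF) is menopause strictly before age 40. Censoring for
the survival analysis: no cessation → censored at age at interview;
hysterectomy or other medical cessation → censored at age of last
menses. Participants missing a field required by their branch are
excluded with a logged reason (complete-case; no imputation, since no
principled imputation model is available for self-reported reproductive
history).

## Cox proportional-hazards fit

Age is the time scale from birth; left truncation at study entry is not
modeled (no entry-age mechanism is specified for these cohorts, and with
age-indexed hazards the approximation is standard). The partial
likelihood is maximized by Newton–Raphson with step-halving on any
likelihood decrease; convergence when the largest score component falls
below 1e-8 (or the step reaches float resolution — the score is a sum
over events so its attainable floor grows with n), hard failure after
100 iterations. Ties use the Efron correction by default because
self-reported menopause ages cluster on integers; Breslow is available
by configuration and the two agree to numerical tolerance on tie-free
data (asserted in tests). Standard errors come from the inverse observed
information; per-group p-values are two-sided Wald tests, matching the
one-HR-per-group presentation. Covariates are internally mean-centered
for conditioning only (Cox estimates are invariant to covariate
location). All PM groups enter one joint fit with three indicators
against the noncarrier reference; race/ethnicity is a single indicator
against a configurable reference level.

POF exclusion removes the POF women from the fit entirely (not
re-censoring them): the excluding-POF column asks what the group effect
looks like once the most severely affected tail is gone.

## Burden score and regression

The Total SNP Risk score weights each effect-allele count by the
*magnitude* of the published per-allele effect (years). The published
effect sizes are negative — each allele brings menopause earlier — so
magnitude weights make the score increase with risk burden and put the
expected regression coefficient at a negative value comparable to the
published one. A signed-weight mode exists for sensitivity analysis and
flips the coefficient sign; it is otherwise equivalent.

The regression is OLS of menopause age on repeat, repeat², and the
score, among women with observed menopause only (no censoring enters
this analysis). Repeat terms are uncentered by default so coefficients
are directly comparable with the published scale; a centering flag
improves the condition number and maps coefficients back to the raw
basis exactly. "Partial R²" is the squared partial correlation
t²/(t² + df_resid) — with this definition the three per-predictor values
need not (and do not) sum to the model R². Missing panel genotypes drop
the woman (complete-case, logged); no dosage imputation.

## Variant prioritization

Quality pass requires QUAL ≥ 30, quality-by-depth ≥ 5, homopolymer run
< 6 and strand bias < −0.10, with a called genotype in every case and
control sample; "pass in all samples" is read as site-level thresholds
plus no no-calls, so a single no-call drops the site. The strand-bias
inequality is taken as printed: more-negative log-odds = less biased,
pass strictly below −0.10. "Homopolymer run" is the caller's HRun
covariate. Variant positions are VCF 1-based; interval files are BED
0-based half-open, so a variant at position p overlaps [start, end) iff
start ≤ p−1 < end. Multi-allelic records are decomposed to bi-allelic
records before filtering. Non-synonymous means missense, stop gain/loss
and start loss; splice variants are excluded. MAF classes: common iff
max-over-sources MAF > 1% (max is the conservative aggregation), rare if
known at or below 1%, novel if absent from dbSNP with no frequency
record. Gene enrichment: ≥ 5 case-specific non-synonymous variants and
at least twice as many case-specific as control-specific, minus a
user-supplied blocklist of genes prone to spurious burden (extreme
length, relaxed selection, cryptic paralogs). The blocklist defaults to
empty with a loud warning because no canonical list ships with the
package. A per-variant case-carrier count is reported so both the
"any case" and "multiple cases" readings of case-specificity are
available downstream.

## Synthetic-data generators

The generators define the study conditions for all recovery tests; they
are seeded and byte-reproducible.

**Cohort generator** (burden analysis): latent age at natural menopause
for PM women is `126.0 − 1.650·r + 0.009·r² − 3.710·TSR + ε`,
ε ~ Normal(0, 7.6²); noncarrier women get a flat intercept of 60.1 (mean
≈ 49.5 after the burden term) because the quadratic is a
premutation-range model and extrapolates absurdly below 55 repeats.
Genotypes are Hardy–Weinberg at the published effect-allele frequencies,
independent across SNPs (no LD — the real panel SNPs sit on five
different chromosomes, so this costs little). Latent ages below 14 are
redrawn (physiologic floor). Repeat draws are uniform within group
bounds, with high-PM capped at 140: the upward branch of the quadratic
makes ages near 200 repeats non-physiologic and observed study repeats
top out in the 90s. The default design is 25/40/7 low/mid/high with
menopause observed for everyone (interview after the latent age); the
`full_study()` configuration adds noncarriers at the observed 694/247/
350/113 composition with interview-age and hysterectomy censoring.

The residual SD (7.6 years) is derived in closed form in
`scripts/calibrate_residual_sd.py`: under HWE the score variance is
Σ wⱼ²·2pⱼ(1−pⱼ) = 0.283, and σ = 7.6 reproduces the published
score-coefficient SE of 1.684 at n=72, implying a partial R² of ~0.067.
No simulation output feeds back into this constant.

**Survival generator**: event ages follow a Weibull baseline (shape 12,
scale 52.6 — median ≈ 51 with the sharp late-40s hazard rise) with the
hazard multiplied by exp(group log-HR + covariate effects); defaults are
ln 2.4 / ln 4.1 / ln 2.5 for low/mid/high PM, 0.25 for smoking, −0.01
per BMI unit, 0.10 for the race indicator. Interview age is independent
of the event time, so its true regression coefficient is zero and
censoring is independent given covariates. This generator is
deliberately separate from the cohort generator: the burden analysis
models the age linearly while the survival analysis models the hazard
proportionally, and no single mechanism realizes both published truth
sets simultaneously. Consequently the hazard ratios fitted on the
*cohort* generator's output are internally consistent but do not equal
2.4/4.1/2.5 — only the survival generator carries those truths.

**Variant generator**: one synthetic chromosome with one exon block per
gene; planted case-specific common/rare/novel missense variants in
candidate-list genes, planted enriched genes whose case/control counts
satisfy the enrichment rule by construction (validated at config time),
and decoys failing each quality filter, inside segmental duplications,
or outside exons at configured fractions. Background variation never
lands in planted enriched genes and contributes no case-specific
missense to candidate-list genes, so the planted truth is exactly
recoverable — this makes end-to-end recovery a sharp test rather than a
statistical one. The truth record lists every planted item.

What the generators do *not* emulate: family ascertainment structure
(the real cohorts are enriched from fragile-X families; observations are
generated independently), linkage disequilibrium, genotyping or
repeat-sizing error, recall error in self-reported ages, and realistic
genome geometry (gene lengths, overlapping transcripts). Passing
recovery tests therefore demonstrates the estimators are unbiased and
correctly implemented under the assumed generating models, not that the
published estimates are robust to those real-data complications.

## Numerical choices and degenerate inputs

- Rank-deficient Cox designs, designs with fewer than two distinct event
  times, and non-convergence raise typed errors with diagnostics rather
  than returning partial results; results objects always carry
  `converged=True`.
- The burden fit refuses designs with condition number above 1e12 and
  reports the condition number.
- A cohort with no PM carriers yields an empty hazard table (not an
  error); a repeat group with no menopause reporters reports an absent
  mean, never zero.
- Report writers use fixed column orders and fixed precision (3 decimals
  for ages/HRs/coefficients, 4 for p-values), so identical inputs give
  identical bytes.
- Replicate seeds in the reproduction script are derived arithmetically
  from the base seed and kept below 2³¹.

## Problem sizes

Recovery suites run 500 replicates at n=72 (burden) and 200 replicates
at n=1400 (survival), the studied sample sizes; the tie-free
closed-form equivalence check uses a single 12-million-observation
two-group exponential fixture, where the partial-likelihood estimate and
the per-group events/exposure rate ratio agree to three decimals. These
sizes were chosen so each suite completes in about a minute on one CPU.

## Known limitations

- No frailty/random-effects Cox model (family clustering is ignored).
- The score uses a fixed five-SNP panel; it is not a genome-wide
  polygenic score.
- Annotation (consequence, deleteriousness, conservation) is consumed,
  never computed; the package trusts its inputs there.
- Left truncation and time-varying covariates are out of scope.
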