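# Methods

## The differential-editing test

Alt-read counts at a candidate site are binomial given per-sample depth.
The condition effect is estimated by binomial logistic regression of
(alt, ref) counts on a condition indicator with donor fixed effects; the
reference donor is absorbed into the intercept. "Paired samples" is thus
read as conditioning on donor: each donor contributes one normoxia and
one hypoxia sample, and the condition coefficient β1 is a within-donor
log odds ratio. A two-sided Wald test on β1 is the default; a
likelihood-ratio test against the donor-only model is available via
`glm_condition_test(..., test="lrt")`. With identical donors the MLE of
β1 equals the log odds ratio of the condition-collapsed 2×2 table, which
the unit tests exploit (the three-donor 30/70-vs-2/98 example has
β1 = ln 21 exactly, verified against a grid-search maximum-likelihood
oracle written without any GLM machinery).

**Separation.** When any cell of the condition-collapsed table
(alt/ref × condition) is zero the unpenalized MLE diverges. The fit then
falls back to the collapsed table with 0.5 added to all four cells
(Haldane–Anscombe), donor terms dropped, and the result is flagged
(`separation_corrected`). This is deterministic, dependency-free and
conservative; Firth-type penalization was deliberately not used.

**Multiplicity.** Benjamini–Hochberg step-up q-values are computed across
all tested sites in one family, C>U and A>I jointly, by default
(`fdr_family="per_class"` adjusts each class separately). Direction
calls use the strict rule β1 > 0 and q < α (α = 0.05): "hypoxia-higher"
events are exactly those with OR > 1 at FDR < 0.05.

**Calibration.** At the default study conditions (3 donors, depths
20–200, ~2% baseline editing, donor SD 0.3 logits) the Wald test's
empirical type-I error over 2000 null sites is ≈ 0.033–0.035 — slightly
conservative, mostly because low-count sites route through the Haldane
correction — and the mean recovered β1 over 200 sites at depth 500 is
within 0.01 of the simulated +2.0. Both are recomputed by
`scripts/acceptance.py` at every run.

## Filter cascade

Order: canonical mismatch classes → SNP blacklist removal → ≥ 5%
prevalence (inclusive, any sample; zero-coverage samples excluded) →
GLM/FDR/direction → −1 C/T → stem-loop in exons/UTRs. Blacklist removal
precedes the prevalence filter, so prevalence is computed on the
SNP-cleaned set. The −1 and structural filters apply only to C>U-class
events; A>I events stop after direction classification and are reported
as-is (database cross-referencing of A>I calls is a reporting step via
`overlap_sites`, not a filter). Every stage's output is asserted to be a
subset of its input, and identical inputs/config give byte-identical
outputs.

## The stem-loop predicate

The edited C must be the 3′-most base of a 3- or 4-nt loop whose closing
stem has either ≥ 2 consecutive Watson–Crick pairs with no defect, or
≥ 4 pair positions containing exactly one defect — a single
non-complementary pair (mismatch) or a single skipped nucleotide on one
arm (bulge). Choices made where the informal rule is ambiguous:

- the loop-closing pair must be a true pair (a mismatch there would
  enlarge the loop);
- the outermost counted pair must be a true pair, so defects are strictly
  interior (mismatch offsets 2..stem−1; bulges between counted pairs);
- at most one defect per stem;
- G:U wobble pairs are not complementary by default (`wobble=True`
  enables them; on random windows this flips a nontrivial fraction of
  calls, so the flag is surfaced everywhere);
- any pair involving N never pairs, and an N at −1 fails the dinucleotide
  filter (conservative).

Preference order of the reported geometry: perfect before defective,
shorter loop first, longest stem within a category, mismatch before
bulge on ties, then smaller offset and 5′ arm. `enumerate_structures`
brute-forces every (loop, defect type, defect position, stem length)
combination independently of the scanning predicate; the two agree on
qualification for every window tested (10⁴ random windows per run plus
N-containing and adversarial cases). The original structural curation
this formalizes was manual, so disagreements with any externally curated
list are reported per site rather than silently reconciled.

## Synthetic data

The generator emulates the assumed study design: 3 donors, paired
conditions, per-sample depth uniform on 20–200, baseline editing ~2%
(logit −3.89) with donor random intercepts (SD 0.3 logits — the donor
spread is a free parameter, not an empirical value), and a +2.0 logit
condition effect giving ~10–30% editing in the induced condition.
Hairpins are planted around every truly edited C by default
(`planted_stemloop_frac`), with the −1 base C with probability 0.7 and T
otherwise (the CC-preferring enzyme dominates but TC events occur).
SNP contaminants sit at alt fractions ~0.5 (het) and ~1 (hom) in all
samples and are emitted in the blacklist; noise sites draw a shared alt
fraction uniform on (0, 0.04), below the 5% prevalence cutoff by design;
null sites carry baseline editing with no condition effect. Default
class counts (60/20 edited up in hypoxia/normoxia, 30+30 SNPs, 40 noise,
100 null) are a scaled-down rendering of a discovery-scale experiment
chosen so a full run stays desk-sized; the 3:1 induced-direction ratio
mirrors the asymmetry such experiments report. Background flank
composition is i.i.d. uniform ACGT — a neutral null for motif and
structure statistics.

What the generator does **not** emulate: read-level artifacts (alignment
error, strand bias, duplicates), RNA degradation, overdispersion beyond
binomial (no beta-binomial), expression-correlated coverage, or linkage
between neighboring sites. Passing end-to-end tests therefore shows the
statistical machinery is correct and calibrated under the stated model,
not that real libraries are free of those artifacts.

## Contingency statistics

Pearson chi-squared (df = 1) uses no continuity correction by default:
on the mismatch-class table (225, 93; 567, 394) the uncorrected statistic
reproduces the reference p = 0.000183 while the Yates-corrected one does
not, which fixes the convention. Two-sided Fisher exact uses the
point-probability rule (sum of all margin-fixed tables with point
probability ≤ the observed), matching brute-force hypergeometric
enumeration for every table with N ≤ 40; a central (doubled one-tail)
variant exists. The retention statistic deliberately compares the
composition of a retained subset against its pre-filter superset — the
rows of that 2×2 overlap, which the output metadata records.

## Sanger quantification

The editing level from chromatogram peaks is minor/(major + minor),
bounded by 0.5; when the nominal minor peak is taller the pair is swapped
with a warning. A minor peak is "detected" when it reaches 5% of the
major peak's height (boundary inclusive), so the minimum quantifiable
level is 5/105 ≈ 0.048. Heights are taken at face value from CSV;
trace-file parsing and base calling are out of scope.

## Problem sizes and numerical choices

Default test and acceptance runs use 2000 null sites (type-I error), 200
sites at depth 500 (effect recovery), 10⁴ windows (predicate/oracle
agreement) and a 280-site cascade; these sizes give stable two-decimal
estimates of the monitored rates. All randomness flows from explicit
`numpy` Generator seeds; re-running any component with the same seed is
bit-reproducible. Threshold comparisons are inclusive for "at least 5%"
(prevalence, minor-peak detection) and strict for FDR < 0.05.

## Known limitations

- The GLM uses donor fixed effects, not a random-effects model; with many
  donors and sparse counts a mixed model could be preferable.
- The structural predicate has no thermodynamics: any Watson–Crick
  geometry qualifies regardless of stability, and loops not ending at the
  edited base are out of scope.
- The Haldane fallback discards donor structure for separated sites.
- Editing levels are point estimates; no uncertainty is propagated into
  the prevalence filter.
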