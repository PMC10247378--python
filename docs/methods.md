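# Methods

This note documents the models and procedures implemented in `metprime`,
the defaults they run with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Data model

All stages exchange typed TSV tables keyed on `sample_id` (samples,
treatments, copy-number segments, mutations, context counts, signature
profiles, exposures, SV clusters, drivers, arm definitions). Coordinates
are 0-based half-open (BED convention) internally and on disk; this is
deliberate — length arithmetic is unambiguous — but differs from the
1-based upstream somatic-caller ecosystem, so imported coordinates must be
shifted. Validation is total: every documented invariant (unique sample
ids, non-overlapping segments per chromosome, pyrimidine-centred SBS
contexts, probability vectors summing to 1, …) raises a structured error
naming the offending rows; nothing is silently repaired. A GRCh37
cytoband-derived chromosome-arm table ships as replaceable package data
(any arm coordinate table of the same schema can be substituted).

## Statistical primitives

Cohort contrasts reduce to: two-sided Mann–Whitney U (exact null
distribution when the pooled size is ≤ 12 and untied, otherwise the normal
approximation with tie and continuity corrections — the exact-path cutoff
is a speed choice, both paths are exposed), two-sided Fisher's exact test
with the standard "probability ≤ observed" rule, and BH / Holm /
Bonferroni corrections. Effect sizes: the sample odds ratio ad/bc
(reported as +inf when bc = 0; no Haldane correction is applied), Cliff's delta for numeric
contrasts and Cramér's V signed by the log odds ratio for binary ones.
Rows of every 2×2 table are fixed as (metastatic, primary) so positive
effects always mean metastatic-enriched. Cosine similarity, mean
silhouette (singleton clusters contribute 0) and non-negative least
squares round out the set. Each primitive is verified in the test suite
against an independent brute-force oracle (full rank-assignment
enumeration for Mann–Whitney at pooled n ≤ 12, hypergeometric enumeration
for all 2×2 tables with total ≤ 40, literal step-up/step-down hand
computations for the corrections).

## Stage models and thresholds

**Clonality.** A mutation with subclonal likelihood ≥ 0.8 is subclonal.
The clonal fraction counts SBS + MNV + ID records; samples with zero
counted mutations are excluded rather than assigned 0 or 1, because the
fraction is undefined. Cohorts are compared per cancer type
(Mann–Whitney, BH across cancer types, q < 0.05); metastatic biopsy-site
groups need ≥ 5 samples each and their pairwise p-values are reported
unadjusted by default (a flag enables BH), mirroring how single pairwise
comparisons are usually reported.

**Karyotype.** Segment CNs round half-away-from-zero (2.5 → 3):
"nearest integer" alone leaves the halfway case open, and this choice is
deterministic and standard in CN practice. Arm ploidy is the integer CN with the
largest covered base fraction; coverage ties break toward the lower CN
(conservative against calling gains; configurable). Observed genome
ploidy is the modal arm ploidy, ties broken toward the
segment-length-weighted mean CN. Expected ploidy: 2 without WGD, 4 with
WGD and observed < 6, 8 at observed ≥ 6 (observed > 8 is rejected as out
of the supported range). Normalized arm classes (−1/0/+1) feed the
per-arm Mann–Whitney (classes, not raw ploidies, are the default — a flag
switches); significance needs q < 0.01 *and* a mean class difference
strictly above 0.25.

**Instability indicators.** Aneuploidy score = arms deviating from the
expected genome ploidy. LOH fraction = genome share of segments with
minor CN < 0.25 and major CN ≥ 0.8, divided by the total genome length
from the arm table. The WGD indicator is recomputed from length-weighted
chromosome-level CN (> 10 autosomes above 1.5); chromosome-level CN is a
length-weighted mean because the upstream definition is left to the
caller. TP53 status is any retained TP53 driver event (likelihood > 0.5),
multiple events counted once. Mann–Whitney for the numeric indicators,
Fisher for the binary ones, BH across cancer types per indicator, q < 0.01.

**Signatures.** De novo profiles matching a reference profile at cosine
≥ 0.85 inherit its aetiology; the rest are clustered by average-linkage
agglomerative clustering on cosine distance (average linkage — standard
for signature profiles; complete and Ward are configurable), cutting at the k ∈ {2…n−1}
maximizing the mean silhouette under the same cosine metric. Identical
profiles (silhouette undefined) fall back to one cluster with a warning.
Cluster labels are for manual curation via an editable mapping file — the
curation itself is data, not code. Comparisons per (cancer type,
aetiology): absolute contributions (Holm within cancer type × mutation
type; significant at q < 0.05 and |log₂((med_met+1)/(med_pri+1))| ≥ 0.4 —
the 0.4 log₂ threshold is the operative rule; note 2^0.4 ≈ 1.32, not the
"×1.4" sometimes quoted for it), relative contributions (share of the
mutation-type total; q < 0.05 and median difference ≥ 0.01), and
hypermutator prevalence (thresholds 10,000/500/1,000 for SBS/DBS/ID,
tested only where a cohort has ≥ 5 hypermutators, Bonferroni-corrected,
signed Cramér's V as effect).

**Clock-like SBS1.** SBS1 mutations are C>T at ACG/CCG/GCG (TCG is
excluded to avoid APOBEC contamination; skin melanoma additionally drops
CCG, which overlaps the UV signature). Hypermutators (TMB > 30,000 or
SBS1 > 5,000, both strict) are excluded everywhere, including the per-year
primary rates. The regression runs 100 OLS fits on random 75% subsets
drawn *without replacement* (subsampling, not a classical bootstrap); the representative fit is the one with the median slope —
lower median for even counts, so the representative line is always an
actually fitted one — and confidence bands come from the 1st/99th
percentile fits. The cohort comparison gates on Pearson r > 0.1 in both
cohorts, compares both cohorts' residuals against the primary fit
(Mann–Whitney, P < 0.01) and requires the metastatic intercept to exceed
the primary one. fc̄ and SBS1diff average the per-age prediction ratio and
difference over integer ages 40…80; these equations are conventionally
written with a 1/40 coefficient over those 41 terms, and because the
quantity is a mean, the default divides by 41 with a `literal_1_over_40`
switch reproducing the 1/40 arithmetic. Per-mutation signature assignment
(for SBS5/SBS40 clonality) is maximum likelihood over exposure × channel
probability with lexicographic tie-break; samples with zero clock-like
exposure aggregate to 0, never null.

**SV burden.** DEL/DUP clusters must be intrachromosomal and split at
10 kb; COMPLEX plus all inversion/translocation resolved types split at 20
breakpoint junctions; LINE is its own class; other tokens are dropped from
the seven counts and the total. Burden comparisons use Bonferroni (q <
0.05) plus a pseudocounted median fold-change gate (≥ 1.2 or ≤ 0.8); a
zero primary median sets a ">" display flag. The feature screen regresses
log₁₀(burden+1) on genome ploidy, treatment count, HRD/MSI, per-mechanism
treatment flags and per-gene driver status (primaries and unannotated
metastatics are coerced untreated); boolean gene features need ≥ 15 true
samples in the combined fit and ≥ 10 in the cohort-specific fits, all
remaining booleans ≥ 5% true; numeric features are never
prevalence-filtered. A feature explains the metastatic increase only if
the combined model passes (overall F-test P < 0.01 — applied to the
combined model only — coefficient P < 0.01, coefficient > 0), the association repeats in a
single-cohort fit, and the feature's cohort effect size is positive. The
screen runs only for (cancer type, SV class) pairs whose burden comparison
was significantly *increased* under the burden rule itself (q < 0.05 plus
the fold-change gate).

**Drivers and TEDs.** Driver events with likelihood > 0.5 (strict) are
deduplicated per gene before counting; count comparison per cancer type at
q < 0.01 (BH). Per-gene enrichment builds 2×2 tables per (gene, alteration
category, cancer type) — homozygous disruptions count as deletions,
partial amplifications as amplifications — with a ≥ 5-mutated-samples
filter, Fisher, BH within cancer type, q < 0.01. Treatment groups pair
cancer type with treatment mechanism and need ≥ 10 patients; the untreated
comparison group is treatment-annotated metastatic patients of the same
cancer type who did not receive the tested mechanism (a strict flag
restricts to fully untreated patients). Candidate elements default to a documented frequency-based
stand-in (genes altered in ≥ 3 treated patients) with a plug-in path for
externally produced coding/non-coding/CN candidate lists, since formal
driver-discovery tools are out of scope. The Fisher test runs per
element, BH within alteration category, q < 0.05 for coding/CN and q < 0.1
for non-coding (which also need ≥ 3 mutated treated patients);
"treatment-exclusive" means untreated frequency < 5% (strict). Gene CN
status: amplified iff gene ploidy exceeds the genome-wide mean by strictly
more than 2.5; deleted iff gene ploidy < 0.3. Overlapping CN candidate
peaks merge per cancer type (amplifications and deletions separately),
keeping the lowest-q treatment and summit-nearest gene. Per (gene, cancer
type, category) only the most significant treatment association survives
unless a curated literature pairing pins another. The TED exclusion
recount removes catalogue entries in a cancer-type-, gene- and
category-specific manner. Patients, not samples, are the testing unit.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
tumour biology: ages are truncated normal (62 ± 11, 30–90); SBS1 counts
are Poisson with mean slope × age × cohort fold change (defaults 4/yr and
1.5, the magnitude reported for breast-like cohorts); other processes are
gamma-Poisson around per-cohort means with APOBEC enriched and a
platinum-like signature restricted to platinum-treated samples; clonal
fractions default 0.85 (primary) vs 0.92 (metastatic); WGD probabilities
0.25 vs 0.5; two arm events (5q loss 0.10→0.45, 8q gain 0.15→0.40) on a
0.05 per-arm background; SV counts are negative binomial with log₁₀ means
linear in HRD, ploidy and cohort (overdispersion motivated by the long
burden tails of real cohorts); a hormone-therapy-linked driver carries an
injected odds ratio of 8. Every injected value is recorded in ground-truth
tables. Contexts are generated directly as channel labels and genomic
positions are uniform noise — coordinates exist only to satisfy the
schema. Randomness is a single stream split per sample by a stable hash
of the sample id, so enlarging a cohort never changes existing samples.

What passing recovery tests does **not** show: the generator has no
genomic correlation structure (no linkage of SVs to CN segments, no
kataegis/clustered mutations, no realistic breakpoint mechanics, no
covariance between age and treatment exposure), so real-data confounders
of that kind are untested here.

Targeted simulators back the stage-level calibration suites at the sizes
used throughout: clock-rate recovery on 250 points/cohort over fc ∈ {1.0,
1.25, 1.5, 2.0} (slope 4/yr, noise sd 30, 20 seeds/level); the three-LM
screen at 200/cohort with a +0.3 log₁₀ injected coefficient, a
cohort-confounded null feature and all-null runs; the TED test at 40
treated vs 200 untreated patients, baseline 5%, OR 8, plus a 200-gene null;
and a 6-aetiology identical-cohort null for the signature comparison. The
full end-to-end run used by the reproduction script is two cancer types at
300 samples per cohort.

## Numerical choices and degenerate inputs

- CN rounding half-away-from-zero; coverage ties toward the lower CN;
  modal-ploidy ties toward the length-weighted mean.
- Odds ratios with an empty cell report +inf (or NaN when both diagonals
  vanish); degenerate 2×2 margins give a signed Cramér's V of 0 with a
  warning.
- Samples with no mutations are excluded from clonality; samples with no
  SBS1 mutations are excluded from clonality ratios; constant inputs make
  the Spearman rate correlation return null with a warning.
- Maximum-likelihood mutation assignment breaks ties lexicographically and
  returns unassigned when all likelihoods vanish.
- Rank-deficient LM designs drop aliased columns rather than failing.
- Floats serialize at %.6g so write→read→write round-trips byte-identically.

## Known limitations

- Driver discovery is a frequency-based stand-in with a plug-in interface;
  dN/dS-style selection inference, non-coding element discovery and focal
  CN peak calling are intentionally out of scope.
- De novo signature extraction (NMF) is consumed, never performed.
- The Mann–Whitney exact/asymptotic switch at pooled n = 12 means large
  tied datasets always use the approximation; both paths share one
  interface, so the cutoff can be raised where exactness matters.
- The biopsy-site and TED analyses assume one biopsy per patient; multiple
  biopsies per patient are collapsed upstream of this package.
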