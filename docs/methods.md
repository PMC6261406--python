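# Methods

`cnvcase` implements a genome-wide CNV case-control analysis of the kind
used to study systemic lupus erythematosus (SLE) in admixed cohorts: burden
comparison, CNV-region (CNVR) construction, a four-step rare-CNV filter,
single- and joint two-locus copy-number association adjusted for ancestry,
and target-specific copy-number quantification by qPCR ΔΔCT and droplet
digital PCR.  This note records the models, the defaults and why, and what
the synthetic-data generator does and does not emulate.

## Coordinates and interval matching

All intervals are 1-based and inclusive on both ends (the convention of
GRCh37 array reports), so `size = end - start + 1`; kb sizes are rounded
half-up, which reproduces the printed sizes of the shipped rare-CNV catalog
exactly from its coordinate column.  BED I/O is the only 0-based half-open
surface, converted explicitly at the boundary.  Whether array-export
coordinates are inclusive of the last probe position is not standardized
across vendors; the inclusive choice is a package decision, consistent with
the catalog arithmetic.  Chromosomes are autosomes plus X; Y is outside the
calling scope.

Two intervals "match" under an overlap rule.  The default for every filter
is 50% reciprocal overlap with same-type (loss/gain) matching — the
standard CNV-comparison criterion — with an any-overlap (≥1 bp) mode
available.  The rule is a single configuration knob and is echoed into the
rare-pipeline report for auditability.

## Burden analysis

Per-sample burden is the count and summed size of calls, split by loss
(CN < 2) and gain (CN > 2) and by chromosome.  Group comparisons fit
case status ~ measure + sex + one admixture proportion by maximum-likelihood
logistic regression; the odds ratio is per call (count measures) or per
base pair (size measures, default total bp per sample rather than mean bp —
both are computed per sample and either can be passed).  Only one of the
three admixture proportions (African, European, Amerindian) enters a model
at a time because the triple sums to one; African is the default and the
component is switchable, with per-component refits available.

Per-chromosome comparisons are two-sample t-tests on call count and summed
size.  Welch's unequal-variance form is the default (group sizes like
23 vs 110 make pooled variance fragile); the classical pooled test is an
option.  No multiplicity correction is applied by default, so the
per-chromosome p-values are raw.

Quasi-separated logistic fits (routine when carrier counts are small) are
detected by divergent coefficients or standard errors and re-estimated with
a Firth Jeffreys-prior penalty, implemented in `cnvcase._stats`; such
results are flagged `method="firth"` rather than silently reported.

## CNV regions

A CNVR is a connected component of the ≥1 bp overlap graph over same-type
segments on one chromosome — the union-of-overlaps recurrence definition.
Losses and gains never merge, copy-number magnitude (0 vs 1, 3 vs 4+) is
ignored for region typing, and a sample carrying several member segments
counts once as a carrier.  The implementation is a sort-and-sweep merge;
its equivalence to brute-force graph components is property-tested.  Each
region's carrier frequency is tested two ways — the adjusted logistic
carrier model and an unadjusted Fisher exact test on the 2×2 carrier table
— and both are emitted, since with individual covariates the two can
legitimately differ.

## Rare-CNV identification

The four-step cascade filters the case call set of the primary caller:
(1) remove calls matching any same-type control call; (2) remove calls
matching a population-frequency panel entry at ≥ 1%; (3) remove calls
matching a known-variant panel entry; (4) keep only calls replicated by an
independent second caller *in the same sample* (cohort-level replication
would conflate recurrence with technical confirmation).  Retained sets are
nested, each removed segment carries the step that removed it, and the
population-frequency label of survivors is `"< 1%"` (matched only
sub-threshold entries) or `"-"` (matched nothing), the two label values a
final rare-variant table needs.  Step order is fixed as above because a
sequential cascade is what per-step retention counts describe.

## Locus association

Integer copy numbers classify as del (CN < 2), diploid (2), dup (> 2).
For a locus pair (A, B) each sample falls into one of eight joint
categories; a single logistic model with category indicator variables plus
sex and one admixture proportion estimates each category's odds ratio
against the diploid-at-both-loci reference (Wald intervals; Firth fallback
under separation).  One joint model, not per-category 2×2 models, because
all categories share one reference.  The `mixed` category (deletion at one
locus, duplication at the other) is reported in the counts but excluded
from the default contrasts — it answers a different question than the
del/del and dup/dup synergy contrasts; `include_mixed=True` models it.

## Copy-number assays

**qPCR ΔΔCT.**  `cn = 2 · 2^(−ΔΔCt)` with ΔCt the target-minus-reference
mean cycle threshold and ΔΔCt its offset from a known-diploid calibrator.
Amplification efficiency is assumed to be exactly 2 per cycle (pure ΔΔCT);
an efficiency-corrected mode is out of scope.  Triplicate QC: if the
replicate range exceeds 0.5 cycles the replicate farthest from the median
is dropped; fewer than two usable replicates fails the sample.  Replicate
scatter propagates to a 95% interval on the estimate.  A non-amplifying
target with an amplifying reference is called CN 0.

**ddPCR.**  Droplet occupancy is Poisson, so the concentration follows
from the positive-droplet fraction as `λ = −ln(1 − p̂)` copies per droplet,
divided by the droplet volume (default 0.85 nL, the vendor-standard value
for the common platform; configurable).  The single-well 95% interval is
the normal interval on p̂ transformed through the Poisson correction, with
an exact one-sided bound when no droplet is positive and a saturation error
when all are.  Copy number is `2 · (target concentration / reference
concentration)`; the volume cancels when both wells share it.  The interval
on the ratio treats the wells as independent and propagates on the
log-ratio scale by the delta method.

**Integer calling.**  Estimates round half-up, but an estimate within
±0.15 of a half-integer is a no-call rather than a forced genotype; call
rate is therefore reported alongside accuracy (accuracy is defined over
made calls).  A run is valid only if its known-diploid internal-control
sample calls CN 2 at every assayed locus.

## Synthetic cohorts

The generator emulates the statistical structure of an array-based CNV
screen of a tri-hybrid Brazilian-style cohort, with defaults set to the
study conditions the analysis is meant for:

- cohort 23 cases / 110 controls (array arm); ancestry proportions
  Dirichlet(2, 6, 1) (≈ 0.22 African / 0.67 European / 0.11 Amerindian);
  female fraction 0.90 in cases (the ~9:1 sex ratio of SLE) and 0.70 in
  controls;
- per-sample call counts negative binomial, means 19.4 (cases) and 24.1
  (controls), dispersion k = 4.5 — chosen so the count SD is ~10–11, the
  overdispersion visible in per-subject call ranges of roughly 5–55 and
  7–74;
- losses are 76% of case calls and 62% of control calls; sizes are
  lognormal with log-means 10.3 (losses) and 11.6 (gains) and log-SD 0.8,
  making the mean deletion several-fold (≈3.7×) smaller than the mean
  duplication;
- chromosome assignment proportional to GRCh37 length with the X weight
  multiplied by 10, putting the X among the most CNV-dense chromosomes per
  sample as observed in female-biased cohorts;
- probe support is size divided by a 600 bp probe pitch, and emitted calls
  respect the caller's 25-probe (deletion) / 50-probe (duplication) minima;
- a second caller re-detects each call with probability 0.8 and adds
  Poisson(3) private calls per sample;
- the rare cascade is planted by marking each case background call as
  shared-with-controls (p = 0.80; an identical call is placed in a random
  control), panel-common (p = 0.24 of the remainder; an entry at 1–20%
  frequency enters the frequency panel), known-variant (p = 0.27 of the
  remainder), or candidate-rare — rates matching the per-step survival of a
  447 → 88 → 67 → 49 → 21 style cascade; a fraction (0.4) of candidate-rare
  calls also enter the frequency panel below 1%, exercising the "< 1%"
  label;
- two risk loci (FCGR3B-like and ADAM3A-like) are planted at
  carrier-level: control del/dup carrier frequencies (0.10/0.08 and
  0.12/0.05 — stated assumptions, as no control frequencies are published
  for these loci) and per-class target odds ratios; case carrier
  probabilities solve the carrier-odds inversion
  `odds_case = OR · p/(1−p)`.  Both callers detect planted risk segments.

Ground-truth rarity labels are recomputed from the emitted artifacts by a
brute-force all-pairs matcher internal to the generator, so they remain
correct even when background calls collide by chance, and the label route
is independent of the pipeline's interval-tree route.

For the two-locus synergy analysis a second generator plants odds ratios at
the joint-category level: cases draw categories from the odds-tilted
distribution `p_case(k) ∝ p_ctrl(k) · OR(k)`, which under case-control
sampling makes each category's true odds ratio exactly `OR(k)`.  Per-locus
independent planting cannot fix the joint OR directly (it becomes a product
of marginals), so the category-level generator is the one used for
parameter-recovery checks (defaults: single-deletion OR 3.6, joint-deletion
OR 5.9, duplication ORs 0.2–0.5).

Assay simulators follow the assay models exactly: qPCR replicates are the
ideal Ct shifted by `−log2(cn/2)` plus N(0, 0.1) cycles of noise (0.1 is a
typical well-run SYBR triplicate SD), CN 0 is a non-amplification sentinel;
ddPCR wells draw positives binomially at `1 − exp(−λ_ref · cn/2)` with
λ_ref = 0.8 copies/droplet over 15,000 droplets.

**What the generator does not emulate:** probe-level intensities and
segmentation noise (calls are emitted, not re-segmented, so breakpoints are
exact), linkage disequilibrium between risk loci, family structure,
ancestry-correlated CNV frequencies (covariates are independent of
genotype, so adjusted and unadjusted effects coincide in expectation —
real admixed cohorts are exactly the case where they do not), batch effects
between callers beyond a flat concordance rate, and assay-specific
artifacts such as droplet rain or qPCR inhibition.  Passing recovery tests
therefore demonstrates the correctness of the statistical machinery under
the stated models, not robustness to those real-data complications.

## Problem sizes and numerics

The shipped tests and the acceptance script run the cohort generator at
its default 23/110 scale, parameter recovery at n = 2,000 over 200
replicates, point estimation at n = 40,000, the permutation null over 600
permutations, the CNVR oracle over 1,000 random instances, and assay
recovery over 200 samples spanning CN 0–4 — sizes at which every
Monte-Carlo band used in a test is a 2.5–4 σ band around its target.
Logistic fits use statsmodels' Newton ML with a hand-rolled Firth fallback
(convergence 1e-8, max 100 iterations); Fisher tests and t-tests come from
scipy.  Ties in the replicate-QC outlier rule break toward the first
farthest replicate; degenerate inputs (all-carrier regions, empty
categories, zero-variance chromosomes, saturated wells) are flagged or
NA'd rather than raised mid-pipeline, except where an error is the only
sound outcome (zero reference concentration, infeasible OR/frequency
combinations).

## Known limitations

- Wald intervals throughout; profile-likelihood intervals are not
  implemented (Firth handles the separation cases where Wald is worst).
- The burden size regression treats summed bp as a plain covariate; at
  genome scale the per-bp odds ratio is necessarily ≈ 1.0 and is best read
  through its CI rather than its point value.
- The rare cascade's step-2/step-3 matching is same-type by default; panels
  without type annotations are not supported.
- qPCR efficiency correction and multi-well ddPCR merging are out of scope.
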