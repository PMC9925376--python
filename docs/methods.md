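# Methods

This note documents the models, rules and numerical choices implemented in
`pgxreg`, the free parameters of its synthetic-registry generator, and the
limits of what the synthetic experiments can show about real registry data.

## Phenotype classification

Phased alleles at rs4244285 (G>A) and rs12248560 (C>T) define the star
allele of each haplotype: A at rs4244285 → \*2 (non-functional); otherwise
T at rs12248560 → \*17 (increased function); otherwise \*1 (wild type). A
phased haplotype carrying both variant alleles does not correspond to any
star allele; because in phased input it indicates data corruption, it
raises an error naming the affected persons rather than being silently
dropped.

The unordered diplotype maps onto six phenotypes — PM (\*2/\*2), IM
(\*2/\*1), IM+ (\*2/\*17), EM (\*1/\*1), EM+ (\*1/\*17), UM (\*17/\*17) —
with an inverted activity score 1 (UM) … 6 (PM), so a higher score means
slower metabolism and higher expected drug exposure. Only the endpoints of
this score are externally pinned; the interior values follow the natural
rank order of the six levels and can be overridden. Because no recombinant
haplotypes exist, the partition obeys margin identities used as tests:
PM = A/A homozygotes, UM = T/T homozygotes, IM + IM+ = G/A heterozygotes,
EM+ + IM+ = C/T heterozygotes.

The expanded 10-level CYP2C scheme adds rs2860840 (C>T) and rs11188059
(G>A): a \*1-background haplotype with rs2860840-T and rs11188059-G is the
rapid CYP2C:TG haplotype; \*2 haplotypes are CYP2C19null; everything else
on a \*1 background is CYP2C:CG-or-TA. Three facts are pinned: rank 1 is
CYP2C:TG/CYP2C19\*17, rank 10 is null/null, and the CG-or-TA homozygote is
the reference. The interior ordering ships as an editable YAML table
(`data/defaults.yaml`), ordered by decreasing expected metabolic capacity;
users following a specific published supplement should supply that table.
The three-group collapse (lower-exposure / reference / higher-exposure) is
derived from rank relative to the reference.

## Treatment episodes

Dispenses of one person × drug group are scanned chronologically. A gap
strictly greater than `gap_days` (default 122; "4 months" at the 30.5
days/month convention also used for 183 = 6 months and 91 = 3 months)
starts a new episode — a gap of exactly 122 days continues the episode.
Each episode ends at its last dispense date plus the dispensed quantity in
DDD units rounded to whole days, capped at `tail_cap_days` (default 90).
The tail rule is applied uniformly to every episode, including the last
one before end of data — the simplest consistent reading; both parameters
are configurable. Quantities are modeled in DDD units (1 DDD ≈ one day of
supply); a converter maps milligram totals using the standard defined
daily doses (citalopram 20 mg, escitalopram 10 mg, sertraline 50 mg,
clomipramine 100 mg, amitriptyline 75 mg).

Because treatment may precede registry coverage, episodes starting on or
before coverage start + `gap_days` (2005-10-31 for coverage from
2005-07-01) are removed as potentially left-truncated.

Drug groups pool ATC substance codes (editable in the same YAML):
N06AB04+N06AB10 (citalopram/escitalopram), N06AB06 (sertraline),
N06AA09+N06AA04 (amitriptyline/clomipramine).

## Outcome derivations

All four derivations anchor at the episode start (first dispense) and
carry sex, study wave, age at start (days/365.25 from January 1 of the
birth year), phenotype columns, and three co-medication flags.

**Early non-persistence** (binary): event if no second dispense within 122
days of the first; the window is inclusive (a refill on day 122 counts),
mirroring the strict-exceed gap rule's complement; configurable. Episodes
of persons who died within the window are excluded. Sensitivity window:
183 days.

**Discontinuation** (survival): the event is the episode's last treatment
day; censoring at study end (2016-12-31), death, or 365 days — whichever
comes first, ties counting as censored. Variants: 60-day follow-up cap,
first episode per person only, 183-day gap, exclusion of episodes with
enzyme inducer/inhibitor co-medication.

**Switch** (survival, new-user design): index events are study-drug
dispenses in July 2006–December 2016 with no N06A dispense in the previous
365 days. The index dispense date itself anchors follow-up (calendar-month
segmentation is treated as a scanning device; binning survival times to
months would only coarsen them). A same-day dispense of a different N06A
substance makes the start ambiguous and excludes the index rather than
counting as an instantaneous event. The event is the first dispense of a
different 7-character N06A substance within 365 days; censoring at death,
study end, or 365 days.

**Treatment-emergent mania** (survival): first inpatient admission with
any diagnosis in F300–302, F308–309, F310–312, F316 (matched on 4-character
prefixes, so sub-codes match and F313–F315 do not) within 91 days of
episode start; censoring at 91 days or death. The admission date is the
event time (admission marks onset; diagnoses are recorded at discharge) —
switchable to the discharge date.

**Co-medication flags.** Monotherapy: no dispense of a *different* N06A
substance within the 122 days up to and including the start.
Mood-stabilizer use: for at least one of lithium (N05AN01), valproate
(N03AG01), lamotrigine (N03AX09) — per substance, not pooled — ≥2
dispenses in the last 365 days with ≥1 in the last 122. Inducer/inhibitor
use: any dispense of carbamazepine, phenobarbital, phenytoin, omeprazole,
esomeprazole, lansoprazole, pantoprazole, fluoxetine or fluvoxamine in the
183 days up to the start; the direction of this window is not externally
pinned, so the look-back reading (consistent with the other two flags) is
the default and the window is a parameter.

## Inference

The binary outcome uses GEE logistic regression with an exchangeable
working correlation over each person's episodes and sandwich standard
errors (population-averaged odds ratios). The moment estimate of the
common correlation is constrained to [0, 0.95]: values below −1/(k−1)
make a size-k cluster's working covariance non-positive-definite and the
IRLS update diverges, while the sandwich covariance remains valid under a
misspecified working structure. Diverging coefficients (|β| > 15) are
reported as separation errors.

Survival outcomes use Cox regression with robust standard errors
clustered on person. Ties are handled by the Efron method — registry dates
are day-resolved, so ties are common — making results reproducible
bit-for-bit. Exposure codings: the six phenotypes with EM as reference;
the PM/IM/IM+ vs EM vs EM+/UM collapse for sparse events; the activity
score as a continuous trend (one HR per step); the 10-level CYP2C rank as
a trend; and the CYP2C three-group collapse. Design matrices are built
explicitly (treatment-coded dummies) so the GEE and Cox layers see
identical codings. When a study wave has no events its coefficient is
inestimable, so the wave covariate is dropped with a logged warning.
Constant design columns raise an identifiability error instead of being
passed to the optimizer. No multiple-testing correction is applied;
p-values are reported raw and should be read accordingly.

The nested interaction test is a joint Wald chi-square on the
monotherapy × exposure block using the full model's robust covariance,
with degrees of freedom equal to the block size; identical models return
p = 1 (nothing to test) and non-nested models are an error.

Sample-size planning uses the Schoenfeld events formula
E = (z₁₋α/₂ + z_power)² / (p(1−p)(ln HR)²) with n = ⌈E / event rate⌉. For
HR 1.2 and 1.5 (p = 0.036, event rate 0.5, 80% power, α = 0.05) it yields
13,608 and 2,752 — agreeing with reference evaluations of the same design
to within 0.25%, the residual being rounding of the normal quantiles.

## Synthetic registry generator

The generator emulates the data structure the analysis assumes, not any
particular country's registry. Defaults:

| parameter | default | meaning |
|---|---|---|
| haplotype frequencies | \*1 0.663, \*2 0.147, \*17 0.190 | common European functional alleles |
| p(TG \| \*1) | 0.30 | CYP2C:TG share of wild-type haplotypes (free choice) |
| study window | 2005-07-01 – 2016-12-31 | registry coverage |
| initiation rate | 0.035/0.027/0.014 per person-year | chosen so ever-use over the window ≈ 23%/27%/8% per drug group |
| refill interval | 85 ± 20 days | ≤3-month supplies refilled after ~⅔ consumption |
| dropout per refill | 0.15 | geometric stream length, mean ≈ 6.7 dispenses |
| dispense size | 90 ± 15 DDD | ~3 months of supply |
| baseline mania hazard | 1.66·10⁻⁴ /day | ≈1.5% 91-day event probability at EM |
| per-step log HR | 0 (null) | the tested effect; ln 1.3 / ln 1.46 in recovery runs |
| background mania rate | 0.002 /person-year | phenotype-independent admissions, on by default so the 91-day window's specificity is testable |
| death rate | 0.006 /person-year | ≈7% deaths over the window |

Each person × drug initiates at most once (probability 1 − e^(−rate·years)),
with the first dispense uniform over the study window; refill intervals
are truncated normal (≥1 day); no dispense is ever dated after death.
Mania event times are exponential at h₀·exp(β·(score−3)) over the first 91
days of each episode, truncated at death. Dates are integer day offsets
internally and ISO-8601 in all CSVs; each output table has its own
generator seeded from the master seed, so adding a table never perturbs
the others and equal configurations give byte-identical files.

Refill-interval and dropout distributions are free parameters, not
registry estimates — no public source reports them. The generator omits
outpatient care, genotyping error, imputation uncertainty, realistic
demography, dose changes and stockpiling. Passing recovery tests therefore
show that the pipeline's rules and estimators are mutually consistent and
unbiased under the assumed generating model — not that real dispense
streams satisfy those assumptions.

## Recovery experiments and problem sizes

The headline simulation (also run by `scripts/acceptance.py`) simulates
200 replicate single-arm cohorts of 3,800 subjects — ≈4,000 episodes after
left truncation, ≈70 events at a ~1.7% marginal event rate — per effect
size (true step HR 1.30 and 1.46), runs the full pipeline per replicate,
and averages the estimated trend HR. With ≈70 events the per-replicate
standard error of the log HR is ≈0.10, so the mean over 200 replicates
estimates the truth to ≈0.01 and small-sample bias (Jensen's inequality on
the exponentiated mean) stays below 0.01. Type-I error of the GEE and Cox
trend tests is checked at 1,000 null replicates against a 5% ± 1.5
percentage-point band.

## Known limitations

* The interior CYP2C rank ordering and the two non-reference collapse
  groups are configurable stand-ins, not a reproduction of any published
  supplement.
* Whether episodes ending exactly at a censoring date count as events is
  resolved as "censored" (strict precedence); real analyses may differ.
* GEE small-sample inflation of the sandwich variance is not corrected;
  with hundreds of clusters the type-I error is near nominal, with tens it
  will not be.
* The switch outcome treats any different N06A substance as a switch, with
  no notion of augmentation vs replacement.
* Events on the episode start day get follow-up time 0; the Cox partial
  likelihood handles them, but analysts preferring a half-day offset must
  apply it upstream.
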