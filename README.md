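# pgxreg

Pharmacogenetic analysis of antidepressant use in prescription registries:
from phased **CYP2C19** genotypes and pharmacy dispensation records to
treatment-outcome estimates.

Antidepressants such as citalopram, escitalopram, sertraline, amitriptyline
and clomipramine are metabolized by the CYP2C19 enzyme. Two common
functional polymorphisms — rs4244285 G>A (the non-functional \*2 allele) and
rs12248560 C>T (the increased-function \*17 allele) — classify patients into
six metabolic phenotypes, from ultra-rapid (UM, \*17/\*17) to poor
metabolizers (PM, \*2/\*2). In bipolar disorder, slower metabolism means
higher drug exposure and plausibly a higher risk of treatment-emergent
mania. `pgxreg` implements the full registry-analysis chain needed to test
such hypotheses, for biostatisticians and pharmacoepidemiologists working
with dispensation and inpatient data:

* **Phenotyping** (`pgxreg.phenotypes`) — phased SNPs → star alleles →
  six-level phenotype with an inverted activity score (UM=1 … PM=6), plus
  the expanded 10-level CYP2C diplotype scheme (rs2860840/rs11188059,
  CYP2C:TG haplotype).
* **Treatment episodes** (`pgxreg.episodes`) — a refill gap > 122 days
  (4 months) splits an episode; each episode ends at its last dispense plus
  its dispensed days of supply (DDD count) capped at 90 days; episodes
  starting within one gap of registry start are left-truncated and dropped.
* **Outcomes** (`pgxreg.outcomes`) — early non-persistence (no refill
  within 4 months), discontinuation within 1 year, switch to another
  antidepressant under a new-user design (1-year washout), and inpatient
  mania (ICD-10 F300–302, F308–309, F310–312, F316) within 3 months of
  treatment start — each with demographics, activity score, and
  co-medication flags.
* **Inference** (`pgxreg.models`) — GEE logistic regression (exchangeable
  working correlation) for the binary outcome; Cox regression with
  cluster-robust standard errors (Efron ties) for the survival outcomes; a
  continuous activity-score trend HR; nested Wald interaction tests;
  Kaplan–Meier medians; and the Schoenfeld events formula

      E = (z₁₋α/₂ + z_power)² / (p(1−p)·(ln HR)²),  n = ⌈E / event rate⌉

  for two-group Cox sample-size planning.
* **Synthetic registry** (`pgxreg.simulate`) — real registries are not
  redistributable, so a generator emulates their structure: haplotypes at
  realistic frequencies, refill streams with dropout, co-medication,
  deaths, and rare mania admissions whose hazard follows
  `h₀·exp(β·(score−3))`. Every stage of the pipeline is testable end to end
  without any data access.

## Worked example

```python
from pgxreg.models import ModelSpec, trend_cox
from pgxreg.pipeline import RunConfig, StudyData, make_fixture

_, tables = make_fixture("effect", seed=7)     # true per-step mania HR 1.3
data = StudyData(tables, RunConfig(input_dir="synthetic"))
recs = data.records("sertraline", "mania")
res = trend_cox(recs, ModelSpec(outcome="mania", coding="activity_score"))
print(res.summary.loc["activity_score"])
```

prints (seed 7):

```
per-step HR 1.24 (95% CI 1.05–1.47, p=0.011); 90 events in 4063 episodes from 3530 persons
```

i.e. each activity-score step toward slower metabolism multiplies the
91-day mania hazard by ≈1.24 in this replicate (truth 1.3; single-cohort
estimates scatter around the truth — see the recovery experiment below).
The `examples/` directory has one short script per capability, and the
`pgxreg` command exposes the same stages from the shell
(`pgxreg simulate|phenotype|episodes|outcomes|analyze|power|run`).

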