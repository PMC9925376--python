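# Editable defaults: ATC code sets, DDD table, ICD-10 mania set, CYP2C rank table.
# Substances are what the analysis names; the WHO ATC codes are recorded here so
# they can be overridden without touching code.

drug_groups:
  escitalopram_citalopram: [N06AB10, N06AB04]
  sertraline: [N06AB06]
  amitriptyline_clomipramine: [N06AA09, N06AA04]

# WHO defined daily dose, mg/day
ddd_mg:
  citalopram: 20
  escitalopram: 10
  sertraline: 50
  clomipramine: 100
  amitriptyline: 75

atc_substance:
  citalopram: N06AB04
  escitalopram: N06AB10
  sertraline: N06AB06
  amitriptyline: N06AA09
  clomipramine: N06AA04

# Inpatient mania / mixed-episode diagnosis set (dot-free Swedish ICD-10 style);
# longer codes match on these 4-character prefixes.
mania_icd10_prefixes: [F300, F301, F302, F308, F309, F310, F311, F312, F316]

mood_stabilizer_atc: [N05AN01, N03AG01, N03AX09]   # lithium, valproate, lamotrigine
inducer_atc: [N03AF01, N03AA02, N03AB02]            # carbamazepine, phenobarbital, phenytoin
inhibitor_atc: [A02BC01, A02BC05, A02BC03, A02BC02, N06AB03, N06AB08]
# omeprazole, esomeprazole, lansoprazole, pantoprazole, fluoxetine, fluvoxamine

# 10-level CYP2C diplotype ranking (1 = fastest expected metabolism, 10 = slowest).
# Endpoints and the reference diplotype are fixed by the phenotyping scheme; the
# interior ordering is an editable choice by decreasing expected metabolic
# capacity and may be replaced wholesale by supplying another table.
cyp2c_rank_table:
  - {haplotypes: ["CYP2C:TG", "CYP2C19*17"], rank: 1}
  - {haplotypes: ["CYP2C19*17", "CYP2C19*17"], rank: 2}
  - {haplotypes: ["CYP2C:TG", "CYP2C:TG"], rank: 3}
  - {haplotypes: ["CYP2C19*17", "CYP2C:CG-or-TA"], rank: 4}
  - {haplotypes: ["CYP2C:TG", "CYP2C:CG-or-TA"], rank: 5}
  - {haplotypes: ["CYP2C:CG-or-TA", "CYP2C:CG-or-TA"], rank: 6}
  - {haplotypes: ["CYP2C19*17", "CYP2C19null"], rank: 7}
  - {haplotypes: ["CYP2C:TG", "CYP2C19null"], rank: 8}
  - {haplotypes: ["CYP2C:CG-or-TA", "CYP2C19null"], rank: 9}
  - {haplotypes: ["CYP2C19null", "CYP2C19null"], rank: 10}
reference_diplotype: ["CYP2C:CG-or-TA", "CYP2C:CG-or-TA"]
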