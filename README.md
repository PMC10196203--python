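# pgxbs — the Pharmacogenomics Benefit Score consult engine

Patients are referred to clinical pharmacology with medication-related
problems — unexpected poor efficacy or intolerable adverse effects at
standard doses — and the question "is pharmacogenomics the answer?".
`pgxbs` implements the structured reactive-PGx consult that answers it
with a single patient-centered number, the **Pharmacogenomics Benefit
Score (PGxBS)**: a measure of congruency between the patient's
medication-related problems and their genotype-predicted phenotypes.

It is written for clinical pharmacologists, PGx pharmacists and
decision-support developers who want the consult logic as a reusable,
testable engine rather than a spreadsheet.

## The score

For each medication *i* in the patient's current and past history, the
consult asks four binary questions:

- *g*ᵢ ∈ {0,1} — is a guideline (CPIC level A or A/B evidence) available?
- *a*ᵢ ∈ {0,1} — did the patient have an adequate therapeutic trial?
  (underdosing or short duration ⇒ 0)
- *o*ᵢ ∈ {0,1} — was there a medication-related problem (unexpected poor
  efficacy or intolerable adverse effects)?
- *c*ᵢ ∈ {+1,−1} — is the problem **congruent** with the genotype-predicted
  phenotype of the drug's guideline gene(s)? Adjudicated only when
  *g*ᵢ·*a*ᵢ·*o*ᵢ = 1.

Then

  PGxBS = Σᵢ gᵢ aᵢ oᵢ cᵢ

with the interpretation rule: **PGxBS ≥ 1** → a possible pharmacogenomic
contribution to the problems; **PGxBS ≤ 0** → pharmacogenomics is less
likely to be important for this patient. For an untested patient, reactive
PGx testing is recommended when two or more medications carry guidelines.

Congruency is mechanistic, driven by the gene's role for the drug:

| gene role | PM/IM (deficient) | NM | RM/UM (excessive) |
|---|---|---|---|
| activating (prodrug, e.g. codeine→morphine via CYP2D6) | poor efficacy | — | adverse effects |
| inactivating (clears active drug) | adverse effects | — | poor efficacy |

HLA risk-allele carriers predict severe adverse reactions (`immune_risk`
role); a non-responsive drug-target genotype predicts poor efficacy
(`target` role). A phenotype that predicts no problem (e.g. a normal
metabolizer) makes an observed problem incongruent (−1); an indeterminate
or untested genotype leaves the row unscored.

Metabolizer phenotypes come from star-allele diplotypes via per-gene
activity scores and bins (CYP2D6: 0 → PM, ≤1 → IM, ≤2.25 → NM, >2.25 → UM)
or a categorical function-class translation, all stored as editable TSV
tables in a knowledge-base directory; a curated synthetic snapshot covering
12 drugs and 8 genes ships with the package. Phenoconversion by inhibiting
or inducing co-medications is available behind a flag.

## Worked example

The shipped example case is a 42-year-old referred for poor responses to
psychotropics and pain killers, with adequate trials of codeine and
clomipramine (both poor efficacy), genotyped CYP2D6 `*1/*1x2` and CYP2C19
`*1/*1`:

```bash
pgxbs score \
  --case src/pgxbs/data/examples/worked_case.yaml \
  --genotypes src/pgxbs/data/examples/worked_case.genotypes.tsv \
  --out ledger.csv
cat ledger.csv
```

```
"medication","guideline","adequate_trial","outcome","congruency","rationale"
"codeine",1,1,1,-1,"CYP2D6 UM (activity 3) with activating role predicts adverse_effects; observed poor_efficacy → incongruent (-1)"
"clomipramine",1,1,1,1,"CYP2D6 UM (activity 3) with inactivating role predicts poor_efficacy; CYP2C19 NM with inactivating role predicts no problem; observed poor_efficacy → congruent (+1)"
"PGxBS",0
"interpretation","pgx_less_likely"
"testing_recommended","false"
"n_guideline_meds",2
```

Reading the ledger: the patient is a CYP2D6 ultrarapid metabolizer
(activity score 1 + 2 = 3). For codeine, a prodrug activated by CYP2D6,
ultrarapid activation predicts toxicity — it cannot explain the poor
analgesic response, so the row scores −1. For clomipramine, cleared by
CYP2D6 and CYP2C19, ultrarapid clearance predicts underexposure and poor
efficacy, matching the observed lack of improvement: +1. The PGxBS is
−1 + 1 = 0, so no known genetic cause for the problems was found. Run
with `--format markdown` or `--format json` for a consult-note section or
the full structured result with provenance.

Other entry points: `pgxbs recommend` (reactive-testing recommendation for
an untested patient), `pgxbs validate-kb` (check a knowledge-base
directory), `pgxbs simulate` (synthetic cohorts with planted congruency
truth), and the library API (`pgxbs.run_consult`, `pgxbs.assess_congruency`,
`pgxbs.predict_phenotype`, …).

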