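# Methods

## The consult model

`pgxbs` models the reactive pharmacogenomics consult as a per-medication
pipeline of binary gates followed by a signed congruency adjudication.
Medications are taken in input order, current and past alike (status is
display-only), with duplicate entries collapsed to the first by normalized
name. A row contributes to the score only when all three gates pass:
guideline available (CPIC level A or A/B evidence in the knowledge base),
adequate therapeutic trial (a clinician-supplied judgment; "no" and
"unsure" both gate the row out), and a medication-related problem
(exactly one of unexpected poor efficacy or intolerable adverse effects;
a good or unknown outcome means there is no problem for genetics to
explain, so the row is left unscored rather than counted against the
patient).

Congruency compares the observed problem with the set of problems the
patient's phenotypes mechanistically predict for the drug, using the gene
role recorded on each drug–gene rule:

| role | deficient (PM/IM) | normal (NM) | excessive (RM/UM) |
|---|---|---|---|
| activating | poor efficacy | ∅ | adverse effects |
| inactivating | adverse effects | ∅ | poor efficacy |

plus, for carrier-system genes: `immune_risk` carriers predict adverse
effects and `target` non-responsive genotypes predict poor efficacy;
non-carriers and responders predict nothing. Multi-gene drugs take the
union over their rules (any-gene disjunction — one congruent gene
suffices, as in the clomipramine example where CYP2D6 UM carries the call
despite CYP2C19 NM). The row scores +1 when the observed problem is in
the union and −1 otherwise; in particular a normal metabolizer predicts
no problem, so an NM-only drug with a problem scores −1 — the genotype
fails to explain the problem.

Three deliberate asymmetries:

- **Indeterminate is not incongruent.** An unknown allele, untested gene
  or unparseable call contributes an empty prediction set; if *every*
  relevant gene is indeterminate the row is unscored and flagged, because
  −1 asserts "the genotype contradicts the problem", which an unknown
  genotype cannot do.
- **Drug-specific risk alleles.** HLA rules carry the allele(s) relevant
  to that drug (allopurinol keys on B\*58:01, abacavir on B\*57:01), so a
  carrier of one is not spuriously congruent with the other. This is an
  extension of the plain gene-level carrier call, made because a single
  HLA-B gene serves several drugs with disjoint risk alleles.
- **Dual problems are out of scope**: one outcome is chosen per
  medication, and repeated problems with the same drug score once.

The PGxBS is the sum of the ±1 rows; scores ≥ 1 read as a possible
pharmacogenomic contribution, 0 and below as pharmacogenomics being less
likely to matter. For a patient with no genotype results, reactive
testing is recommended when at least two distinct medications pass the
guideline gate.

## Phenotype translation

Metabolizer genes translate star-allele diplotypes one of two ways,
declared per gene in the knowledge base:

- **Activity score** (CYP2D6, CYP2C9): the diplotype score is the sum of
  the two allele activity values (0, 0.25, 0.5 or 1, with copy-number
  alleles such as `*1x2` carrying integer multiples); the score is looked
  up in per-gene bins stored as data. The shipped CYP2D6 bins follow the
  consensus convention — 0 → PM, (0, 1] → IM, (1, 2.25] → NM,
  > 2.25 → UM — stored as closed intervals over the attainable 0.25-step
  lattice so that bins provably partition every attainable diplotype
  score (validated at load time by enumeration).
- **Categorical** (CYP2C19, TPMT, NUDT15, SLCO1B1): a fixed lookup on the
  sorted pair of allele function classes (e.g. normal+increased → RM,
  no_function+no_function → PM). This mirrors the field's practice for
  genes whose increased-function alleles have no defined activity value.
  SLCO1B1, a transporter, is represented on the same metabolizer scale
  (poor/decreased/normal function ↦ PM/IM/NM) as an analogue.

Carrier-system genes (HLA-B; CFTR as the target-gene example) are called
positive when any risk-classed allele is present. The CFTR encoding —
risk alleles mark the *non-responsive* genotype for the targeted drug —
is a synthetic simplification adopted so the fixture exercises the target
role; it is not a clinical CFTR translation table.

Unknown alleles or genes yield an explicit `indeterminate` call, never a
silent normal-metabolizer default.

## Phenoconversion

Co-medications that inhibit or induce an enzyme can make the functional
phenotype differ from the genotype-predicted one. For activity-score
genes the adjusted score is the base score times one multiplier per
matching perpetrator (defaults: strong inhibitor ×0, moderate inhibitor
×0.5, moderate inducer ×1.5, strong inducer ×2 — editable data in
`phenoconversion.tsv`), re-binned through the gene's own bins (an
adjusted score falling in a lattice gap rounds down; the label is capped
at the top bin). Categorical genes, having no score, shift along
PM < IM < NM < RM < UM: a strong inhibitor forces PM, a moderate
inhibitor steps down one label, moderate/strong inducers step up one/two.
Inhibitors never raise and inducers never lower the adjusted activity;
the product form makes the result independent of perpetrator order.

Whether congruency should use the raw or the phenoconverted phenotype is
genuinely open; the engine computes both and scores with the raw
phenotype by default (`phenoconversion_enabled=False`), surfacing a
differing phenoconverted label in the rationale so the consulting
clinician sees it. The perpetrator pool for a given drug is the patient's
co-medication list plus their other *current* medications.

## The knowledge base

The shipped knowledge base is a curated synthetic snapshot — 8 genes, 16
drug–gene rules spanning all four gene roles, 12 guideline drugs — chosen
to cover every mechanism the score distinguishes (prodrug activation,
active-drug clearance, multi-gene antidepressants, thiopurine toxicity,
three HLA-mediated reactions, a drug-target pair) while staying small
enough to enumerate exhaustively in tests. Evidence levels reflect the
2023-era consensus but the snapshot is versioned and makes no claim of
currency; it is data, and a site can point the engine at its own
directory. A deliberately sub-threshold rule (risperidone×CYP2D6, level
B) exercises the evidence gate. Drug-name matching is exact after
normalization (case-fold, trim, collapse whitespace); synonyms are extra
rows, not fuzzy matches, to keep the consult deterministic.

## Synthetic cohorts

The generator draws genotypes from per-gene allele frequencies (round
synthetic numbers, not population estimates), assembles 2–5 medications
per case from the guideline drugs (plus occasional non-guideline
distractors), and *plants* each scoreable medication's outcome: congruent
with the drawn phenotype with probability `congruent_fraction` (default
0.5), incongruent otherwise. Planting uses its own literal copy of the
direction table, so engine-vs-truth agreement is a genuine
two-implementation check of the congruency logic. When a drawn phenotype
predicts no problem, congruent planting is impossible and the row is
planted incongruent (and vice versa when a multi-gene drug predicts both
problems); truth is always recorded as planted. Default nuisance rates:
20% inadequate trials, 15% problem-free medications, configurable
fraction of untested patients. Generation is reproducible from the seed.

What passing the recovery test shows: the engine and generator agree
exactly on the congruency table, the gates and the summation over
hundreds of random cases. What it does not show: anything about real
referral streams — real cases involve recall bias, dual problems, dose
nuance and guideline drift that the generator does not model.

## Numerical and design choices

- Scores are exact integers; activity arithmetic is on 0.25-step
  rationals represented as floats, safe because all values are dyadic.
- Test and acceptance cohort sizes (500 cases across five seeds; 10,000
  draws for the frequency check) are the package's chosen balance of
  coverage and sub-second feedback.
- The ledger's canonical CSV form is byte-stable across runs (fixed
  dialect: comma-separated, quoted strings, LF, UTF-8); timestamps live
  only in the JSON provenance block.
- Errors are graded: missing knowledge-base tables and invariant
  violations are fatal with the offending file/row named; unknown drugs
  answer "no guideline" (the consult's no/unsure convention); unknown
  genes/alleles degrade to indeterminate with a warning.

## Limitations

The score is a structured summary of clinical judgments, not a validated
decision instrument; trial adequacy and outcomes are supplied by the
clinician, not inferred. The engine does not call star alleles from
sequence data, does not retrieve live guidelines, and does not produce
dosing recommendations. The congruency direction table is deliberately
coarse (binary outcomes, five metabolizer states); nuances such as
substrate-specific activity-score cut-offs or partial inhibition are out
of scope.
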