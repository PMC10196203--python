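"""The structured pharmacogenomics consult and the PGx Benefit Score.

The consult walks six steps per patient:

1. list current and past medications;
2. per medication, is a guideline (CPIC level A / A-B) available? (1/0);
3. did the patient have an adequate therapeutic trial? (1 = yes, 0 = no or
   unsure — underdosing and short durations score 0);
4. was there a medication-related problem — unexpected poor efficacy or
   intolerable adverse effects? (1/0; medications failing step 3 are
   ignored);
5. is the problem congruent with the genotype-predicted phenotype for the
   drug's guideline gene(s)? (+1 congruent, −1 incongruent);
6. sum the ±1 scores into the PGxBS. A score ≥ 1 indicates a possible
   pharmacogenomic contribution to the problems; 0 or negative scores mean
   pharmacogenomics is less likely to be important for the patient.

Congruency (step 5) is adjudicated mechanistically from the gene's role for
the drug: an ultrarapid metabolizer of a prodrug-activating enzyme predicts
toxicity, of a clearing enzyme predicts underexposure and poor efficacy;
an HLA risk-allele carrier predicts a severe adverse reaction; a
non-responsive drug-target genotype predicts poor efficacy. A normal
metabolizer predicts neither problem, so an observed problem is incongruent
with it. A medication whose relevant genotypes are all indeterminate (or
untested) is left unscored: an unknown genotype can neither support nor
contradict the problem.
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .knowledge_base import (
    DrugGeneRule,
    GeneRole,
    KnowledgeBase,
    Phenotype,
    PhenotypeCall,
    PhenotypeSystem,
    guideline_available,
    normalize_drug_name,
    predict_phenotype,
)
from .phenoconversion import apply_phenoconversion


class MedicationStatus(str, enum.Enum):
    CURRENT = "current"
    PAST = "past"


class TrialAdequacy(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNSURE = "unsure"


class Outcome(str, enum.Enum):
    POOR_EFFICACY = "poor_efficacy"
    ADVERSE_EFFECTS = "adverse_effects"
    NONE_OR_UNKNOWN = "none_or_unknown"


class Congruency(str, enum.Enum):
    CONGRUENT = "congruent"        # +1
    INCONGRUENT = "incongruent"    # -1
    NOT_SCORED = "not_scored"      # 0

    @property
    def score(self) -> int:
        return {"congruent": 1, "incongruent": -1, "not_scored": 0}[self.value]


class Interpretation(str, enum.Enum):
    POSSIBLE_PGX_CONTRIBUTION = "possible_pgx_contribution"
    PGX_LESS_LIKELY = "pgx_less_likely"


class MedicationRecord(BaseModel):
    """One current or past medication with the clinician's structured
    judgments on trial adequacy and therapeutic outcome."""

    drug_name: str
    status: MedicationStatus = MedicationStatus.CURRENT
    dose_text: str = ""
    duration_text: str = ""
    trial_adequate: TrialAdequacy = TrialAdequacy.UNSURE
    outcome: Outcome = Outcome.NONE_OR_UNKNOWN

    @field_validator("drug_name")
    @classmethod
    def _normalized(cls, v: str) -> str:
        return normalize_drug_name(v)

    @field_validator("trial_adequate", mode="before")
    @classmethod
    def _coerce_bool(cls, v):
        # YAML 1.1 parses bare yes/no as booleans
        if isinstance(v, bool):
            return "yes" if v else "no"
        return v


class GenotypeRecord(BaseModel):
    """One row of a genotype report: gene plus diplotype or allele list."""

    gene: str
    diplotype: str


class PatientCase(BaseModel):
    """A referral: demographics stub, medication history, co-medications
    and (optionally) genotype results embedded in the case."""

    patient: dict = Field(default_factory=dict)
    medications: list[MedicationRecord] = Field(default_factory=list)
    comedications: list[str] = Field(default_factory=list)
    genotypes: list[GenotypeRecord] = Field(default_factory=list)

    @field_validator("comedications")
    @classmethod
    def _normalized(cls, v: list[str]) -> list[str]:
        return [normalize_drug_name(d) for d in v]


class LedgerRow(BaseModel):
    """One medication's step 2–5 answers in the consult ledger."""

    drug_name: str
    status: MedicationStatus = MedicationStatus.CURRENT
    guideline_flag: int = Field(ge=0, le=1)
    adequacy_flag: int = Field(ge=0, le=1)
    outcome_flag: int = Field(ge=0, le=1)
    congruency: Congruency
    rationale: str

    @property
    def score(self) -> int:
        return self.congruency.score


class ConsultResult(BaseModel):
    """Full consult outcome: the ledger, the PGxBS and its interpretation."""

    rows: list[LedgerRow]
    pgxbs: int
    interpretation: Interpretation
    testing_recommended: bool
    n_guideline_meds: int
    genotyped: bool = True
    phenoconversion_enabled: bool = False


# ---------------------------------------------------------------------------
# steps 3 and 4
# ---------------------------------------------------------------------------

def assess_adequacy(med: MedicationRecord) -> int:
    """Step 3: 1 for an adequate therapeutic trial, 0 for no/unsure."""
    return 1 if med.trial_adequate is TrialAdequacy.YES else 0


def assess_outcome(med: MedicationRecord) -> int:
    """Step 4: 1 iff a medication-related problem (poor efficacy or
    adverse effects) occurred; a good or unknown outcome scores 0."""
    return 1 if med.outcome in (Outcome.POOR_EFFICACY, Outcome.ADVERSE_EFFECTS) else 0


# ---------------------------------------------------------------------------
# step 5: congruency
# ---------------------------------------------------------------------------

_DEFICIENT = (Phenotype.PM, Phenotype.IM)
_EXCESSIVE = (Phenotype.UM, Phenotype.RM)


def expected_outcomes(rule: DrugGeneRule, phenotype: PhenotypeCall) -> set[Outcome]:
    """Outcomes the phenotype mechanistically predicts for this drug–gene
    rule.

    Direction table by gene role: for a prodrug-activating enzyme, deficient
    metabolizers (PM/IM) fail to form the active moiety (poor efficacy)
    while excessive metabolizers (RM/UM) overshoot it (adverse effects);
    for a clearing enzyme the directions invert. HLA risk carriers predict
    severe adverse reactions; a non-responsive target genotype predicts
    poor efficacy. Normal metabolizers, non-carriers and indeterminate
    calls predict no problem.
    """
    if rule.gene_symbol != phenotype.gene_symbol:
        raise ValueError(
            f"rule is for {rule.gene_symbol}, phenotype call is for "
            f"{phenotype.gene_symbol}"
        )
    p = phenotype.phenotype
    if p is Phenotype.INDETERMINATE:
        return set()

    if rule.gene_role is GeneRole.ACTIVATING:
        if p in _DEFICIENT:
            return {Outcome.POOR_EFFICACY}
        if p in _EXCESSIVE:
            return {Outcome.ADVERSE_EFFECTS}
        return set()
    if rule.gene_role is GeneRole.INACTIVATING:
        if p in _DEFICIENT:
            return {Outcome.ADVERSE_EFFECTS}
        if p in _EXCESSIVE:
            return {Outcome.POOR_EFFICACY}
        return set()

    # carrier-system roles; honour drug-specific risk alleles when given
    if p is Phenotype.POSITIVE:
        if rule.risk_alleles and not (
            set(rule.risk_alleles) & set(phenotype.risk_alleles_present)
        ):
            return set()
        if rule.gene_role is GeneRole.IMMUNE_RISK:
            return {Outcome.ADVERSE_EFFECTS}
        return {Outcome.POOR_EFFICACY}  # target: non-responsive genotype
    return set()


def assess_congruency(
    drug: str,
    phenotypes: Sequence[PhenotypeCall],
    observed: Outcome,
    kb: KnowledgeBase,
) -> int:
    """Step 5: +1 if any of the drug's guideline genes predicts the observed
    problem, else −1.

    Multi-gene drugs use an any-gene disjunction: one congruent gene
    suffices. Requires a guideline drug, an actual problem outcome, and at
    least one determinate phenotype among the drug's genes.
    """
    _, rules = guideline_available(drug, kb)
    if not rules:
        raise ValueError(f"{drug!r} has no guideline rule; congruency is undefined")
    if observed not in (Outcome.POOR_EFFICACY, Outcome.ADVERSE_EFFECTS):
        raise ValueError("congruency requires an observed medication-related problem")

    by_gene = {p.gene_symbol: p for p in phenotypes}
    calls = [by_gene.get(r.gene_symbol) for r in rules]
    if all(c is None or c.indeterminate for c in calls):
        raise ValueError(
            f"{drug!r}: every relevant genotype is indeterminate or missing; "
            "congruency cannot be adjudicated"
        )
    union: set[Outcome] = set()
    for rule, call in zip(rules, calls):
        if call is not None:
            union |= expected_outcomes(rule, call)
    return 1 if observed in union else -1


# ---------------------------------------------------------------------------
# step 6 and the full consult
# ---------------------------------------------------------------------------

def interpret(pgxbs: int) -> Interpretation:
    """Step 6 threshold: scores ≥ 1 suggest a possible pharmacogenomic
    contribution; 0 and negative scores mean it is less likely."""
    return (
        Interpretation.POSSIBLE_PGX_CONTRIBUTION
        if pgxbs >= 1
        else Interpretation.PGX_LESS_LIKELY
    )


def recommend_testing(case: PatientCase, kb: KnowledgeBase) -> tuple[bool, int]:
    """Reactive-testing recommendation for an untested patient.

    Testing is recommended when two or more distinct medications carry
    guidelines — the suggested cut-off for reactive testing. Returns
    ``(recommended, n_guideline_meds)``.
    """
    seen: set[str] = set()
    n = 0
    for med in case.medications:
        if med.drug_name in seen:
            continue
        seen.add(med.drug_name)
        flag, _ = guideline_available(med.drug_name, kb)
        n += flag
    return n >= 2, n


def _phenotype_label_text(call: PhenotypeCall) -> str:
    if call.activity_score is not None:
        return f"{call.gene_symbol} {call.phenotype.value} (activity {call.activity_score:g})"
    return f"{call.gene_symbol} {call.phenotype.value}"


def _row_rationale(
    rules: list[DrugGeneRule],
    calls: dict[str, PhenotypeCall],
    observed: Outcome,
    score: int,
    shadow: dict[str, PhenotypeCall],
) -> str:
    parts = []
    for rule in rules:
        call = calls.get(rule.gene_symbol)
        if call is None or call.indeterminate:
            parts.append(f"{rule.gene_symbol} indeterminate")
            continue
        expected = expected_outcomes(rule, call)
        exp_text = (
            " or ".join(sorted(o.value for o in expected)) if expected else "no problem"
        )
        text = (
            f"{_phenotype_label_text(call)} with {rule.gene_role.value} role "
            f"predicts {exp_text}"
        )
        alt = shadow.get(rule.gene_symbol)
        if alt is not None and alt.phenotype is not call.phenotype:
            kind = "phenoconverted" if alt.phenoconverted else "genotype-only"
            text += f" ({kind} phenotype would be {alt.phenotype.value})"
        parts.append(text)
    verdict = "congruent" if score > 0 else "incongruent"
    return f"{'; '.join(parts)}; observed {observed.value} → {verdict} ({score:+d})"


def run_consult(
    case: PatientCase,
    genotypes: Optional[Sequence[GenotypeRecord]] = None,
    kb: Optional[KnowledgeBase] = None,
    phenoconversion_enabled: bool = False,
) -> ConsultResult:
    """Run the full six-step consult and return the ledger and PGxBS.

    One ledger row is emitted per distinct medication in input order
    (duplicate entries collapse to the first). Rows failing any of steps
    2–4, or whose relevant genotypes are all indeterminate, are left
    unscored. ``genotypes`` overrides any genotype block embedded in the
    case; an empty genotype set marks the patient as untested and triggers
    the reactive-testing recommendation.

    With ``phenoconversion_enabled``, congruency for each medication uses
    the phenotype adjusted for enzyme inhibitors/inducers among the
    patient's co-medications and other current medications; otherwise the
    raw genotype-predicted phenotype is used and any differing
    phenoconverted phenotype is surfaced in the rationale.
    """
    if kb is None:
        raise ValueError("a knowledge base is required")
    genotype_records = list(genotypes) if genotypes is not None else list(case.genotypes)
    genotyped = bool(genotype_records)

    base_calls: dict[str, PhenotypeCall] = {}
    for rec in genotype_records:
        base_calls[rec.gene] = predict_phenotype(rec.gene, rec.diplotype, kb)

    def calls_for_drug(drug: str) -> tuple[dict[str, PhenotypeCall], dict[str, PhenotypeCall]]:
        """(calls used for scoring, shadow calls for the rationale)."""
        comeds = [
            m.drug_name
            for m in case.medications
            if m.status is MedicationStatus.CURRENT and m.drug_name != drug
        ] + [c for c in case.comedications if c != drug]
        used: dict[str, PhenotypeCall] = {}
        shadow: dict[str, PhenotypeCall] = {}
        for gene, call in base_calls.items():
            gdef = kb.genes.get(gene)
            adjustable = (
                gdef is not None
                and gdef.phenotype_system is PhenotypeSystem.METABOLIZER
                and not call.indeterminate
            )
            if adjustable:
                adjusted = apply_phenoconversion(call, comeds, kb).as_call()
            else:
                adjusted = call
            if phenoconversion_enabled:
                used[gene], shadow[gene] = adjusted, call
            else:
                used[gene], shadow[gene] = call, adjusted
        return used, shadow

    rows: list[LedgerRow] = []
    seen: set[str] = set()
    for med in case.medications:
        if med.drug_name in seen:
            continue
        seen.add(med.drug_name)

        guideline_flag, rules = guideline_available(med.drug_name, kb)
        adequacy_flag = assess_adequacy(med)
        outcome_flag = assess_outcome(med) if adequacy_flag else 0

        if not guideline_flag:
            congruency, rationale = Congruency.NOT_SCORED, "no CPIC level A/A-B guideline"
        elif not adequacy_flag:
            congruency, rationale = Congruency.NOT_SCORED, "inadequate or unsure therapeutic trial"
        elif not assess_outcome(med):
            congruency, rationale = Congruency.NOT_SCORED, "no medication-related problem"
        else:
            used, shadow = calls_for_drug(med.drug_name)
            relevant = [used.get(r.gene_symbol) for r in rules]
            if all(c is None or c.indeterminate for c in relevant):
                congruency = Congruency.NOT_SCORED
                rationale = (
                    "genotype unavailable or indeterminate for "
                    + ", ".join(r.gene_symbol for r in rules)
                    + " — congruency not adjudicated"
                )
            else:
                score = assess_congruency(
                    med.drug_name, list(used.values()), med.outcome, kb
                )
                congruency = (
                    Congruency.CONGRUENT if score > 0 else Congruency.INCONGRUENT
                )
                rationale = _row_rationale(rules, used, med.outcome, score, shadow)

        rows.append(
            LedgerRow(
                drug_name=med.drug_name,
                status=med.status,
                guideline_flag=guideline_flag,
                adequacy_flag=adequacy_flag,
                outcome_flag=outcome_flag,
                congruency=congruency,
                rationale=rationale,
            )
        )

    pgxbs = sum(r.score for r in rows)
    recommended, n_guideline = recommend_testing(case, kb)
    return ConsultResult(
        rows=rows,
        pgxbs=pgxbs,
        interpretation=interpret(pgxbs),
        testing_recommended=(not genotyped) and recommended,
        n_guideline_meds=n_guideline,
        genotyped=genotyped,
        phenoconversion_enabled=phenoconversion_enabled,
    )
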