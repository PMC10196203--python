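"""Synthetic patient-case generation with planted congruency structure.

Every consult path is testable without any real patient data: the generator
draws genotypes from configurable allele frequencies, picks medications
from the knowledge base, and *plants* each scoreable medication's outcome
to be congruent (with probability ``congruent_fraction``) or incongruent
with the drawn phenotype, recording the planted truth and the expected
PGxBS per case. Because the direction table used for planting is written
out literally here — not derived from the scoring engine — agreement
between the engine's score and the planted truth is a genuine
two-implementation check.

Allele frequencies default to round numbers and are synthetic; they are not
population estimates.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .knowledge_base import (
    KnowledgeBase,
    PhenotypeSystem,
    predict_phenotype,
)
from .scoring import (
    GenotypeRecord,
    MedicationRecord,
    PatientCase,
)

#: Independent congruency direction table: (gene_role, phenotype label) →
#: the outcome that phenotype predicts, or None for "no problem predicted".
#: Deliberately a literal grid, maintained separately from the engine.
PLANTING_GRID: dict[tuple[str, str], Optional[str]] = {
    ("activating", "PM"): "poor_efficacy",
    ("activating", "IM"): "poor_efficacy",
    ("activating", "NM"): None,
    ("activating", "RM"): "adverse_effects",
    ("activating", "UM"): "adverse_effects",
    ("inactivating", "PM"): "adverse_effects",
    ("inactivating", "IM"): "adverse_effects",
    ("inactivating", "NM"): None,
    ("inactivating", "RM"): "poor_efficacy",
    ("inactivating", "UM"): "poor_efficacy",
    ("immune_risk", "positive"): "adverse_effects",
    ("immune_risk", "negative"): None,
    ("target", "positive"): "poor_efficacy",
    ("target", "negative"): None,
}

#: Synthetic round-number allele frequencies per gene. Carrier genes carry
#: a "none" pseudo-allele for the no-risk-allele draw.
DEFAULT_ALLELE_FREQUENCIES: dict[str, dict[str, float]] = {
    "CYP2D6": {"*1": 0.40, "*2": 0.15, "*4": 0.20, "*5": 0.05, "*10": 0.10,
               "*41": 0.05, "*1x2": 0.05},
    "CYP2C19": {"*1": 0.60, "*2": 0.20, "*3": 0.05, "*17": 0.15},
    "CYP2C9": {"*1": 0.70, "*2": 0.15, "*3": 0.15},
    "TPMT": {"*1": 0.90, "*2": 0.02, "*3A": 0.05, "*3C": 0.03},
    "NUDT15": {"*1": 0.92, "*2": 0.03, "*3": 0.05},
    "SLCO1B1": {"*1": 0.75, "*5": 0.15, "*15": 0.10},
    "HLA-B": {"none": 0.80, "B*57:01": 0.05, "B*58:01": 0.10, "B*15:02": 0.05},
    "CFTR": {"none": 0.70, "F508del": 0.30},
}

_DISTRACTOR_DRUGS = ("paracetamol", "lisinopril", "metformin", "risperidone")
_PROBLEMS = ("adverse_effects", "poor_efficacy")


class SimulationConfig(BaseModel):
    """Knobs of the synthetic cohort; defaults describe a reactive-consult
    caseload of a few medications per referral."""

    n_cases: int = Field(default=100, gt=0)
    meds_per_case: tuple[int, int] = (2, 5)
    congruent_fraction: float = Field(default=0.5, ge=0, le=1)
    fraction_inadequate_trials: float = Field(default=0.2, ge=0, le=1)
    fraction_no_problem: float = Field(default=0.15, ge=0, le=1)
    fraction_untested: float = Field(default=0.0, ge=0, le=1)
    fraction_distractor: float = Field(default=0.3, ge=0, le=1)
    seed: int = 0
    allele_frequencies: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            g: dict(f) for g, f in DEFAULT_ALLELE_FREQUENCIES.items()
        }
    )

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.meds_per_case
        if not (1 <= lo <= hi):
            raise ValueError("meds_per_case must be a nondecreasing positive range")
        for gene, freqs in self.allele_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies for {gene} sum to {total}, expected 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"negative allele frequency for {gene}")
        return self


class SyntheticCase(BaseModel):
    """A generated case together with its planted ground truth."""

    case: PatientCase
    truth_labels: dict[str, str]  # drug → congruent / incongruent / not_scored
    expected_pgxbs: int

    @model_validator(mode="after")
    def _consistent(self):
        planted = sum(
            1 if v == "congruent" else -1 if v == "incongruent" else 0
            for v in self.truth_labels.values()
        )
        if planted != self.expected_pgxbs:
            raise ValueError("expected_pgxbs inconsistent with planted labels")
        return self


def draw_allele(rng: random.Random, freqs: dict[str, float]) -> str:
    alleles = sorted(freqs)
    return rng.choices(alleles, weights=[freqs[a] for a in alleles], k=1)[0]


def draw_genotypes(
    rng: random.Random, config: SimulationConfig, kb: KnowledgeBase
) -> list[GenotypeRecord]:
    """Draw one genotype record per configured gene."""
    records = []
    for gene in sorted(config.allele_frequencies):
        gdef = kb.genes.get(gene)
        freqs = config.allele_frequencies[gene]
        if gdef is not None and gdef.phenotype_system is PhenotypeSystem.CARRIER:
            drawn = draw_allele(rng, freqs)
            records.append(
                GenotypeRecord(
                    gene=gene, diplotype="negative" if drawn == "none" else drawn
                )
            )
        else:
            a, b = draw_allele(rng, freqs), draw_allele(rng, freqs)
            records.append(GenotypeRecord(gene=gene, diplotype=f"{a}/{b}"))
    return records


def _predicted_outcomes(
    drug: str, genotypes: list[GenotypeRecord], kb: KnowledgeBase
) -> set[str]:
    """Union of outcomes the drawn phenotypes predict for the drug, per the
    literal planting grid (any-gene disjunction)."""
    by_gene = {g.gene: g for g in genotypes}
    union: set[str] = set()
    for rule in kb.guideline_rules_for(drug):
        rec = by_gene.get(rule.gene_symbol)
        if rec is None:
            continue
        call = predict_phenotype(rule.gene_symbol, rec.diplotype, kb)
        label = call.phenotype.value
        if label == "positive" and rule.risk_alleles:
            # drug-specific risk allele must actually be carried
            if not set(rule.risk_alleles) & set(call.risk_alleles_present):
                label = "negative"
        outcome = PLANTING_GRID.get((rule.gene_role.value, label))
        if outcome is not None:
            union.add(outcome)
    return union


def generate_cases(config: SimulationConfig, kb: KnowledgeBase) -> list[SyntheticCase]:
    """Generate ``config.n_cases`` cases with known planted truth.

    For each scoreable medication the outcome is drawn from the phenotype's
    predicted outcomes with probability ``congruent_fraction`` (planting a
    congruent row) or from their complement (planting incongruence). When a
    drawn phenotype predicts no outcome, congruent planting is impossible
    and the row is planted incongruent; when it predicts both outcomes
    (multi-gene drugs), incongruent planting is impossible and the row is
    planted congruent. Truth is always recorded as planted. Reproducible
    for a fixed config.
    """
    rng = random.Random(config.seed)
    guideline_drugs = sorted(
        d for d in kb.drug_gene_rules if kb.guideline_rules_for(d)
    )
    cases: list[SyntheticCase] = []
    for i in range(config.n_cases):
        genotypes = draw_genotypes(rng, config, kb)
        untested = rng.random() < config.fraction_untested

        n_meds = rng.randint(*config.meds_per_case)
        n_meds = min(n_meds, len(guideline_drugs))
        drugs = rng.sample(guideline_drugs, n_meds)
        if rng.random() < config.fraction_distractor:
            drugs.append(rng.choice(_DISTRACTOR_DRUGS))
        rng.shuffle(drugs)

        meds: list[MedicationRecord] = []
        truth: dict[str, str] = {}
        expected = 0
        for drug in drugs:
            status = rng.choice(["current", "past"])
            is_guideline = drug in guideline_drugs
            if rng.random() < config.fraction_inadequate_trials:
                meds.append(
                    MedicationRecord(
                        drug_name=drug,
                        status=status,
                        trial_adequate=rng.choice(["no", "unsure"]),
                        outcome=rng.choice(_PROBLEMS),
                    )
                )
                truth[drug] = "not_scored"
                continue
            if rng.random() < config.fraction_no_problem:
                meds.append(
                    MedicationRecord(
                        drug_name=drug, status=status,
                        trial_adequate="yes", outcome="none_or_unknown",
                    )
                )
                truth[drug] = "not_scored"
                continue

            if not is_guideline or untested:
                outcome = rng.choice(_PROBLEMS)
                truth[drug] = "not_scored"
            else:
                predicted = _predicted_outcomes(drug, genotypes, kb)
                complement = set(_PROBLEMS) - predicted
                plant_congruent = rng.random() < config.congruent_fraction
                if plant_congruent and not predicted:
                    plant_congruent = False  # congruence unattainable for this draw
                if not plant_congruent and not complement:
                    plant_congruent = True  # incongruence unattainable
                pool = predicted if plant_congruent else complement
                outcome = rng.choice(sorted(pool))
                truth[drug] = "congruent" if plant_congruent else "incongruent"
                expected += 1 if plant_congruent else -1
            meds.append(
                MedicationRecord(
                    drug_name=drug, status=status,
                    trial_adequate="yes", outcome=outcome,
                )
            )

        cases.append(
            SyntheticCase(
                case=PatientCase(
                    patient={"case_id": f"synthetic-{config.seed}-{i:04d}"},
                    medications=meds,
                    comedications=[],
                    genotypes=[] if untested else genotypes,
                ),
                truth_labels=truth,
                expected_pgxbs=expected,
            )
        )
    return cases


def write_batch(cases: list[SyntheticCase], directory: Path | str) -> Path:
    """Write cases in the formats the report reader consumes, plus
    ``truth.json`` with the planted labels and expected scores."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = {}
    for i, sc in enumerate(cases):
        stem = f"case_{i:04d}"
        data = sc.case.model_dump(mode="json")
        genotypes = data.pop("genotypes")
        (directory / f"{stem}.yaml").write_text(
            yaml.safe_dump(data, sort_keys=False), encoding="utf-8"
        )
        lines = ["# gene\tdiplotype"] + [
            f"{g['gene']}\t{g['diplotype']}" for g in genotypes
        ]
        (directory / f"{stem}.genotypes.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        truth[stem] = {
            "labels": sc.truth_labels,
            "expected_pgxbs": sc.expected_pgxbs,
        }
    (directory / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return directory
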