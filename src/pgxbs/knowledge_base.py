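"""Machine-readable pharmacogenomics knowledge base.

The knowledge base answers the three questions the structured consult needs
per medication: *is there a guideline?* (drug–gene rules with evidence
levels), *what phenotype does this diplotype predict?* (allele function
tables plus activity-score bins or categorical translation), and *what
outcome does that phenotype mechanistically predict for this drug?* (the
gene role carried on each rule, consumed by :mod:`pgxbs.scoring`).

A knowledge base is a directory of tab-separated tables::

    genes.tsv             gene definitions (category, phenotype system)
    allele_functions.tsv  per-allele function class / activity value
    phenotype_bins.tsv    activity-score → metabolizer label bins
    drug_gene_rules.tsv   drug–gene pairs with evidence level and gene role
    interactions.tsv      perpetrator-drug → enzyme interaction strengths

plus an optional ``phenoconversion.tsv`` (strength → activity multiplier)
and ``kb_version.txt``. Lines starting with ``#`` are comments. The package
ships a curated synthetic snapshot under :func:`default_kb_path`.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

#: Activity-score multipliers used when the KB directory ships no
#: phenoconversion.tsv; one multiplier per matching perpetrator drug.
DEFAULT_PHENOCONVERSION_MULTIPLIERS: dict[str, float] = {
    "strong_inhibitor": 0.0,
    "moderate_inhibitor": 0.5,
    "strong_inducer": 2.0,
    "moderate_inducer": 1.5,
}

#: Activity values a single allele may carry (copy-number alleles carry
#: integer multiples of one of these).
_BASE_ACTIVITY_VALUES = {0.0, 0.25, 0.5, 1.0}

_COPY_NUMBER_RE = re.compile(r"^(?P<base>.+?)x(?P<n>\d+)$")


class KnowledgeBaseError(Exception):
    """Base class for knowledge-base loading/validation failures."""


class MissingTableError(KnowledgeBaseError):
    """A required table file is absent from the KB directory."""


class KBValidationError(KnowledgeBaseError):
    """A table row violates a knowledge-base invariant."""


class DiplotypeParseError(ValueError):
    """A genotype string cannot be parsed for the gene's phenotype system."""


class GeneCategory(str, enum.Enum):
    EXPOSURE = "exposure"
    RESPONSE = "response"
    SAFETY = "safety"


class PhenotypeSystem(str, enum.Enum):
    METABOLIZER = "metabolizer"
    CARRIER = "carrier"


class FunctionClass(str, enum.Enum):
    NO_FUNCTION = "no_function"
    DECREASED = "decreased"
    NORMAL = "normal"
    INCREASED = "increased"
    RISK = "risk"
    NON_RISK = "non_risk"


class CpicLevel(str, enum.Enum):
    A = "A"
    A_B = "A_B"
    B = "B"
    OTHER = "other"


class GeneRole(str, enum.Enum):
    """Mechanistic role of the gene for a given drug."""

    ACTIVATING = "activating"      # enzyme converts a prodrug to its active moiety
    INACTIVATING = "inactivating"  # enzyme clears the active drug
    TARGET = "target"              # response biomarker (pharmacodynamics)
    IMMUNE_RISK = "immune_risk"    # HLA-type severe-reaction risk


class Phenotype(str, enum.Enum):
    """Genotype-predicted phenotype labels across both systems."""

    PM = "PM"
    IM = "IM"
    NM = "NM"
    RM = "RM"
    UM = "UM"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


#: Total ordering of metabolizer labels, PM (no activity) → UM (ultrarapid).
METABOLIZER_ORDER: tuple[Phenotype, ...] = (
    Phenotype.PM,
    Phenotype.IM,
    Phenotype.NM,
    Phenotype.RM,
    Phenotype.UM,
)


class GeneDefinition(BaseModel):
    gene_symbol: str
    category: GeneCategory
    phenotype_system: PhenotypeSystem
    uses_activity_score: bool


class AlleleFunction(BaseModel):
    gene_symbol: str
    allele: str
    function_class: FunctionClass
    activity_value: Optional[float] = None

    @field_validator("activity_value")
    @classmethod
    def _nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError("activity_value must be nonnegative")
        return v


class PhenotypeBin(BaseModel):
    gene_symbol: str
    phenotype_label: Phenotype
    lower_bound: float  # inclusive
    upper_bound: float  # inclusive


class DrugGeneRule(BaseModel):
    drug_name: str
    gene_symbol: str
    cpic_level: CpicLevel
    gene_role: GeneRole
    #: For carrier-system genes: the drug-specific risk allele(s); empty
    #: means any risk allele of the gene applies.
    risk_alleles: tuple[str, ...] = ()

    @field_validator("drug_name")
    @classmethod
    def _normalized(cls, v: str) -> str:
        return normalize_drug_name(v)


class InteractionStrength(BaseModel):
    perpetrator_drug: str
    gene_symbol: str
    strength: str

    @field_validator("perpetrator_drug")
    @classmethod
    def _normalized(cls, v: str) -> str:
        return normalize_drug_name(v)

    @field_validator("strength")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in DEFAULT_PHENOCONVERSION_MULTIPLIERS:
            raise ValueError(f"unknown interaction strength {v!r}")
        return v


class PhenotypeCall(BaseModel):
    """Genotype-predicted phenotype for one gene.

    ``activity_score`` is populated only for activity-score genes;
    ``risk_alleles_present`` only for carrier-system genes.
    """

    gene_symbol: str
    diplotype: str
    phenotype: Phenotype
    activity_score: Optional[float] = None
    risk_alleles_present: tuple[str, ...] = ()
    phenoconverted: bool = False
    note: str = ""

    @property
    def indeterminate(self) -> bool:
        return self.phenotype is Phenotype.INDETERMINATE


def normalize_drug_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace in a drug name."""
    return " ".join(name.strip().casefold().split())


# ---------------------------------------------------------------------------
# categorical (non-activity-score) metabolizer translation
# ---------------------------------------------------------------------------
# Function-class pair → phenotype, CPIC-style categorical translation for
# genes whose increased-function alleles have no defined activity value.
# Keys are alphabetically sorted pairs.
_CLASS_PAIR_LABEL: dict[tuple[str, str], Phenotype] = {
    ("no_function", "no_function"): Phenotype.PM,
    ("decreased", "no_function"): Phenotype.IM,
    ("decreased", "decreased"): Phenotype.IM,
    ("no_function", "normal"): Phenotype.IM,
    ("decreased", "normal"): Phenotype.IM,
    ("normal", "normal"): Phenotype.NM,
    ("increased", "no_function"): Phenotype.IM,
    ("decreased", "increased"): Phenotype.NM,
    ("increased", "normal"): Phenotype.RM,
    ("increased", "increased"): Phenotype.UM,
}


@dataclass
class KnowledgeBase:
    """In-memory, validated knowledge base."""

    genes: dict[str, GeneDefinition] = field(default_factory=dict)
    allele_functions: dict[tuple[str, str], AlleleFunction] = field(default_factory=dict)
    phenotype_bins: dict[str, list[PhenotypeBin]] = field(default_factory=dict)
    drug_gene_rules: dict[str, list[DrugGeneRule]] = field(default_factory=dict)
    interactions: dict[tuple[str, str], InteractionStrength] = field(default_factory=dict)
    phenoconversion_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOCONVERSION_MULTIPLIERS)
    )
    version: str = "unversioned"

    # -- queries -----------------------------------------------------------
    def rules_for(self, drug_name: str) -> list[DrugGeneRule]:
        return self.drug_gene_rules.get(normalize_drug_name(drug_name), [])

    def guideline_rules_for(self, drug_name: str) -> list[DrugGeneRule]:
        """Rules carrying CPIC level A or A/B evidence for the drug."""
        return [
            r
            for r in self.rules_for(drug_name)
            if r.cpic_level in (CpicLevel.A, CpicLevel.A_B)
        ]

    def perpetrators_for(
        self, gene_symbol: str, comedications: list[str]
    ) -> list[InteractionStrength]:
        """Interaction rows matching any of the co-medications for a gene."""
        hits = []
        for drug in comedications:
            inter = self.interactions.get((normalize_drug_name(drug), gene_symbol))
            if inter is not None:
                hits.append(inter)
        return hits

    def alleles_of(self, gene_symbol: str) -> list[AlleleFunction]:
        return [af for (g, _), af in self.allele_functions.items() if g == gene_symbol]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check every cross-table invariant; raise :class:`KBValidationError`."""
        for (gene, allele), af in self.allele_functions.items():
            gdef = self.genes.get(gene)
            if gdef is None:
                raise KBValidationError(
                    f"allele_functions: {gene} {allele}: gene not defined in genes.tsv"
                )
            if gdef.uses_activity_score:
                if af.activity_value is None:
                    raise KBValidationError(
                        f"allele_functions: {gene} {allele}: activity_value required "
                        "for an activity-score gene"
                    )
                self._check_activity_value(af)
            elif af.activity_value is not None:
                raise KBValidationError(
                    f"allele_functions: {gene} {allele}: activity_value given but "
                    f"{gene} does not use activity scores"
                )
            if af.function_class in (FunctionClass.RISK, FunctionClass.NON_RISK):
                if gdef.phenotype_system is not PhenotypeSystem.CARRIER:
                    raise KBValidationError(
                        f"allele_functions: {gene} {allele}: risk/non_risk classes are "
                        "only valid for carrier-system genes"
                    )
            elif gdef.phenotype_system is PhenotypeSystem.CARRIER:
                raise KBValidationError(
                    f"allele_functions: {gene} {allele}: carrier-system genes use "
                    "risk/non_risk function classes"
                )

        for gene, gdef in self.genes.items():
            if gdef.category is GeneCategory.SAFETY and (
                gdef.phenotype_system is not PhenotypeSystem.CARRIER
            ):
                raise KBValidationError(
                    f"genes: {gene}: safety-category genes must use the carrier system"
                )
            if gdef.uses_activity_score:
                self._check_bin_partition(gene)
            elif gene in self.phenotype_bins:
                raise KBValidationError(
                    f"phenotype_bins: {gene}: bins given but gene does not use "
                    "activity scores"
                )

        role_category = {
            GeneRole.IMMUNE_RISK: GeneCategory.SAFETY,
            GeneRole.TARGET: GeneCategory.RESPONSE,
            GeneRole.ACTIVATING: GeneCategory.EXPOSURE,
            GeneRole.INACTIVATING: GeneCategory.EXPOSURE,
        }
        for drug, rules in self.drug_gene_rules.items():
            for rule in rules:
                gdef = self.genes.get(rule.gene_symbol)
                if gdef is None:
                    raise KBValidationError(
                        f"drug_gene_rules: {drug}×{rule.gene_symbol}: gene not defined"
                    )
                if gdef.category is not role_category[rule.gene_role]:
                    raise KBValidationError(
                        f"drug_gene_rules: {drug}×{rule.gene_symbol}: gene_role "
                        f"{rule.gene_role.value} requires category "
                        f"{role_category[rule.gene_role].value}, gene is "
                        f"{gdef.category.value}"
                    )

        for (perp, gene), inter in self.interactions.items():
            gdef = self.genes.get(gene)
            if gdef is None or gdef.phenotype_system is not PhenotypeSystem.METABOLIZER:
                raise KBValidationError(
                    f"interactions: {perp}×{gene}: interactions apply only to "
                    "metabolizer-system genes"
                )

    def _check_activity_value(self, af: AlleleFunction) -> None:
        v = af.activity_value
        if v in _BASE_ACTIVITY_VALUES:
            return
        m = _COPY_NUMBER_RE.match(af.allele)
        if m:
            n = int(m.group("n"))
            if any(math.isclose(v, n * b) for b in _BASE_ACTIVITY_VALUES):
                return
        raise KBValidationError(
            f"allele_functions: {af.gene_symbol} {af.allele}: activity_value {v} is "
            "not a base value (0, 0.25, 0.5, 1) or a copy-number multiple"
        )

    def _check_bin_partition(self, gene: str) -> None:
        bins = self.phenotype_bins.get(gene, [])
        if not bins:
            raise KBValidationError(
                f"phenotype_bins: {gene}: activity-score gene has no bins"
            )
        for a, b in combinations_with_replacement(bins, 2):
            if a is b:
                continue
            if a.lower_bound <= b.upper_bound and b.lower_bound <= a.upper_bound:
                raise KBValidationError(
                    f"phenotype_bins: {gene}: bins {a.phenotype_label.value} and "
                    f"{b.phenotype_label.value} overlap — bins must partition the "
                    "attainable activity-score range"
                )
        values = [
            af.activity_value for af in self.alleles_of(gene) if af.activity_value is not None
        ]
        for x, y in combinations_with_replacement(values, 2):
            score = x + y
            hits = [b for b in bins if b.lower_bound <= score <= b.upper_bound]
            if len(hits) != 1:
                raise KBValidationError(
                    f"phenotype_bins: {gene}: attainable activity score {score} falls "
                    f"in {len(hits)} bins — bins must partition the attainable range"
                )

    # -- serialization -----------------------------------------------------
    def to_directory(self, directory_path: Path | str) -> None:
        """Write the KB back out as the five canonical TSV tables."""
        directory = Path(directory_path)
        directory.mkdir(parents=True, exist_ok=True)

        def dump(name: str, rows: list[dict]) -> None:
            pd.DataFrame(rows).to_csv(directory / name, sep="\t", index=False)

        dump(
            "genes.tsv",
            [
                {**g.model_dump(), "uses_activity_score": str(g.uses_activity_score).lower()}
                for g in self.genes.values()
            ],
        )
        dump(
            "allele_functions.tsv",
            [
                {
                    "gene_symbol": af.gene_symbol,
                    "allele": af.allele,
                    "function_class": af.function_class.value,
                    "activity_value": "" if af.activity_value is None else af.activity_value,
                }
                for af in self.allele_functions.values()
            ],
        )
        dump(
            "phenotype_bins.tsv",
            [
                {
                    "gene_symbol": b.gene_symbol,
                    "phenotype_label": b.phenotype_label.value,
                    "lower_bound": b.lower_bound,
                    "upper_bound": b.upper_bound,
                }
                for bins in self.phenotype_bins.values()
                for b in bins
            ],
        )
        dump(
            "drug_gene_rules.tsv",
            [
                {
                    "drug_name": r.drug_name,
                    "gene_symbol": r.gene_symbol,
                    "cpic_level": r.cpic_level.value,
                    "gene_role": r.gene_role.value,
                    "risk_alleles": ",".join(r.risk_alleles),
                }
                for rules in self.drug_gene_rules.values()
                for r in rules
            ],
        )
        dump(
            "interactions.tsv",
            [i.model_dump() for i in self.interactions.values()],
        )
        dump(
            "phenoconversion.tsv",
            [
                {"strength": k, "multiplier": v}
                for k, v in self.phenoconversion_multipliers.items()
            ],
        )
        (directory / "kb_version.txt").write_text(self.version + "\n", encoding="utf-8")


def default_kb_path() -> Path:
    """Path of the curated knowledge-base snapshot shipped with the package."""
    return Path(resources.files("pgxbs").joinpath("data/kb"))


def example_case_paths() -> tuple[Path, Path]:
    """Paths of the shipped worked-example case and genotype files."""
    base = Path(resources.files("pgxbs").joinpath("data/examples"))
    return base / "worked_case.yaml", base / "worked_case.genotypes.tsv"


def _read_table(directory: Path, name: str, required_columns: list[str]) -> pd.DataFrame:
    path = directory / name
    if not path.is_file():
        raise MissingTableError(f"knowledge base table missing: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise KBValidationError(f"{name}: missing column(s) {missing}")
    return df


def load_knowledge_base(directory_path: Path | str) -> KnowledgeBase:
    """Load and validate a knowledge base from a directory of TSV tables.

    Raises :class:`MissingTableError` if a required table is absent and
    :class:`KBValidationError` naming the offending row and rule if any
    invariant is violated.
    """
    directory = Path(directory_path)
    kb = KnowledgeBase()

    genes = _read_table(
        directory, "genes.tsv",
        ["gene_symbol", "category", "phenotype_system", "uses_activity_score"],
    )
    for i, row in genes.iterrows():
        g = GeneDefinition(
            gene_symbol=row["gene_symbol"],
            category=row["category"],
            phenotype_system=row["phenotype_system"],
            uses_activity_score=str(row["uses_activity_score"]).strip().lower()
            in ("true", "1", "yes"),
        )
        if g.gene_symbol in kb.genes:
            raise KBValidationError(f"genes.tsv row {i}: duplicate gene {g.gene_symbol}")
        kb.genes[g.gene_symbol] = g

    alleles = _read_table(
        directory, "allele_functions.tsv",
        ["gene_symbol", "allele", "function_class"],
    )
    for i, row in alleles.iterrows():
        raw = row.get("activity_value")
        af = AlleleFunction(
            gene_symbol=row["gene_symbol"],
            allele=row["allele"].strip(),
            function_class=row["function_class"],
            activity_value=None if pd.isna(raw) or str(raw).strip() == "" else float(raw),
        )
        key = (af.gene_symbol, af.allele)
        if key in kb.allele_functions:
            raise KBValidationError(
                f"allele_functions.tsv row {i}: duplicate allele {key}"
            )
        kb.allele_functions[key] = af

    bins = _read_table(
        directory, "phenotype_bins.tsv",
        ["gene_symbol", "phenotype_label", "lower_bound", "upper_bound"],
    )
    for _, row in bins.iterrows():
        b = PhenotypeBin(
            gene_symbol=row["gene_symbol"],
            phenotype_label=row["phenotype_label"],
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
        )
        kb.phenotype_bins.setdefault(b.gene_symbol, []).append(b)

    rules = _read_table(
        directory, "drug_gene_rules.tsv",
        ["drug_name", "gene_symbol", "cpic_level", "gene_role"],
    )
    for i, row in rules.iterrows():
        raw_risk = row.get("risk_alleles")
        risk = (
            tuple(a.strip() for a in str(raw_risk).split(",") if a.strip())
            if raw_risk is not None and not pd.isna(raw_risk)
            else ()
        )
        rule = DrugGeneRule(
            drug_name=row["drug_name"],
            gene_symbol=row["gene_symbol"],
            cpic_level=row["cpic_level"],
            gene_role=row["gene_role"],
            risk_alleles=risk,
        )
        existing = kb.drug_gene_rules.setdefault(rule.drug_name, [])
        if any(r.gene_symbol == rule.gene_symbol for r in existing):
            raise KBValidationError(
                f"drug_gene_rules.tsv row {i}: duplicate pair "
                f"{rule.drug_name}×{rule.gene_symbol}"
            )
        existing.append(rule)

    inter = _read_table(
        directory, "interactions.tsv",
        ["perpetrator_drug", "gene_symbol", "strength"],
    )
    for i, row in inter.iterrows():
        rec = InteractionStrength(
            perpetrator_drug=row["perpetrator_drug"],
            gene_symbol=row["gene_symbol"],
            strength=row["strength"],
        )
        key = (rec.perpetrator_drug, rec.gene_symbol)
        if key in kb.interactions:
            raise KBValidationError(f"interactions.tsv row {i}: duplicate pair {key}")
        kb.interactions[key] = rec

    pconv = directory / "phenoconversion.tsv"
    if pconv.is_file():
        df = pd.read_csv(pconv, sep="\t", comment="#", dtype=str)
        kb.phenoconversion_multipliers = {
            row["strength"]: float(row["multiplier"]) for _, row in df.iterrows()
        }

    version_file = directory / "kb_version.txt"
    if version_file.is_file():
        kb.version = version_file.read_text(encoding="utf-8").strip()

    kb.validate()
    logger.info(
        "loaded knowledge base %s: %d genes, %d alleles, %d bins, %d rules, "
        "%d interactions",
        kb.version,
        len(kb.genes),
        len(kb.allele_functions),
        sum(len(v) for v in kb.phenotype_bins.values()),
        sum(len(v) for v in kb.drug_gene_rules.values()),
        len(kb.interactions),
    )
    return kb


def guideline_available(drug_name: str, kb: KnowledgeBase) -> tuple[int, list[DrugGeneRule]]:
    """Step-2 answer: is CPIC level A / A-B evidence available for this drug?

    Returns ``(1, matched_rules)`` when at least one rule qualifies and
    ``(0, [])`` otherwise. Unknown drugs answer 0 ("no/unsure"), never an
    error.
    """
    matched = kb.guideline_rules_for(drug_name)
    return (1, matched) if matched else (0, [])


def parse_carrier_genotype(genotype: str) -> list[str]:
    """Parse a carrier-gene genotype into the list of present alleles.

    Accepts comma-separated allele names, an optional trailing ``present``
    marker, and ``negative``/``none``/``none detected`` for no alleles.
    """
    text = genotype.strip()
    if text.casefold() in ("", "negative", "none", "none detected", "not detected"):
        return []
    alleles = []
    for token in text.split(","):
        token = token.strip()
        if token.casefold().endswith(" present"):
            token = token[: -len(" present")].strip()
        if token:
            alleles.append(token)
    return alleles


def _lookup_allele(kb: KnowledgeBase, gene: str, allele: str) -> Optional[AlleleFunction]:
    af = kb.allele_functions.get((gene, allele))
    if af is not None:
        return af
    # copy-number allele not listed explicitly: derive from its base allele
    m = _COPY_NUMBER_RE.match(allele)
    if m:
        base = kb.allele_functions.get((gene, m.group("base")))
        if base is not None and base.activity_value is not None:
            return AlleleFunction(
                gene_symbol=gene,
                allele=allele,
                function_class=base.function_class,
                activity_value=base.activity_value * int(m.group("n")),
            )
    return None


def bin_activity_score(kb: KnowledgeBase, gene: str, score: float) -> Phenotype:
    """Map an activity score to its phenotype bin.

    Exact containment is used first; a score falling in a gap between bins
    (possible only for phenoconversion-adjusted scores, never for attainable
    diplotype sums) is assigned the nearest bin below, floored at the lowest
    bin.
    """
    bins = sorted(kb.phenotype_bins[gene], key=lambda b: b.lower_bound)
    for b in bins:
        if b.lower_bound <= score <= b.upper_bound:
            return b.phenotype_label
    below = [b for b in bins if b.lower_bound <= score]
    return below[-1].phenotype_label if below else bins[0].phenotype_label


def predict_phenotype(gene_symbol: str, diplotype: str, kb: KnowledgeBase) -> PhenotypeCall:
    """Translate a diplotype (or carrier allele list) into a phenotype call.

    Unknown genes or alleles yield an ``indeterminate`` call with an
    explanatory note — never a silent normal-metabolizer default. A
    malformed metabolizer diplotype raises :class:`DiplotypeParseError`.
    """
    gdef = kb.genes.get(gene_symbol)
    if gdef is None:
        return PhenotypeCall(
            gene_symbol=gene_symbol,
            diplotype=diplotype,
            phenotype=Phenotype.INDETERMINATE,
            note=f"gene {gene_symbol} not in knowledge base",
        )

    if gdef.phenotype_system is PhenotypeSystem.CARRIER:
        present = parse_carrier_genotype(diplotype)
        unknown = [a for a in present if (gene_symbol, a) not in kb.allele_functions]
        if unknown:
            return PhenotypeCall(
                gene_symbol=gene_symbol,
                diplotype=diplotype,
                phenotype=Phenotype.INDETERMINATE,
                note=f"unknown allele(s): {', '.join(unknown)}",
            )
        risk = tuple(
            a
            for a in present
            if kb.allele_functions[(gene_symbol, a)].function_class is FunctionClass.RISK
        )
        return PhenotypeCall(
            gene_symbol=gene_symbol,
            diplotype=diplotype,
            phenotype=Phenotype.POSITIVE if risk else Phenotype.NEGATIVE,
            risk_alleles_present=risk,
        )

    # metabolizer system: "alleleA/alleleB"
    parts = diplotype.strip().split("/")
    if len(parts) != 2 or not all(p.strip() for p in parts):
        raise DiplotypeParseError(
            f"{gene_symbol}: expected 'alleleA/alleleB', got {diplotype!r}"
        )
    funcs = []
    for part in parts:
        af = _lookup_allele(kb, gene_symbol, part.strip())
        if af is None:
            return PhenotypeCall(
                gene_symbol=gene_symbol,
                diplotype=diplotype,
                phenotype=Phenotype.INDETERMINATE,
                note=f"unknown allele {part.strip()!r}",
            )
        funcs.append(af)

    if gdef.uses_activity_score:
        score = sum(af.activity_value for af in funcs)
        return PhenotypeCall(
            gene_symbol=gene_symbol,
            diplotype=diplotype,
            phenotype=bin_activity_score(kb, gene_symbol, score),
            activity_score=score,
        )

    key = tuple(sorted(af.function_class.value for af in funcs))
    label = _CLASS_PAIR_LABEL.get(key)  # type: ignore[arg-type]
    if label is None:
        return PhenotypeCall(
            gene_symbol=gene_symbol,
            diplotype=diplotype,
            phenotype=Phenotype.INDETERMINATE,
            note=f"no categorical translation for function classes {key}",
        )
    return PhenotypeCall(gene_symbol=gene_symbol, diplotype=diplotype, phenotype=label)
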