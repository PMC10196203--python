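import pytest

from pgxbs import (
    default_kb_path,
    example_case_paths,
    load_knowledge_base,
    read_case,
    read_genotypes,
)

# ---------------------------------------------------------------------------
# Brute-force congruency oracle: the full gene_role × phenotype × outcome
# grid written out cell by cell, independent of the scoring engine. A cell
# maps to the outcome that phenotype predicts (None = predicts no problem);
# congruency for an observed problem is +1 iff the problem matches the
# prediction, else -1.
# ---------------------------------------------------------------------------
ORACLE_PREDICTION = {
    ("activating", "PM"): "poor_efficacy",
    ("activating", "IM"): "poor_efficacy",
    ("activating", "NM"): None,
    ("activating", "RM"): "adverse_effects",
    ("activating", "UM"): "adverse_effects",
    ("activating", "indeterminate"): None,
    ("inactivating", "PM"): "adverse_effects",
    ("inactivating", "IM"): "adverse_effects",
    ("inactivating", "NM"): None,
    ("inactivating", "RM"): "poor_efficacy",
    ("inactivating", "UM"): "poor_efficacy",
    ("inactivating", "indeterminate"): None,
    ("immune_risk", "positive"): "adverse_effects",
    ("immune_risk", "negative"): None,
    ("immune_risk", "indeterminate"): None,
    ("target", "positive"): "poor_efficacy",
    ("target", "negative"): None,
    ("target", "indeterminate"): None,
}


def oracle_congruency(gene_role: str, phenotype: str, observed: str) -> int:
    """Independent single-gene congruency adjudication."""
    return 1 if ORACLE_PREDICTION[(gene_role, phenotype)] == observed else -1


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base(default_kb_path())


@pytest.fixture(scope="session")
def worked_case():
    case_path, _ = example_case_paths()
    return read_case(case_path)


@pytest.fixture(scope="session")
def worked_genotypes(kb):
    _, geno_path = example_case_paths()
    return read_genotypes(geno_path, kb)
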