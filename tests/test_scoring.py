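"""Consult steps 2–6: binary gates, congruency adjudication, summation."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import ORACLE_PREDICTION, oracle_congruency
from pgxbs import (
    MedicationRecord,
    Outcome,
    PatientCase,
    assess_adequacy,
    assess_congruency,
    assess_outcome,
    expected_outcomes,
    interpret,
    recommend_testing,
    run_consult,
)
from pgxbs.knowledge_base import Phenotype, PhenotypeCall
from pgxbs.scoring import Congruency, Interpretation
from pgxbs.synthetic_cases import SimulationConfig, generate_cases

METABOLIZER_LABELS = ["PM", "IM", "NM", "RM", "UM", "indeterminate"]
CARRIER_LABELS = ["positive", "negative", "indeterminate"]
PROBLEMS = [Outcome.POOR_EFFICACY, Outcome.ADVERSE_EFFECTS]

# one fixture drug per gene role, with the gene and carrier details needed
# to build a phenotype call for any label
ROLE_DRUGS = {
    "activating": ("codeine", "CYP2D6", METABOLIZER_LABELS),
    "inactivating": ("warfarin", "CYP2C9", METABOLIZER_LABELS),
    "immune_risk": ("allopurinol", "HLA-B", CARRIER_LABELS),
    "target": ("ivacaftor", "CFTR", CARRIER_LABELS),
}


def make_call(gene: str, label: str, risk_allele: str = "") -> PhenotypeCall:
    return PhenotypeCall(
        gene_symbol=gene,
        diplotype="synthetic",
        phenotype=Phenotype(label),
        risk_alleles_present=(risk_allele,) if label == "positive" and risk_allele else (),
    )


def _med(drug, trial="yes", outcome="poor_efficacy", status="current"):
    return MedicationRecord(
        drug_name=drug, status=status, trial_adequate=trial, outcome=outcome
    )


class TestBinaryGates:
    @pytest.mark.parametrize(
        "trial,expected", [("yes", 1), ("no", 0), ("unsure", 0)]
    )
    def test_step3_adequacy(self, trial, expected):
        assert assess_adequacy(_med("codeine", trial=trial)) == expected

    @pytest.mark.parametrize(
        "outcome,expected",
        [("poor_efficacy", 1), ("adverse_effects", 1), ("none_or_unknown", 0)],
    )
    def test_step4_problem_outcomes(self, outcome, expected):
        assert assess_outcome(_med("codeine", outcome=outcome)) == expected


class TestCongruencyGrid:
    def test_expected_outcomes_match_oracle_on_every_grid_cell(self, kb):
        """Full gene_role × phenotype × outcome grid against the
        independent cell-by-cell oracle."""
        checked = 0
        for role, (drug, gene, labels) in ROLE_DRUGS.items():
            (rule,) = [r for r in kb.guideline_rules_for(drug) if r.gene_symbol == gene]
            for label in labels:
                call = make_call(gene, label, risk_allele=rule.risk_alleles[0]
                                 if rule.risk_alleles else "F508del")
                predicted = expected_outcomes(rule, call)
                for observed in PROBLEMS:
                    oracle_key = ORACLE_PREDICTION[(role, label)]
                    assert (observed.value == oracle_key) == (observed in predicted)
                    checked += 1
        assert checked == 36  # 2 roles × 6 labels × 2 + 2 roles × 3 labels × 2

    def test_assess_congruency_matches_oracle_on_determinate_cells(self, kb):
        for role, (drug, gene, labels) in ROLE_DRUGS.items():
            (rule,) = [r for r in kb.guideline_rules_for(drug) if r.gene_symbol == gene]
            for label in labels:
                if label == "indeterminate":
                    continue
                call = make_call(gene, label, risk_allele=rule.risk_alleles[0]
                                 if rule.risk_alleles else "F508del")
                for observed in PROBLEMS:
                    assert assess_congruency(drug, [call], observed, kb) == (
                        oracle_congruency(role, label, observed.value)
                    )

    def test_worked_illustrations(self, kb):
        um = make_call("CYP2D6", "UM")
        pm = make_call("CYP2D6", "PM")
        nm19 = make_call("CYP2C19", "NM")
        # ultrarapid activation of codeine cannot explain poor analgesia
        assert assess_congruency("codeine", [um], Outcome.POOR_EFFICACY, kb) == -1
        # ultrarapid clearance of clomipramine explains no mental-state improvement
        assert assess_congruency(
            "clomipramine", [um, nm19], Outcome.POOR_EFFICACY, kb
        ) == 1
        # poor metabolizer cannot over-activate tramadol: toxicity incongruent
        assert assess_congruency("tramadol", [pm], Outcome.ADVERSE_EFFECTS, kb) == -1
        # deficient thiopurine clearance explains toxicity
        assert assess_congruency(
            "azathioprine", [make_call("TPMT", "PM")], Outcome.ADVERSE_EFFECTS, kb
        ) == 1
        # SCAR on allopurinol in a B*58:01 carrier is congruent
        assert assess_congruency(
            "allopurinol",
            [make_call("HLA-B", "positive", "B*58:01")],
            Outcome.ADVERSE_EFFECTS,
            kb,
        ) == 1

    def test_drug_specific_risk_alleles_do_not_cross_react(self, kb):
        # a B*58:01 carrier is not at genotype-predicted risk from abacavir
        carrier = make_call("HLA-B", "positive", "B*58:01")
        assert assess_congruency("abacavir", [carrier], Outcome.ADVERSE_EFFECTS, kb) == -1

    def test_one_indeterminate_gene_among_several_contributes_nothing(self, kb):
        calls = [make_call("CYP2D6", "indeterminate"), make_call("CYP2C19", "PM")]
        assert assess_congruency(
            "clomipramine", calls, Outcome.ADVERSE_EFFECTS, kb
        ) == 1

    def test_all_indeterminate_cannot_be_adjudicated(self, kb):
        with pytest.raises(ValueError, match="indeterminate"):
            assess_congruency(
                "codeine",
                [make_call("CYP2D6", "indeterminate")],
                Outcome.POOR_EFFICACY,
                kb,
            )

    def test_gene_mismatch_is_a_contract_error(self, kb):
        (rule,) = kb.guideline_rules_for("codeine")
        with pytest.raises(ValueError, match="CYP2C9"):
            expected_outcomes(rule, make_call("CYP2C9", "PM"))


class TestInterpretation:
    def test_threshold_exhaustively(self):
        for s in range(-10, 11):
            expected = (
                Interpretation.POSSIBLE_PGX_CONTRIBUTION
                if s >= 1
                else Interpretation.PGX_LESS_LIKELY
            )
            assert interpret(s) is expected


class TestRecommendTesting:
    def test_two_guideline_meds_meet_the_reactive_cutoff(self, worked_case, kb):
        assert recommend_testing(worked_case, kb) == (True, 2)

    def test_one_guideline_med_is_below_the_cutoff(self, worked_case, kb):
        for keep in range(2):
            case = worked_case.model_copy(
                update={"medications": [worked_case.medications[keep]]}
            )
            assert recommend_testing(case, kb) == (False, 1)

    def test_zero_medications(self, kb):
        assert recommend_testing(PatientCase(), kb) == (False, 0)

    def test_duplicates_and_non_guideline_meds_do_not_inflate_the_count(self, kb):
        case = PatientCase(
            medications=[_med("codeine"), _med("codeine"), _med("paracetamol")]
        )
        assert recommend_testing(case, kb) == (False, 1)


class TestRunConsult:
    def test_worked_example_ledger(self, worked_case, worked_genotypes, kb):
        result = run_consult(worked_case, worked_genotypes, kb)
        assert [r.drug_name for r in result.rows] == ["codeine", "clomipramine"]
        assert [r.score for r in result.rows] == [-1, 1]
        assert result.pgxbs == 0
        assert result.interpretation is Interpretation.PGX_LESS_LIKELY
        assert all(r.rationale for r in result.rows)

    def test_zero_medications_scores_zero(self, kb):
        result = run_consult(PatientCase(), genotypes=[], kb=kb)
        assert result.rows == [] and result.pgxbs == 0

    def test_untested_patient_rows_not_scored_and_testing_recommended(
        self, worked_case, kb
    ):
        result = run_consult(worked_case, genotypes=[], kb=kb)
        assert all(r.congruency is Congruency.NOT_SCORED for r in result.rows)
        assert result.pgxbs == 0
        assert result.testing_recommended and result.n_guideline_meds == 2

    def test_failed_gates_leave_rows_unscored(self, worked_genotypes, kb):
        case = PatientCase(
            medications=[
                _med("paracetamol"),                       # step 2 fails
                _med("codeine", trial="unsure"),           # step 3 fails
                _med("warfarin", outcome="none_or_unknown"),  # step 4 fails
            ]
        )
        result = run_consult(case, worked_genotypes, kb)
        assert [r.congruency for r in result.rows] == [Congruency.NOT_SCORED] * 3
        assert result.pgxbs == 0

    def test_nm_only_genotype_fails_to_explain_a_problem(self, worked_genotypes, kb):
        # normal metabolizer predicts no problem, so a problem is incongruent
        case = PatientCase(medications=[_med("clopidogrel", outcome="poor_efficacy")])
        result = run_consult(case, worked_genotypes, kb)
        assert result.rows[0].congruency is Congruency.INCONGRUENT

    def test_duplicate_medication_entries_collapse_to_first(self, worked_genotypes, kb):
        case = PatientCase(
            medications=[
                _med("codeine", outcome="poor_efficacy"),
                _med("codeine", outcome="adverse_effects"),
            ]
        )
        result = run_consult(case, worked_genotypes, kb)
        assert len(result.rows) == 1
        assert result.rows[0].congruency is Congruency.INCONGRUENT  # poor_efficacy kept

    def test_past_and_current_medications_score_identically(self, worked_genotypes, kb):
        scores = []
        for status in ("current", "past"):
            case = PatientCase(medications=[_med("codeine", status=status)])
            scores.append(run_consult(case, worked_genotypes, kb).rows[0].score)
        assert scores[0] == scores[1] == -1

    def test_removing_a_non_guideline_medication_never_changes_pgxbs(
        self, worked_case, worked_genotypes, kb
    ):
        with_extra = worked_case.model_copy(
            update={"medications": worked_case.medications + [_med("paracetamol")]}
        )
        assert (
            run_consult(with_extra, worked_genotypes, kb).pgxbs
            == run_consult(worked_case, worked_genotypes, kb).pgxbs
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), med_index=st.integers(0, 7))
    def test_gate_monotonicity_and_conservation(self, kb, seed, med_index):
        """Downgrading one trial to inadequate unscores that row only, and
        the score always equals #congruent − #incongruent."""
        config = SimulationConfig(n_cases=1, seed=seed, congruent_fraction=0.6)
        (sc,) = generate_cases(config, kb)
        result = run_consult(sc.case, kb=kb)
        plus = sum(1 for r in result.rows if r.congruency is Congruency.CONGRUENT)
        minus = sum(1 for r in result.rows if r.congruency is Congruency.INCONGRUENT)
        assert result.pgxbs == plus - minus
        assert abs(result.pgxbs) <= plus + minus

        meds = sc.case.medications
        idx = med_index % len(meds)
        downgraded = [
            m.model_copy(update={"trial_adequate": "no"}) if i == idx else m
            for i, m in enumerate(meds)
        ]
        changed = run_consult(
            sc.case.model_copy(update={"medications": downgraded}), kb=kb
        )
        target = meds[idx].drug_name
        for before, after in zip(result.rows, changed.rows):
            if before.drug_name == target:
                assert after.congruency is Congruency.NOT_SCORED
            else:
                assert after.congruency is before.congruency
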