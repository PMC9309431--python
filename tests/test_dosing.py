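"""Dosing rules engine: printed dose values, priorities and totality."""

import json
from itertools import product

import pytest

from cyp2c19sup.calling import Phenotype, PredictivePhenotype, call_cohort
from cyp2c19sup.dosing import (
    Action,
    ClinicalContext,
    Drug,
    Indication,
    STANDARD_DOSES,
    absolute_dose,
    default_rule_table,
    recommend,
    recommendation_report,
)
from cyp2c19sup.errors import StandardDoseUnavailableError, VocabularyError

from conftest import make_sample

FIRST_GEN_PLUS_DEX = [Drug.OMEPRAZOLE, Drug.LANSOPRAZOLE,
                      Drug.PANTOPRAZOLE, Drug.DEXLANSOPRAZOLE]


def pheno(label: Phenotype) -> PredictivePhenotype:
    return PredictivePhenotype(label, provisional=(label is Phenotype.AM))


def all_contexts():
    for drug, ind, flags in product(Drug, Indication,
                                    product([False, True], repeat=5)):
        yield ClinicalContext(
            drug=drug, indication=ind,
            chronic_over_12_weeks=flags[0], h_pylori_positive=flags[1],
            ppi_hypersensitivity=flags[2], genotype_available=flags[3],
            interacting_cyp_drug=flags[4])


class TestPrintedDoseRules:
    @pytest.mark.parametrize("drug", FIRST_GEN_PLUS_DEX)
    def test_um_sup_increase_100_percent(self, drug):
        rec = recommend(pheno(Phenotype.UM), ClinicalContext(drug=drug))
        assert rec.action is Action.INCREASE
        assert (rec.multiplier_low, rec.multiplier_high) == (2.0, 2.0)
        assert rec.split_dose_allowed

    @pytest.mark.parametrize("label",
                             [Phenotype.PM, Phenotype.IM, Phenotype.AM])
    @pytest.mark.parametrize("drug", FIRST_GEN_PLUS_DEX)
    def test_chronic_reduced_function_halves_dose(self, label, drug):
        rec = recommend(pheno(label), ClinicalContext(
            drug=drug, chronic_over_12_weeks=True))
        assert rec.action is Action.REDUCE_CONSIDER
        assert (rec.multiplier_low, rec.multiplier_high) == (0.5, 0.5)
        assert rec.preferred_agent == "rabeprazole"

    @pytest.mark.parametrize("drug,fold", [
        (Drug.OMEPRAZOLE, 3.0), (Drug.LANSOPRAZOLE, 4.0),
        (Drug.PANTOPRAZOLE, 5.0), (Drug.DEXLANSOPRAZOLE, 4.0),
    ])
    def test_um_h_pylori_eradication_folds(self, drug, fold):
        rec = recommend(pheno(Phenotype.UM), ClinicalContext(
            drug=drug, indication=Indication.H_PYLORI_ERADICATION))
        assert rec.action is Action.INCREASE
        assert rec.multiplier_low == rec.multiplier_high == fold

    @pytest.mark.parametrize("indication", [
        Indication.H_PYLORI_ERADICATION, Indication.EROSIVE_ESOPHAGITIS])
    @pytest.mark.parametrize("label", [Phenotype.EM, Phenotype.RM])
    def test_em_rm_acid_intensive_increase(self, label, indication):
        rec = recommend(pheno(label), ClinicalContext(
            drug=Drug.OMEPRAZOLE, indication=indication))
        assert rec.action is Action.INCREASE
        assert (rec.multiplier_low, rec.multiplier_high) == (1.5, 2.0)
        assert rec.split_dose_allowed

    def test_em_rm_sup_standard(self):
        for label in (Phenotype.EM, Phenotype.RM):
            rec = recommend(pheno(label),
                            ClinicalContext(drug=Drug.OMEPRAZOLE))
            assert rec.action is Action.STANDARD_DOSE
            assert rec.multiplier_low == rec.multiplier_high == 1.0

    def test_rabeprazole_standard_for_every_phenotype(self):
        for label in Phenotype:
            rec = recommend(pheno(label),
                            ClinicalContext(drug=Drug.RABEPRAZOLE))
            assert rec.action is Action.STANDARD_DOSE

    def test_esomeprazole_reduced_function_no_specific(self):
        for label in (Phenotype.PM, Phenotype.IM, Phenotype.AM):
            rec = recommend(pheno(label),
                            ClinicalContext(drug=Drug.ESOMEPRAZOLE))
            assert rec.action is Action.NO_SPECIFIC_RECOMMENDATION
            assert "CYP2C19" in rec.rationale

    def test_esomeprazole_um_eradication_increase(self):
        rec = recommend(pheno(Phenotype.UM), ClinicalContext(
            drug=Drug.ESOMEPRAZOLE,
            indication=Indication.H_PYLORI_ERADICATION))
        assert rec.action is Action.INCREASE
        assert (rec.multiplier_low, rec.multiplier_high) == (1.5, 2.0)

    def test_um_h_pylori_positive_sup_prefers_rabeprazole(self):
        rec = recommend(pheno(Phenotype.UM), ClinicalContext(
            drug=Drug.OMEPRAZOLE, h_pylori_positive=True))
        assert rec.action is Action.SWITCH_AGENT
        assert rec.preferred_agent == "rabeprazole"
        assert rec.multiplier_low == rec.multiplier_high == 1.0


class TestPriorityLogic:
    def test_hypersensitivity_dominates_everything(self):
        for label in Phenotype:
            p = pheno(label)
            for ctx in all_contexts():
                if not ctx.ppi_hypersensitivity:
                    continue
                rec = recommend(p, ctx)
                assert rec.action is Action.SWITCH_AGENT
                assert rec.preferred_agent == "H2RA/GMP"

    @pytest.mark.parametrize("label", list(Phenotype))
    def test_no_genotype_routes_to_rabeprazole(self, label):
        rec = recommend(pheno(label), ClinicalContext(
            drug=Drug.OMEPRAZOLE, genotype_available=False))
        assert rec.preferred_agent == "rabeprazole"
        assert rec.action is Action.SWITCH_AGENT

    def test_unknown_phenotype_routes_to_rabeprazole(self):
        rec = recommend(pheno(Phenotype.UNKNOWN),
                        ClinicalContext(drug=Drug.LANSOPRAZOLE))
        assert rec.preferred_agent == "rabeprazole"

    def test_interacting_drug_routes_to_rabeprazole(self):
        rec = recommend(pheno(Phenotype.EM), ClinicalContext(
            drug=Drug.OMEPRAZOLE, interacting_cyp_drug=True))
        assert rec.preferred_agent == "rabeprazole"

    def test_am_always_provisional(self):
        for ctx in all_contexts():
            assert recommend(pheno(Phenotype.AM), ctx).provisional


class TestEngineInvariants:
    def test_total_and_deterministic(self):
        table = default_rule_table()
        for label in Phenotype:
            p = pheno(label)
            for ctx in all_contexts():
                first = recommend(p, ctx, table)
                assert recommend(p, ctx, table) == first

    def test_never_increase_for_pm_im_never_reduce_for_um(self):
        for ctx in all_contexts():
            if ctx.drug not in FIRST_GEN_PLUS_DEX:
                continue
            for label in (Phenotype.PM, Phenotype.IM):
                assert recommend(pheno(label), ctx).action \
                    is not Action.INCREASE
            assert recommend(pheno(Phenotype.UM), ctx).action \
                is not Action.REDUCE_CONSIDER

    def test_rationales_map_one_to_one_to_rule_table(self):
        table = default_rule_table()
        by_id = table.rationale_by_id()
        seen = set()
        for label in Phenotype:
            p = pheno(label)
            for ctx in all_contexts():
                rec = recommend(p, ctx, table)
                assert by_id[rec.rule_id] == rec.rationale
                seen.add(rec.rule_id)
        assert seen == set(by_id)  # every shipped rule is reachable

    def test_vocabulary_errors(self):
        with pytest.raises(VocabularyError):
            ClinicalContext(drug="tenatoprazole")
        with pytest.raises(VocabularyError):
            ClinicalContext(drug="omeprazole", indication="GERD")


class TestAbsoluteDose:
    def test_standard_dose_table(self):
        expected = {"omeprazole": 20, "lansoprazole": 30, "pantoprazole": 20,
                    "esomeprazole": 20, "rabeprazole": 20}
        assert {d.value: s.dose_mg_per_day
                for d, s in STANDARD_DOSES.items()} == expected

    @pytest.mark.parametrize("label,drug,ctx_kwargs,expected", [
        (Phenotype.UM, Drug.OMEPRAZOLE, {}, (40.0, 40.0)),
        (Phenotype.PM, Drug.LANSOPRAZOLE,
         {"chronic_over_12_weeks": True}, (15.0, 15.0)),
        (Phenotype.EM, Drug.ESOMEPRAZOLE, {}, (20.0, 20.0)),
    ])
    def test_absolute_doses(self, label, drug, ctx_kwargs, expected):
        rec = recommend(pheno(label), ClinicalContext(drug=drug, **ctx_kwargs))
        assert absolute_dose(rec, drug) == expected

    def test_dexlansoprazole_has_no_standard_dose(self):
        rec = recommend(pheno(Phenotype.UM),
                        ClinicalContext(drug=Drug.DEXLANSOPRAZOLE))
        with pytest.raises(StandardDoseUnavailableError):
            absolute_dose(rec, Drug.DEXLANSOPRAZOLE)


class TestRecommendationReport:
    def test_six_sample_cohort_rows_with_rule_ids(
            self, nine_haplogenotype_samples):
        calls = call_cohort(nine_haplogenotype_samples[:5]
                            + [nine_haplogenotype_samples[6]])
        report = recommendation_report(
            calls, ClinicalContext(drug=Drug.OMEPRAZOLE))
        assert len(report.rows) == 6
        assert all(r["rule_id"] for r in report.rows)
        parsed = json.loads(report.to_json())
        assert len(parsed["recommendations"]) == 6
        assert report.to_text().count("\n") >= 6

    def test_empty_cohort_empty_report(self):
        report = recommendation_report(
            call_cohort([]), ClinicalContext(drug=Drug.OMEPRAZOLE))
        assert report.rows == []

    def test_unknown_phenotype_row_prefers_cyp2c19_independent(self):
        calls = call_cohort([make_sample("NC", "TT", "AA")])
        report = recommendation_report(
            calls, ClinicalContext(drug=Drug.OMEPRAZOLE))
        (row,) = report.rows
        assert row["phenotype"] == "UNKNOWN"
        assert row["preferred_agent"] == "rabeprazole"

    def test_uncallable_sample_reported_with_fallback(self):
        calls = call_cohort([make_sample("M", None, "GG")])
        report = recommendation_report(
            calls, ClinicalContext(drug=Drug.OMEPRAZOLE))
        (row,) = report.rows
        assert row["status"] == "uncallable"
        assert row["preferred_agent"] == "rabeprazole"
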