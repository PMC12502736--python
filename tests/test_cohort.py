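"""Case extraction, drug normalization, and the three exclusion schemes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_store
from pvsweet.cohort import (DrugNormalizer,
                            IndicationClassifier, build_dataset,
                            extract_cases, normalize_drug,
                            retained_primaryids)
from pvsweet.errors import DegenerateDatasetError


def corpus_with_cases(n=10, case_ids=(0, 1, 2), indications=None):
    demo = [{"primaryid": i, "caseid": i, "fda_dt": "20200101"}
            for i in range(n)]
    drug = [{"primaryid": i, "caseid": i, "drug_seq": 1, "role_cod": "PS",
             "drugname": "Azathioprine"} for i in range(n)]
    reac = [{"primaryid": i, "caseid": i,
             "pt": "Sweet syndrome" if i in case_ids else "Nausea"}
            for i in range(n)]
    indi = []
    for pid, terms in (indications or {}).items():
        for t in terms:
            indi.append({"primaryid": pid, "caseid": pid,
                         "indi_drug_seq": 1, "indi_pt": t})
    return make_store(demo=demo, drug=drug, reac=reac, indi=indi)


class TestExtractCases:
    def test_count_matches_planted_target_pt(self):
        store = corpus_with_cases(n=50, case_ids=tuple(range(37)))
        cases = extract_cases(store)
        assert cases.n_cases == 37

    def test_pt_match_is_case_insensitive(self):
        store = corpus_with_cases()
        store.tables["reac"].loc[0, "pt"] = "SWEET SYNDROME"
        assert extract_cases(store).n_cases == 3

    def test_case_with_only_concomitant_drugs_kept_without_exposure(self):
        store = corpus_with_cases(case_ids=(0,))
        store.tables["drug"].loc[0, "role_cod"] = "C"
        cases = extract_cases(store)
        assert cases.n_cases == 1
        assert 0 not in set(cases.ps_drugs["primaryid"])

    def test_absent_pt_gives_empty_set(self):
        store = corpus_with_cases(case_ids=())
        assert extract_cases(store).n_cases == 0


class TestNormalizer:
    def test_synonym_mapping(self):
        nz = DrugNormalizer(synonym_map={"humira": "adalimumab"}, atc_map={})
        assert normalize_drug("HUMIRA", nz) == "adalimumab"

    def test_trim_and_fold(self):
        nz = DrugNormalizer(synonym_map={}, atc_map={})
        assert normalize_drug("  Azathioprine ", nz) == "azathioprine"

    def test_unknown_passes_through_flagged(self):
        nz = DrugNormalizer(synonym_map={}, atc_map={})
        name, mapped = nz.normalize("xyzzy")
        assert name == "xyzzy" and mapped is False

    def test_atc_lookup_after_normalization(self):
        nz = DrugNormalizer()
        assert nz.atc(normalize_drug("Imuran", nz)) == ("L", "L04")


class TestIndicationClassifier:
    def test_flags_not_a_partition(self):
        cl = IndicationClassifier(malignancy_terms=["leukaemia"],
                                  immune_terms=["leukaemia", "colitis"])
        assert cl.classify("Acute myeloid leukaemia") == (True, True)

    def test_exact_mode_requires_equality(self):
        cl = IndicationClassifier(malignancy_terms=["leukaemia"],
                                  immune_terms=[], mode="exact")
        assert cl.classify("Acute myeloid leukaemia") == (False, False)
        assert cl.classify("Leukaemia") == (True, False)


class TestBuildDataset:
    def exclusion_store(self):
        # 100 reports: 20 malignancy-only, 10 immune-only, 5 both
        indications = {}
        for pid in range(20):
            indications[pid] = ["Acute myeloid leukaemia"]
        for pid in range(20, 30):
            indications[pid] = ["Ulcerative colitis"]
        for pid in range(30, 35):
            indications[pid] = ["Acute myeloid leukaemia", "Ulcerative colitis"]
        return corpus_with_cases(n=100, case_ids=(0, 40, 50),
                                 indications=indications)

    def test_inclusion_exclusion_counts(self):
        store = self.exclusion_store()
        ds_main = build_dataset(store, "main", ["azathioprine"])
        assert len(ds_main.frame) == 100 - 35
        ds_a = build_dataset(store, "sensitivity_A", ["azathioprine"])
        assert len(ds_a.frame) == 100 - 25
        ds_b = build_dataset(store, "sensitivity_B", ["azathioprine"])
        assert len(ds_b.frame) == 100 - 15

    def test_full_scheme_keeps_everything(self):
        ds = build_dataset(self.exclusion_store(), "full", ["azathioprine"])
        assert len(ds.frame) == 100

    def test_reports_without_indications_retained_everywhere(self):
        store = self.exclusion_store()
        cl = IndicationClassifier()
        retained = retained_primaryids(store, "main", cl)
        assert set(range(35, 100)) <= retained

    def test_all_excluded_raises_degenerate(self):
        store = corpus_with_cases(
            n=5, case_ids=(0,),
            indications={i: ["Lymphoma"] for i in range(5)})
        with pytest.raises(DegenerateDatasetError):
            build_dataset(store, "main", ["azathioprine"])

    def test_exposure_is_primary_suspect_only(self):
        store = corpus_with_cases(n=4, case_ids=(0,))
        store.tables["drug"].loc[3, "role_cod"] = "C"
        ds = build_dataset(store, "full", ["azathioprine"])
        expo = ds.frame.set_index("primaryid")["azathioprine"]
        assert expo[3] == 0 and expo[0] == 1

    def test_main_equals_intersection_of_sensitivities(self):
        store = self.exclusion_store()
        cl = IndicationClassifier()
        main = retained_primaryids(store, "main", cl)
        a = retained_primaryids(store, "sensitivity_A", cl)
        b = retained_primaryids(store, "sensitivity_B", cl)
        assert main == a & b


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                max_size=40))
def test_scheme_algebra_on_random_indication_patterns(flags):
    """main-retained = A-retained ∩ B-retained for every indication pattern."""
    indications = {}
    for pid, (mal, imm) in enumerate(flags):
        terms = []
        if mal:
            terms.append("Plasma cell myeloma")
        if imm:
            terms.append("Rheumatoid arthritis")
        if terms:
            indications[pid] = terms
    store = corpus_with_cases(n=len(flags), case_ids=(0,),
                              indications=indications)
    cl = IndicationClassifier()
    main = retained_primaryids(store, "main", cl)
    a = retained_primaryids(store, "sensitivity_A", cl)
    b = retained_primaryids(store, "sensitivity_B", cl)
    full = retained_primaryids(store, "full", cl)
    assert main == a & b
    assert main <= a <= full and main <= b <= full
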