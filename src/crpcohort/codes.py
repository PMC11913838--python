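"""Default ICD-9 / ATC concept code lists.

These lists are ILLUSTRATIVE, not authoritative: they cover the common codes a
primary-care phenotype for each concept would match, using the hierarchical
prefix semantics of both vocabularies (an ICD-9 code ``410.11`` matches the
prefix ``410``; an ATC code ``J01CA04`` matches ``J01``).  Production use
against a real database should replace them, via the ``code_lists`` section of
the run configuration, with locally validated lists.
"""

from __future__ import annotations

from .model import CodeList

ICD9 = "ICD9"
ATC = "ATC"


def _c(name: str, system: str, *prefixes: str) -> CodeList:
    return CodeList(name=name, system=system, prefixes=tuple(prefixes))


#: Malignant neoplasms span ICD-9 chapters 140-208.
_MALIGNANCY_PREFIXES = tuple(str(i) for i in range(140, 209))

DEFAULT_CODE_LISTS: dict[str, CodeList] = {
    # --- ASCVD subtypes (diagnosis) ---
    "ascvd_coronary": _c("ascvd_coronary", ICD9, "410", "411", "412", "413", "414"),
    "ascvd_cerebrovascular": _c(
        "ascvd_cerebrovascular", ICD9, "433", "434", "435", "436", "437", "438"
    ),
    "ascvd_pad": _c("ascvd_pad", ICD9, "440.2", "443", "444"),
    "ascvd_other": _c(
        "ascvd_other", ICD9, "440.0", "440.1", "440.8", "440.9", "441", "442"
    ),
    # --- patient-level exclusions ---
    "chronic_infection": _c(
        # HIV, tuberculosis, viral hepatitis
        "chronic_infection", ICD9,
        "042", "010", "011", "012", "013", "014", "015", "016", "017", "018", "070",
    ),
    # --- CRP eligibility triggers ---
    "malignancy": _c("malignancy", ICD9, *_MALIGNANCY_PREFIXES),
    "non_melanoma_skin_cancer": _c("non_melanoma_skin_cancer", ICD9, "173"),
    "antibiotic_antiviral": _c("antibiotic_antiviral", ATC, "J01", "J05"),
    "immunosuppressant": _c("immunosuppressant", ATC, "L04"),
    # --- renal ---
    "ckd_stage3_plus": _c("ckd_stage3_plus", ICD9, "585.3", "585.4", "585.5", "585.6"),
    # --- comorbidities (any time before index) ---
    "diabetes": _c("diabetes", ICD9, "250"),
    "hypertension": _c("hypertension", ICD9, "401", "402", "403", "404", "405"),
    "copd": _c("copd", ICD9, "490", "491", "492", "494", "496"),
    "dementia": _c("dementia", ICD9, "290", "331.0"),
    "heart_failure": _c("heart_failure", ICD9, "428"),
    "atrial_fibrillation": _c("atrial_fibrillation", ICD9, "427.3"),
    "ibd": _c("ibd", ICD9, "555", "556"),
    "rheumatoid_disease": _c("rheumatoid_disease", ICD9, "710", "714", "720"),
    "cns_inflammatory_disease": _c("cns_inflammatory_disease", ICD9, "323", "340"),
    "liver_disease": _c("liver_disease", ICD9, "571"),
    # sensitivity analysis: chronic inflammatory / rheumatoid conditions
    "inflammatory_rheumatoid": _c(
        "inflammatory_rheumatoid", ICD9, "555", "556", "710", "714", "720", "323", "340"
    ),
    # --- drug classes (prescriptions, ATC) ---
    "corticosteroids": _c("corticosteroids", ATC, "H02"),
    "immunosuppressants_rx": _c("immunosuppressants_rx", ATC, "L04"),
    "antibiotics_antivirals_antimycotics": _c(
        "antibiotics_antivirals_antimycotics", ATC, "J01", "J02", "J05"
    ),
    "antibiotics": _c("antibiotics", ATC, "J01"),
    "antivirals": _c("antivirals", ATC, "J05"),
    "antimycotics": _c("antimycotics", ATC, "J02"),
    "antiplatelet": _c("antiplatelet", ATC, "B01AC"),
    "aspirin": _c("aspirin", ATC, "B01AC06", "N02BA01"),
    "anticoagulants": _c("anticoagulants", ATC, "B01AA", "B01AE", "B01AF"),
    "nsaids": _c("nsaids", ATC, "M01A"),
    "acei_arb": _c("acei_arb", ATC, "C09"),
    "mra": _c("mra", ATC, "C03DA"),
    "beta_blockers": _c("beta_blockers", ATC, "C07"),
    "diuretics": _c("diuretics", ATC, "C03"),
    "calcium_channel_blockers": _c("calcium_channel_blockers", ATC, "C08"),
    "glucose_lowering": _c("glucose_lowering", ATC, "A10"),
    "sglt2_inhibitors": _c("sglt2_inhibitors", ATC, "A10BK"),
    "glp1_receptor_agonists": _c("glp1_receptor_agonists", ATC, "A10BJ"),
    "statins": _c("statins", ATC, "C10AA", "C10BA"),
    "other_lipid_lowering": _c("other_lipid_lowering", ATC, "C10AX"),
    "ezetimibe": _c("ezetimibe", ATC, "C10AX09"),
    "pcsk9_inhibitors": _c("pcsk9_inhibitors", ATC, "C10AX13", "C10AX14"),
    "omega3": _c("omega3", ATC, "C10AX06"),
    "fibrates_resins_nicotinic": _c(
        "fibrates_resins_nicotinic", ATC, "C10AB", "C10AC", "C10AD"
    ),
    "other_bp_medications": _c("other_bp_medications", ATC, "C02"),
    "colchicine": _c("colchicine", ATC, "M04AC01"),
}

#: Drug-class concepts reported in the utilization tables, in display order.
UTILIZATION_CLASSES: tuple[str, ...] = (
    "corticosteroids",
    "immunosuppressants_rx",
    "antibiotics_antivirals_antimycotics",
    "antibiotics",
    "antivirals",
    "antimycotics",
    "antiplatelet",
    "aspirin",
    "anticoagulants",
    "nsaids",
    "acei_arb",
    "mra",
    "beta_blockers",
    "diuretics",
    "calcium_channel_blockers",
    "glucose_lowering",
    "sglt2_inhibitors",
    "glp1_receptor_agonists",
    "statins",
    "other_lipid_lowering",
    "ezetimibe",
    "pcsk9_inhibitors",
    "omega3",
    "fibrates_resins_nicotinic",
    "other_bp_medications",
    "colchicine",
)

#: Comorbidity concepts reported in the baseline tables, in display order.
COMORBIDITY_CONCEPTS: tuple[str, ...] = (
    "diabetes",
    "hypertension",
    "copd",
    "dementia",
    "heart_failure",
    "atrial_fibrillation",
    "ibd",
    "rheumatoid_disease",
    "cns_inflammatory_disease",
    "liver_disease",
)

#: Representative concrete codes used by the synthetic-data generator when it
#: emits an event for a concept (one valid member per concept).
REPRESENTATIVE_CODES: dict[str, str] = {
    "ascvd_coronary": "410.91",
    "ascvd_cerebrovascular": "434.91",
    "ascvd_pad": "443.9",
    "ascvd_other": "440.9",
    "chronic_infection": "042",
    "malignancy": "153.9",
    "non_melanoma_skin_cancer": "173.9",
    "antibiotic_antiviral": "J01CA04",
    "immunosuppressant": "L04AA06",
    "ckd_stage3_plus": "585.3",
    "diabetes": "250.00",
    "hypertension": "401.9",
    "copd": "496",
    "dementia": "290.0",
    "heart_failure": "428.0",
    "atrial_fibrillation": "427.31",
    "ibd": "555.9",
    "rheumatoid_disease": "714.0",
    "cns_inflammatory_disease": "340",
    "liver_disease": "571.5",
    "corticosteroids": "H02AB06",
    "immunosuppressants_rx": "L04AA06",
    "antibiotics": "J01CA04",
    "antivirals": "J05AB01",
    "antimycotics": "J02AC01",
    "antiplatelet": "B01AC04",
    "aspirin": "B01AC06",
    "anticoagulants": "B01AA03",
    "nsaids": "M01AE01",
    "acei_arb": "C09AA02",
    "mra": "C03DA01",
    "beta_blockers": "C07AB07",
    "diuretics": "C03CA01",
    "calcium_channel_blockers": "C08CA01",
    "glucose_lowering": "A10BA02",
    "sglt2_inhibitors": "A10BK01",
    "glp1_receptor_agonists": "A10BJ06",
    "statins": "C10AA05",
    "other_lipid_lowering": "C10AX09",
    "ezetimibe": "C10AX09",
    "pcsk9_inhibitors": "C10AX13",
    "omega3": "C10AX06",
    "fibrates_resins_nicotinic": "C10AB05",
    "other_bp_medications": "C02AC01",
    "colchicine": "M04AC01",
}
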