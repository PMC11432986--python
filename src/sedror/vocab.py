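"""Bundled mini-vocabulary: MedDRA-style PT -> SOC labels and drug pools.

MedDRA itself is licence-encumbered, so the package ships only a small
curated vocabulary sufficient for the analysis: the rhabdomyolysis target
term, the default set of PTs indicative of rhabdomyolysis (signs, symptoms
and laboratory findings consistent with muscle breakdown), and a background
vocabulary spanning the System Organ Classes seen in sedative reports.
Users can extend or override any of these with their own term files.
"""

from __future__ import annotations

from .model import PtTerm, normalize_text

# System Organ Class labels (spontaneous-report usage)
SOC_BLOOD = "Blood and lymphatic system disorders"
SOC_CARDIAC = "Cardiac disorders"
SOC_CONGENITAL = "Congenital, familial, and genetic disorders"
SOC_EAR = "Ear and labyrinth disorders"
SOC_ENDOCRINE = "Endocrine disorders"
SOC_EYE = "Eye disorders"
SOC_GI = "Gastrointestinal disorders"
SOC_GENERAL = "General disorders and administration site conditions"
SOC_HEPATO = "Hepatobiliary disorders"
SOC_INFECTION = "Infections and infestations"
SOC_INJURY = "Injury, poisoning, and procedural complications"
SOC_INVESTIGATIONS = "Investigations"
SOC_METABOLISM = "Metabolism and nutrition disorders"
SOC_MUSCULO = "Musculoskeletal and connective tissue disorders"
SOC_NEOPLASM = "Neoplasms, benign, malignant, and unspecified (incl cysts and polyps)"
SOC_NERVOUS = "Nervous system disorders"
SOC_PSYCH = "Psychiatric disorders"
SOC_RENAL = "Renal and urinary disorders"
SOC_REPRO = "Reproductive system and breast disorders"
SOC_RESPIRATORY = "Respiratory, thoracic, and mediastinal disorders"
SOC_SKIN = "Skin and subcutaneous tissue disorders"
SOC_SOCIAL = "Social circumstances"
SOC_SURGICAL = "Surgical and medical procedures"
SOC_VASCULAR = "Vascular disorders"

ALL_SOCS = [
    SOC_BLOOD, SOC_CARDIAC, SOC_CONGENITAL, SOC_EAR, SOC_ENDOCRINE, SOC_EYE,
    SOC_GI, SOC_GENERAL, SOC_HEPATO, SOC_INFECTION, SOC_INJURY,
    SOC_INVESTIGATIONS, SOC_METABOLISM, SOC_MUSCULO, SOC_NEOPLASM,
    SOC_NERVOUS, SOC_PSYCH, SOC_RENAL, SOC_REPRO, SOC_RESPIRATORY, SOC_SKIN,
    SOC_SOCIAL, SOC_SURGICAL, SOC_VASCULAR,
]

TARGET_PT = PtTerm("Rhabdomyolysis", SOC_MUSCULO)

# PTs indicative of rhabdomyolysis: myoglobin release markers, muscle enzyme
# elevations, muscle signs/symptoms, dark urine and reduced urine output.
INDICATIVE_PTS: list[PtTerm] = [
    TARGET_PT,
    PtTerm("Myoglobinuria", SOC_RENAL),
    PtTerm("Myoglobin urine present", SOC_INVESTIGATIONS),
    PtTerm("Blood myoglobin increased", SOC_INVESTIGATIONS),
    PtTerm("Blood myoglobin present", SOC_INVESTIGATIONS),
    PtTerm("Blood creatine phosphokinase increased", SOC_INVESTIGATIONS),
    PtTerm("Blood creatine phosphokinase abnormal", SOC_INVESTIGATIONS),
    PtTerm("Myalgia", SOC_MUSCULO),
    PtTerm("Muscular weakness", SOC_MUSCULO),
    PtTerm("Muscle necrosis", SOC_MUSCULO),
    PtTerm("Chromaturia", SOC_RENAL),
    PtTerm("Blood lactate dehydrogenase increased", SOC_INVESTIGATIONS),
    PtTerm("Aspartate aminotransferase increased", SOC_INVESTIGATIONS),
    PtTerm("Alanine aminotransferase increased", SOC_INVESTIGATIONS),
    PtTerm("Oliguria", SOC_RENAL),
]

# Background vocabulary for non-target events; excludes all indicative PTs.
BACKGROUND_PTS: list[PtTerm] = [
    PtTerm("Anaemia", SOC_BLOOD),
    PtTerm("Thrombocytopenia", SOC_BLOOD),
    PtTerm("Leukocytosis", SOC_BLOOD),
    PtTerm("Bradycardia", SOC_CARDIAC),
    PtTerm("Tachycardia", SOC_CARDIAC),
    PtTerm("Cardiac arrest", SOC_CARDIAC),
    PtTerm("Congenital metabolic disorder", SOC_CONGENITAL),
    PtTerm("Mitochondrial myopathy", SOC_CONGENITAL),
    PtTerm("Vertigo", SOC_EAR),
    PtTerm("Tinnitus", SOC_EAR),
    PtTerm("Adrenal insufficiency", SOC_ENDOCRINE),
    PtTerm("Inappropriate antidiuretic hormone secretion", SOC_ENDOCRINE),
    PtTerm("Mydriasis", SOC_EYE),
    PtTerm("Visual impairment", SOC_EYE),
    PtTerm("Diplopia", SOC_EYE),
    PtTerm("Nausea", SOC_GI),
    PtTerm("Vomiting", SOC_GI),
    PtTerm("Diarrhoea", SOC_GI),
    PtTerm("Pyrexia", SOC_GENERAL),
    PtTerm("Fatigue", SOC_GENERAL),
    PtTerm("Multiple organ dysfunction syndrome", SOC_GENERAL),
    PtTerm("Hepatic failure", SOC_HEPATO),
    PtTerm("Hepatitis", SOC_HEPATO),
    PtTerm("Hepatomegaly", SOC_HEPATO),
    PtTerm("Pneumonia", SOC_INFECTION),
    PtTerm("Sepsis", SOC_INFECTION),
    PtTerm("Urinary tract infection", SOC_INFECTION),
    PtTerm("Overdose", SOC_INJURY),
    PtTerm("Medication error", SOC_INJURY),
    PtTerm("Anaesthetic complication", SOC_INJURY),
    PtTerm("Blood pressure decreased", SOC_INVESTIGATIONS),
    PtTerm("Heart rate decreased", SOC_INVESTIGATIONS),
    PtTerm("Body temperature increased", SOC_INVESTIGATIONS),
    PtTerm("Metabolic acidosis", SOC_METABOLISM),
    PtTerm("Hyperkalaemia", SOC_METABOLISM),
    PtTerm("Lactic acidosis", SOC_METABOLISM),
    PtTerm("Muscle spasms", SOC_MUSCULO),
    PtTerm("Pain in extremity", SOC_MUSCULO),
    PtTerm("Musculoskeletal stiffness", SOC_MUSCULO),
    PtTerm("Tumour lysis syndrome", SOC_NEOPLASM),
    PtTerm("Neoplasm malignant", SOC_NEOPLASM),
    PtTerm("Somnolence", SOC_NERVOUS),
    PtTerm("Seizure", SOC_NERVOUS),
    PtTerm("Coma", SOC_NERVOUS),
    PtTerm("Agitation", SOC_PSYCH),
    PtTerm("Delirium", SOC_PSYCH),
    PtTerm("Hallucination", SOC_PSYCH),
    PtTerm("Acute kidney injury", SOC_RENAL),
    PtTerm("Renal failure", SOC_RENAL),
    PtTerm("Anuria", SOC_RENAL),
    PtTerm("Erectile dysfunction", SOC_REPRO),
    PtTerm("Amenorrhoea", SOC_REPRO),
    PtTerm("Respiratory depression", SOC_RESPIRATORY),
    PtTerm("Apnoea", SOC_RESPIRATORY),
    PtTerm("Hypoxia", SOC_RESPIRATORY),
    PtTerm("Rash", SOC_SKIN),
    PtTerm("Pruritus", SOC_SKIN),
    PtTerm("Hyperhidrosis", SOC_SKIN),
    PtTerm("Alcohol use", SOC_SOCIAL),
    PtTerm("Drug abuser", SOC_SOCIAL),
    PtTerm("Intubation", SOC_SURGICAL),
    PtTerm("Dialysis", SOC_SURGICAL),
    PtTerm("Hypotension", SOC_VASCULAR),
    PtTerm("Hypertension", SOC_VASCULAR),
    PtTerm("Circulatory collapse", SOC_VASCULAR),
]

_PT_INDEX: dict[str, PtTerm] = {
    pt.key: pt for pt in INDICATIVE_PTS + BACKGROUND_PTS
}


def lookup_pt(name: str, soc: str = "") -> PtTerm:
    """Resolve a PT name against the bundled vocabulary.

    Unknown names are returned as new terms carrying the supplied SOC
    (user-supplied extensions pass through untouched).
    """
    known = _PT_INDEX.get(normalize_text(name))
    if known is not None and (not soc or known.soc == soc):
        return known
    return PtTerm(name, soc)


def background_pts_for_soc(soc: str) -> list[PtTerm]:
    pts = [pt for pt in BACKGROUND_PTS if pt.soc == soc]
    if not pts:
        raise KeyError(f"no background PT for SOC {soc!r}")
    return pts


# Drug pools used by the synthetic-report generator (name, ATC).
CO_SUSPECT_DRUGS: list[tuple[str, str]] = [
    ("fentanyl", "N01AH01"),
    ("remifentanil", "N01AH06"),
    ("ketamine", "N01AX03"),
    ("etomidate", "N01AX07"),
    ("sevoflurane", "N01AB08"),
    ("rocuronium", "M03AC09"),
    ("suxamethonium", "M03AB01"),
    ("atorvastatin", "C10AA05"),
    ("quetiapine", "N05AH04"),
    ("morphine", "N02AA01"),
]

CONCOMITANT_DRUGS: list[tuple[str, str]] = [
    ("fentanyl", "N01AH01"),
    ("sevoflurane", "N01AB08"),
    ("lidocaine", "N01BB02"),
    ("paracetamol", "N02BE01"),
    ("morphine", "N02AA01"),
    ("quetiapine", "N05AH04"),
    ("haloperidol", "N05AD01"),
    ("furosemide", "C03CA01"),
    ("noradrenaline", "C01CA03"),
    ("heparin", "B01AB01"),
]
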