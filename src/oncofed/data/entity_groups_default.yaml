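# Default cancer entity-group map: 24 labeled groups over ICD-10-GM codes,
# plus a fallback group for everything unmatched.  The grouping is a
# best-effort reconstruction of common registry reporting groups; edit freely.
# Matching is first-match-wins in the order below; a bare three-character
# category (e.g. "C50") matches all of its subcodes, a range ("C18-C21")
# matches every category in the range, and a dotted spec ("D09.0") matches
# only that subcode.
fallback: other
groups:
  - label: breast
    icd10: ["C50", "D05"]
  - label: prostate
    icd10: ["C61"]
  - label: melanoma
    icd10: ["C43"]
  - label: lung
    icd10: ["C33-C34"]
  - label: lip_oral_pharynx
    icd10: ["C00-C14"]
  - label: colorectum
    icd10: ["C18-C21"]
  - label: non_hodgkin_lymphoma
    icd10: ["C82-C88"]
  - label: cervix
    icd10: ["C53", "D06"]
  - label: pancreas
    icd10: ["C25"]
  - label: thyroid
    icd10: ["C73"]
  - label: larynx
    icd10: ["C32"]
  - label: esophagus
    icd10: ["C15"]
  - label: bladder
    icd10: ["C67", "D09.0"]
  - label: liver
    icd10: ["C22"]
  - label: kidney
    icd10: ["C64"]
  - label: stomach
    icd10: ["C16"]
  - label: leukemia
    icd10: ["C91-C95"]
  - label: uterus
    icd10: ["C54-C55"]
  - label: ovary
    icd10: ["C56"]
  - label: testis
    icd10: ["C62"]
  - label: hodgkin_lymphoma
    icd10: ["C81"]
  - label: brain_cns
    icd10: ["C70-C72"]
  - label: multiple_myeloma
    icd10: ["C90"]
  - label: biliary
    icd10: ["C23-C24"]
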