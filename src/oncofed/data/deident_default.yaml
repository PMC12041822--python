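# Default deidentification rule set: pseudonymize the patient identifier
# within the "patient" domain, strip the quasi-identifier, keep the three
# analysis fields.  The list is ordered; fields not named fall under
# default_action.
default_action: keep
rules:
  - resource_type: Patient
    field_path: Patient.identifier
    action: pseudonymize
    domain: patient
  - resource_type: Patient
    field_path: Patient.quasi_identifier
    action: remove
  - resource_type: Patient
    field_path: Patient.gender
    action: keep
  - resource_type: Condition
    field_path: Condition.code
    action: keep
  - resource_type: Condition
    field_path: Condition.onset_date
    action: keep
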