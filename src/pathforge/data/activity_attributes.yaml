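# Kind-specific descriptive attributes for activities.
#
# This file is the "customized form" definition used during formalization:
# for each activity kind it lists which attributes a domain expert must
# supply (required) and which are helpful but optional.  Extending a kind
# means editing this file, not the code.  'name' is required for every kind.
procedure:
  required: [name, ops_code]
  optional: [laterality, anesthesia, setting]
medication:
  required: [name, substance, dosage, route]
  optional: [frequency, duration]
encounter:
  required: [name, encounter_type]
  optional: [location, admission_source]
observation:
  required: [name, target]
  optional: [method, specimen, frequency]
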