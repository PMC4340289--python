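# Rendering templates for the DOC.Path-like reference target system.
#
# Templates are data: adding or adapting a target system means editing a
# profile, a mapping and a template file of this shape -- no code change.
# Each representation option carries one template per dialect; every
# template emits exactly one unit (one primary INSERT, or one XML element
# carrying an element="..." attribute) so unit counts can be audited
# independently of the renderer.
#
# Substitution variables: $node $element_id $label $kind $payload $day $scope
# ($day is a quoted phase_day id or NULL / empty; values arrive pre-escaped
# for the dialect).

dialect_set: docpath

# dimension id -> label shown in the calendric view
dimensions:
  diagnosis: Diagnosis
  phase: Phase
  medication: Medication
  order: Orders
  encounter: Encounters
  information: Information

options:
  "docpath:InclusionDiagnosis":
    dimension: diagnosis
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', NULL, 'diagnosis', 'diagnosis', '$label', '$payload');
    xml_container: "dimension:diagnosis"
    xml_fragment: '<entry element="$node" kind="diagnosis" label="$label" payload="$payload"/>'

  "docpath:PhaseDimension":
    dimension: phase
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', $day, 'phase', 'phase', '$label', '$payload');
    xml_container: "dimension:phase"
    xml_fragment: '<entry element="$node" kind="phase" label="$label" day="$day"/>'

  "docpath:OptionalElement":
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', $day, NULL, 'optional', '$label', '$payload');
    xml_container: optionalElements
    xml_fragment: '<optionalElement element="$node" label="$label" day="$day"/>'

  "docpath:Prescription":
    dimension: medication
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', $day, 'medication', 'prescription', '$label', '$payload');
    xml_container: "dimension:medication"
    xml_fragment: '<entry element="$node" kind="prescription" label="$label" day="$day" payload="$payload"/>'

  "docpath:Order":
    dimension: order
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', $day, 'order', 'order', '$label', '$payload');
    xml_container: "dimension:order"
    xml_fragment: '<entry element="$node" kind="order" label="$label" day="$day" payload="$payload"/>'

  "docpath:AdmissionEntry":
    dimension: encounter
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', $day, 'encounter', 'admission', '$label', '$payload');
    xml_container: "dimension:encounter"
    xml_fragment: '<entry element="$node" kind="admission" label="$label" day="$day"/>'

  "docpath:InformationDimension":
    dimension: information
    relational: >-
      INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
      VALUES ('$node', NULL, 'information', 'information', '$label', '$payload');
    xml_container: "dimension:information"
    xml_fragment: '<entry element="$node" kind="information" label="$label" payload="$payload"/>'

  "docpath:TextualDescription":
    relational: >-
      INSERT INTO attachment (element_id, kind, content)
      VALUES ('$node', 'text', '$payload');
    xml_container: attachments
    xml_fragment: '<attachment element="$node" target="$scope" kind="text">$payload</attachment>'

  "docpath:DocumentLink":
    relational: >-
      INSERT INTO attachment (element_id, kind, content)
      VALUES ('$node', 'document', '$payload');
    xml_container: attachments
    xml_fragment: '<attachment element="$node" target="$scope" kind="document">$payload</attachment>'
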