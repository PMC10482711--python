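# PT -> clinical symptom category mapping for co-reported withdrawal
# symptoms.  Editable: spontaneous reports code symptoms at PT level while
# summaries and the co-occurrence network aggregate to these categories.
respiratory symptoms:
  - dyspnoea
  - apnoea
  - respiratory distress
  - respiratory depression
  - tachypnoea
  - cyanosis
irritability/agitation:
  - irritability
  - agitation
  - crying
  - restlessness
tremor:
  - tremor
  - tremor neonatal
feeding problems:
  - feeding disorder
  - feeding disorder neonatal
  - poor feeding infant
  - vomiting
seizures:
  - seizure
  - convulsion neonatal
  - clonic convulsion
muscle symptoms:
  - hypertonia
  - hypotonia
  - muscle rigidity
somnolence:
  - somnolence
  - lethargy
pyrexia:
  - pyrexia
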