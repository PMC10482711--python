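# Case-defining reaction terms for neonatal withdrawal syndrome.
# A report is a case when any reaction preferred term (PT) matches case_pts,
# or any attached standardized-query tag matches case_smqs, AND the patient
# is a neonate (age window configured separately, default 1-27 days).
case_pts:
  - withdrawal syndrome
  - drug withdrawal syndrome
  - drug withdrawal syndrome neonatal
  - antidepressants discontinuation syndrome
  - drug withdrawal headache
  - drug withdrawal convulsions
  - drug withdrawal maintenance therapy
case_smqs:
  - drug withdrawal
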