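# Psychotropic co-medication classes considered potential confounders for
# neonatal withdrawal syndrome (themselves capable of causing it).  Used for
# the monotherapy flag, the confounder-free count of the priority score, and
# the network subset.  Drug-level membership is editable config: class names
# are fixed by the analysis, the lists are a pragmatic minimal formulary.
# Antidepressants themselves are handled by the drug-class map (a second
# antidepressant in any role also breaks monotherapy).
benzodiazepine:
  - diazepam
  - lorazepam
  - clonazepam
  - oxazepam
  - alprazolam
  - zolpidem
  - zopiclone
antipsychotic:
  - haloperidol
  - olanzapine
  - quetiapine
  - risperidone
  - aripiprazole
  - chlorpromazine
opioid:
  - methadone
  - morphine
  - buprenorphine
  - oxycodone
  - tramadol
  - fentanyl
  - codeine
mood_stabilizer:
  - lithium
  - valproate
  - lamotrigine
  - carbamazepine
  - gabapentin
  - pregabalin
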