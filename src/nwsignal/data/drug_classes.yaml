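# Antidepressant classification (ATC-based) used for exposure flagging.
# 27 antidepressants in three classes; methadone serves as the positive
# control comparator (an opioid with an established causal relation to
# neonatal withdrawal).
positive_control: methadone
classes:
  tca:
    amitriptyline: N06AA09
    clomipramine: N06AA04
    desipramine: N06AA01
    doxepin: N06AA12
    imipramine: N06AA02
    lofepramine: N06AA07
    nortriptyline: N06AA10
  ssri:
    citalopram: N06AB04
    escitalopram: N06AB10
    fluoxetine: N06AB03
    fluvoxamine: N06AB08
    paroxetine: N06AB05
    sertraline: N06AB06
  other_antidepressant:
    agomelatine: N06AX22
    bupropion: N06AX12
    desvenlafaxine: N06AX23
    duloxetine: N06AX21
    mianserin: N06AX03
    milnacipran: N06AX17
    mirtazapine: N06AX11
    nefazodone: N06AX06
    reboxetine: N06AX18
    saint john's wort: N06AX25
    trazodone: N06AX05
    venlafaxine: N06AX16
    vilazodone: N06AX24
    vortioxetine: N06AX26
# Drug-name synonyms normalized at lookup (herbals lack a unique common ATC).
synonyms:
  hypericum perforatum: saint john's wort
  st john's wort: saint john's wort
  st. john's wort: saint john's wort
atc_positive_control: N07BC02
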