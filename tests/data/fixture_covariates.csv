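subject_id,torsion
S00,9.97
S01,10.64
S02,16.57
S03,26.16
S04,16.5
S05,19.68
S06,17.52
S07,17.72
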