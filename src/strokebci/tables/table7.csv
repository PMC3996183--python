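test,accuracy
H1,100.0
H2,90.0
H3,95.0
H4,80.0
H5,87.5
H6,97.5
H7,92.5
H8,95.0
H9,95.0
H10,85.0
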