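test,accuracy
S1E,87.5
S1L,62.5
S2E,52.5
S2L,55.0
S3E,75.0
S3L,87.5
S4E,65.0
S4L,65.0
S5E,82.5
S5L,90.0
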