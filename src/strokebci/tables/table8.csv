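train,test,accuracy
S1E,S1L,82.5
S2E,S2L,72.5
S3E,S3L,95.0
S4E,S4L,62.5
S5E,S5L,75.0
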