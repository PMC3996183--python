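dataset,rank1,rank2,rank3,rank4
S1E,16-20,12-16,8-12,16-20
S1L,8-12,4-8,8-12,4-8
S2E,8-12,8-12,12-16,20-24
S2L,36-40,32-36,32-36,12-16
S3E,12-16,8-12,16-20,20-24
S3L,12-16,12-16,16-20,12-16
S4E,24-28,8-12,16-20,20-24
S4L,24-28,12-16,20-24,16-20
S5E,16-20,12-16,24-28,16-20
S5L,4-8,4-8,8-12,4-8
H1,16-20,20-24,16-20,16-20
H2,24-28,36-40,20-24,24-28
H3,36-40,16-20,24-28,36-40
H4,16-20,16-20,20-24,16-20
H5,20-24,24-28,20-24,16-20
H6,12-16,8-12,12-16,12-16
H7,12-16,16-20,16-20,12-16
H8,20-24,16-20,20-24,24-28
H9,12-16,16-20,8-12,16-20
H10,20-24,16-20,20-24,16-20
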