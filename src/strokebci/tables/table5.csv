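test,H1,H2,H3,H4,H5,H6,H7,H8,H9,H10
S1E,62.5,75.0,97.5,85.0,72.5,47.5,87.5,90.0,87.5,72.5
S1L,75.0,70.0,80.0,75.0,42.5,77.5,57.5,70.0,82.5,67.5
S2E,70.0,62.5,60.0,77.5,50.0,62.5,70.0,50.0,87.5,65.0
S2L,57.5,50.0,55.0,55.0,40.0,55.0,60.0,52.5,62.5,57.5
S3E,75.0,53.1,81.3,75.0,62.5,78.1,84.4,78.1,81.3,75.0
S3L,77.5,60.0,87.5,72.5,52.5,85.0,70.0,80.0,92.5,90.0
S4E,70.0,57.5,40.0,65.0,60.0,65.0,67.5,52.5,62.5,72.5
S4L,52.5,70.0,40.0,50.0,55.0,70.0,47.5,55.0,60.0,57.5
S5E,90.0,55.0,65.0,90.0,75.0,80.0,55.0,72.5,65.0,72.5
S5L,82.5,57.5,60.0,77.5,80.0,55.0,47.5,85.0,70.0,95.0
H1,,72.5,75.0,92.5,97.5,97.5,87.5,100.0,97.5,100.0
H2,62.5,,37.5,62.5,80.0,55.0,67.5,90.0,55.0,82.5
H3,95.0,65.0,,85.0,80.0,65.0,87.5,95.0,80.0,90.0
H4,80.0,72.5,77.5,,57.5,65.0,77.5,82.5,90.0,90.0
H5,85.0,72.5,55.0,52.5,,52.5,65.0,80.0,60.0,85.0
H6,100.0,65.0,65.0,97.5,87.5,,80.0,70.0,95.0,87.5
H7,92.5,65.0,92.5,82.5,87.5,72.5,,92.5,92.5,65.0
H8,100.0,80.0,60.0,90.0,90.0,80.0,72.5,,90.0,92.5
H9,95.0,55.0,67.5,97.5,80.0,92.5,65.0,100.0,,97.5
H10,87.5,67.5,80.0,85.0,85.0,87.5,70.0,95.0,100.0,
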