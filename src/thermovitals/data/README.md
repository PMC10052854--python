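# Packaged validation tables

`table1.csv` is a transcription of the published per-session validation
table for the zoo thermography study (58 imaging sessions across 52
species): covariates, video quality score, and true vs IRT-derived
respiration and heart rates.  Several rows in the published table are
typographically run together; every cell whose reading is uncertain carries
an explanation in the `transcription_notes` column rather than a silent
guess.  `true_measured` marks sessions with a reference measurement
(the n = 44 validation set) even where its numeric value is unrecoverable.

`table2.csv` records the published per-group sample sizes and success
percentages (sedation status, taxa, integument thickness, video quality,
subcutaneous fat); 2x2 counts implied by these percentages feed the
chi-squared analyses.
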