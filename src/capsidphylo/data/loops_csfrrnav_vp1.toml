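# Surface-loop boundaries of CsfrRNAV VP1 (author residue numbering,
# modeled range 625-894).  The loops are defined graphically in the
# structure figures rather than by residue number, so these inclusive
# ranges are approximate working definitions; edit them to taste and pass
# the file to `capsidphylo profile --regions`.
"CD-Loop" = "700-720"
"E1E2-Loop" = "766-793"
"EF-Loop" = "806-836"
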