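# RNBS-B minor
GSRIIITTRN
GSKIIITTRD
GSRIVITTRN
GSRIIITSRN
GSRLIITTRN
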