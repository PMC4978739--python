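# RNBS-D minor
CFLYCSLFPED
CFLYCALFPED
CFLYCSLFPKD
CLLYCSLFPED
CFLYCSLYPED
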