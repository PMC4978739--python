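# kinase-2 major
KRYLIVLDDVW
KRYLLVLDDVW
KKYLIVLDDVW
KRFLIVLDDVW
KRYLIVIDDVW
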