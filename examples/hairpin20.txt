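# a 20-nt unconstrained hairpin target
>hairpin20
NNNNNNNNNNNNNNNNNNNN
((((((((....))))))))
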