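# one sequence, two alternative conformations:
# a long stem with a double loop, or two separate hairpins
>alt_switch
NNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNN
((((..((((((....))))))......))))
((((....))))....((((((....))))))
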