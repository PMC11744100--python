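# Com-binding 19-mer duplex design; the bipartite GAD(N)2HC motif is fixed
>mom19_dimer
GADNNHCNNNGAGNNNNNN&GADNNHCNNNGAGNNNNNN
(((((((((.(((((((((&))))))))).)))))))))
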