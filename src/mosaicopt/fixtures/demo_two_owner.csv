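# Invented two-property demo grid for inter-property (reserve-quota) runs.
F,F,A,A,G,G
F,F,A,A,G,G
F,A,A,G,G,F
A,A,G,A,A,A
A,G,G,A,F,A
G,G,A,A,A,A
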