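# Synthetic stand-in for the second hypothetical 6x6 initial landscape
# (12 parcels each of G, F, A): random arrangement, generator seed 1.
# NOT a transcription of any published figure.
G,G,G,G,A,G
A,F,F,F,F,G
G,A,F,F,A,A
A,A,A,F,F,A
A,G,A,F,G,F
G,G,G,A,F,F
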