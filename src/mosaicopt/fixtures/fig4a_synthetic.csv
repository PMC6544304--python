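# Synthetic stand-in for the first hypothetical 6x6 initial landscape
# (12 parcels each of G, F, A): random arrangement, generator seed 0.
# NOT a transcription of any published figure.
G,A,A,G,G,F
A,F,G,G,G,F
A,G,G,G,A,F
G,F,F,F,A,F
G,G,F,A,F,A
A,F,A,A,F,A
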