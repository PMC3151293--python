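FIG1A 1 0 0 1 2 0
FIG1A 2 0 0 2 0 0
FIG1A 3 1 2 1 0 0
FIG1A 4 0 0 2 2 0
FIG1A 5 1 2 2 2 1
FIG1A 6 1 2 2 1 0
FIG1A 7 0 0 1 2 0
FIG1A 8 3 4 1 2 1
FIG1A 9 3 4 2 1 0
FIG1A 10 7 6 1 1 0
FIG1A 11 7 6 2 2 1
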