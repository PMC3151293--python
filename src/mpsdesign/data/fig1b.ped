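FIG1B 1 0 0 1 0 0
FIG1B 2 0 0 2 1 0
FIG1B 3 1 2 1 2 0
FIG1B 4 0 0 2 1 0
FIG1B 5 1 2 2 1 0
FIG1B 6 1 2 2 1 0
FIG1B 7 0 0 1 1 0
FIG1B 8 3 4 1 2 1
FIG1B 9 3 4 2 1 0
FIG1B 10 7 6 1 1 0
FIG1B 11 7 6 2 2 0
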