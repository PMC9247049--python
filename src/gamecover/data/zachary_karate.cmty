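1 2 3 4 5 6 7 8 9 11 12 13 14 17 18 20 22
10 15 16 19 21 23 24 25 26 27 28 29 30 31 32 33 34
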