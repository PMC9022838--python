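name,metabolite,pattern
U-13C-pyruvate,PYR.ext,111
U-13C-glutamine,GLN.ext,11111
3-13C-pyruvate,PYR.ext,001
"1,2-13C-glutamine",GLN.ext,11000
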