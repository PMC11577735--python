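# Cytolytic activity score (CYTscore): mean log2 expression of two effector genes
GZMA
PRF1
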