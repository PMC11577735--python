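# Antigen-presentation machinery (APM) signature: sum of log2 z-scores
B2M
CALR
NLRC5
PSMB9
PSME1
PSME3
RFX5
HSP90AB1
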