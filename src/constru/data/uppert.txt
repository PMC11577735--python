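# UpperT signature: genes whose upper expression tertile conditions a
# favorable score-survival association (4th-percentile parity cutoff)
C8orf33
CDC42EP4
DDX21
DNAJC9
MEGF6
NCAPD3
RAF1
RTF1
TPD52
TUBGCP4
UBP1
UQCRB
ZNF250
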