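# LowerT signature: genes whose lower expression tertile conditions a
# favorable score-survival association (4th-percentile parity cutoff)
ALB
AMACR
APBB2
BAG2
BDH2
CAMK2N1
CAV2
CDC14B
DNAJB4
EVA1B
FAT4
GALC
HAS2
HOXA9
MFGE8
NPTXR
OSR2
PCGF1
PCOLCE2
PEPD
PID1
PLAGL1
POGLUT2
STAM2
TRPC1
WDFY3
WNT7A
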