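# Synthetic codon -> relative-expression fixture: Boltzmann-consistent
# with the shipped presets' oracle pairing penalties at kT_eff = kB*310 K.
# Not measured data.
codon	ddg	frequency_percent
AUG	0.0	100.0
CUG	6.452113376838522	8.177935486107248
GUG	7.434665336921757	5.585434874874602
UUG	7.590559664973899	5.257563958333169
ACG	4.8004810537577995	15.52346185801135
AUU	4.841512481294572	15.278252003378304
CΨG	1.2726623540886663	61.02697348264634
GΨG	2.2896975179178263	41.12669291921797
mCUG	7.285431502457996	5.918435870278955
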