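# 13-transcript T-cell infiltration signature (mean expression score)
CD8A
CCL2
CCL3
CCL4
CXCL9
CXCL10
ICOS
GZMK
IRF1
HLA-DMA
HLA-DMB
HLA-DOA
HLA-DOB
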