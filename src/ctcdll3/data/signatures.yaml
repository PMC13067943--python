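# SCLC molecular-subtype signature gene lists and the marker gene sets used
# throughout the single-cell stages. Keratin "CK n" names are mapped to KRT
# symbols (CK6 -> KRT6A); B7H3 is the protein name of gene CD276.
subtypes:
  SCLC-A: [ASCL1, SOX4, STMN2, DOC2A]
  SCLC-N: [NEUROD1, ADCYAP1, NRXN1, SSTR2, ID1, ID3, SST, DLK1]
  SCLC-P: [POU2F3, ASCL2, CD44, MYC, KIT, YBX1]
  SCLC-I: [CD274, PDCD1, CD80, CD86, CTLA4, CD38, IDO1, TIGIT, ICOS, LAG3,
           CCL5, CXCL10, HLA-A, HLA-B, HLA-C, HLA-E, HLA-F, HLA-G, HLA-DRA,
           HLA-DRB1, HLA-DQA1, HLA-DMA, HLA-DPA1, HLA-DMB, HLA-DPB1,
           HLA-DQB1, HLA-DOA, HLA-DOB]
epitopes: [DLL3, SEZ6, CD276]
notch: [NOTCH1, NOTCH2, NOTCH3, NOTCH4, HES1, HEY1, JAG1, JAG2]
epithelial: [EPCAM, KRT4, KRT5, KRT6A, KRT8, KRT10, KRT13, KRT18]
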