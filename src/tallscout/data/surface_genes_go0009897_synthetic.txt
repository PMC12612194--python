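# Synthetic stand-in snapshot of human genes annotated to GO:0009897
# (external side of plasma membrane). Hand-curated 2025-09 from well-known
# members (CD antigens, receptors); override with a real ontology export
# via targets.load_surface_genes(path).
CD1A
CD1B
CD1C
CD2
CD3D
CD3E
CD3G
CD4
CD5
CD7
CD8A
CD8B
CD14
CD19
CD22
CD24
CD27
CD28
CD33
CD34
CD36
CD38
CD40
CD44
CD47
CD48
CD52
CD53
CD58
CD63
CD69
CD70
CD72
CD74
CD80
CD81
CD83
CD86
CD96
CD99
CD109
CD151
CD160
CD200
CD226
CD244
CD247
CD274
CD276
IL2RA
IL2RB
IL2RG
IL3RA
IL7R
IL10RA
KIT
FLT3
CSF1R
CSF2RA
TFRC
TNFRSF4
TNFRSF8
TNFRSF9
TNFRSF14
TNFRSF18
PDCD1
CTLA4
LAG3
HAVCR2
TIGIT
BTLA
ICOS
SLAMF1
SLAMF6
SLAMF7
KLRB1
KLRC1
KLRD1
KLRG1
KLRK1
NCR1
NCR2
NCR3
FCGR3A
FCGR2A
FCGR2B
NT5E
ENTPD1
THY1
PROM1
MME
ANPEP
ITGA4
ITGA6
ITGAE
ITGAL
ITGAM
ITGAX
ITGB1
ITGB2
ITGB7
SELL
SELPLG
PECAM1
ICAM1
ICAM2
ICAM3
VCAM1
ALCAM
MCAM
NCAM1
EPCAM
CDH1
CDH2
CDH5
LY9
LY75
TLR2
TLR4
CXCR4
CCR7
CCR4
CCR6
CX3CR1
S1PR1
PTPRC
CR1
CR2
C3AR1
C5AR1
TREM1
TREM2
SIRPA
SIGLEC7
SIGLEC9
LILRB1
LILRB2
KIR2DL1
KIR2DL3
KIR3DL1
HLA-A
HLA-B
HLA-C
HLA-E
B2M
MICA
MICB
ULBP1
ULBP2
ULBP3
RAET1E
CRTAM
TRAC
TRBC1
TRGC1
TRDC
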