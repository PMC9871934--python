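# Canonical lineage markers for annotating major aortic cell types.
# Convenience defaults (human symbols); edit freely for other tissues.
SMC: [MYH11, ACTA2, TAGLN, CNN1, MYL9]
EC: [PECAM1, CDH5, VWF, CLDN5]
Fibroblast: [DCN, LUM, PDGFRA, COL1A1, FBLN1]
Macrophage: [CD68, CD14, LYZ, AIF1, C1QA]
TCell: [CD3D, CD3E, TRAC, CD2, IL7R]
BCell: [CD79A, CD79B, MS4A1, IGHM]
NK: [KLRD1, NKG7, GNLY, NCR1]
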