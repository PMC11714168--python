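B-cells	lymphoid
Naive B-cells	lymphoid
Memory B-cells	lymphoid
Class-switched memory B-cells	lymphoid
pro B-cells	lymphoid
Plasma cells	lymphoid
Plasmablasts	lymphoid
Germinal center B-cells	lymphoid
Immature B-cells	lymphoid
Activated B-cells	lymphoid
CD4+ T-cells	lymphoid
CD4+ naive T-cells	lymphoid
CD4+ memory T-cells	lymphoid
CD4+ Tcm	lymphoid
CD4+ Tem	lymphoid
CD8+ T-cells	lymphoid
CD8+ naive T-cells	lymphoid
CD8+ Tcm	lymphoid
CD8+ Tem	lymphoid
Tregs	lymphoid
Th1 cells	lymphoid
Th2 cells	lymphoid
Th17 cells	lymphoid
Tfh cells	lymphoid
Tgd cells	lymphoid
NK cells	lymphoid
NKT cells	lymphoid
CD56bright NK cells	lymphoid
CD56dim NK cells	lymphoid
Common lymphoid progenitors	lymphoid
T helper cells	lymphoid
Cytotoxic T-cells	lymphoid
Exhausted CD8+ T-cells	lymphoid
Central memory T-cells	lymphoid
Effector memory T-cells	lymphoid
Naive T-cells	lymphoid
MAIT cells	lymphoid
Innate lymphoid cells	lymphoid
Activated CD4+ T-cells	lymphoid
Activated CD8+ T-cells	lymphoid
Monocytes	myeloid
Macrophages	myeloid
Macrophages M1	myeloid
Macrophages M2	myeloid
DC	myeloid
cDC	myeloid
pDC	myeloid
aDC	myeloid
iDC	myeloid
Neutrophils	myeloid
Eosinophils	myeloid
Basophils	myeloid
Mast cells	myeloid
Common myeloid progenitors	myeloid
GMP	myeloid
Hematopoietic stem cells	stem
MSC	stem
Multipotent progenitors	stem
MEP	stem
Erythroid progenitors	stem
Granulocyte progenitors	stem
Platelets	stem
Megakaryocytes	stem
Erythrocytes	stem
Proerythroblasts	stem
CD34+ progenitors	stem
Fibroblasts	stromal
Endothelial cells	stromal
Lymphatic endothelial cells	stromal
Microvascular endothelial cells	stromal
Pericytes	stromal
Smooth muscle cells	stromal
Skeletal muscle cells	stromal
Adipocytes	stromal
Osteoblasts	stromal
Chondrocytes	stromal
Mesangial cells	stromal
Epithelial cells	other
Keratinocytes	other
Hepatocytes	other
Melanocytes	other
Neurons	other
Astrocytes	other
Sebocytes	other
Enterocytes	other
Myocytes	other
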