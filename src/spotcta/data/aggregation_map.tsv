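fine_type	major_class
Cancer Epithelial	tumor
Normal Epithelial	tumor
T-cells	immune
ILC	immune
B-cells	immune
Plasmablasts	immune
Myeloid	immune
CAFs	stroma
PVL	stroma
Endothelial	stroma
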