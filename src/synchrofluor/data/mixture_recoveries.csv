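# Reference added/found values (ng/mL) for synthetic 1:2 FEX:PSE laboratory
# mixtures analysed by the first-derivative synchronous method; each found
# value is the average of three determinations.  Transcribed from the
# method's reported validation tables.
analyte,added_ng_ml,found_ng_ml
FEX,100,100.94
FEX,150,152.75
FEX,200,203.44
FEX,250,249.65
FEX,300,302.73
PSE,200,196.70
PSE,300,300.57
PSE,400,397.64
PSE,500,491.90
PSE,600,601.56
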