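# Reference standard-addition study on tablet extract (ng/mL): base sample
# quantified first, then pure standard spiked in three increments.
# pure_found is the recovered increment (total found minus base found).
# Transcribed from the method's reported validation tables.
analyte,base_taken_ng_ml,base_found_ng_ml,pure_added_ng_ml,pure_found_ng_ml
FEX,150,149.24,100,99.27
FEX,150,149.24,200,196.62
FEX,150,149.24,300,303.24
PSE,300,296.01,100,100.12
PSE,300,296.01,200,196.38
PSE,300,296.01,300,297.21
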