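# Reference added/found values (ng/mL) for FEX and PSE spiked into human
# plasma (protein precipitation with acetonitrile, evaporation,
# reconstitution in ethanol); found values are averages of three
# determinations.  Transcribed from the method's reported validation tables.
analyte,added_ng_ml,found_ng_ml
FEX,100,95.38
FEX,150,139.79
FEX,200,192.54
FEX,250,233.98
FEX,300,292.83
PSE,200,184.48
PSE,300,288.03
PSE,400,377.28
PSE,500,477.35
PSE,600,578.34
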