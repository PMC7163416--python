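statin_type,dose_mg_equal_to_atorva20
atorvastatin,20
rosuvastatin,10
simvastatin,40
pravastatin,80
fluvastatin,80
lovastatin,80
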