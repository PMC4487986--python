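mirna	conserved_in
MIR185	mouse
MIR1306	mouse
MIR1286	
MIR3618	
MIR649	
MIR4761	
MIR6816	
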