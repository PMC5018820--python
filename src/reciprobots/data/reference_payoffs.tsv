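	Selfish	Helper	Reciprocator
Selfish	152	205	160
Helper	132	198	175
Reciprocator	147	203	173
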