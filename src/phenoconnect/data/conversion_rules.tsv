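from	to	factor
m	cm	100
m	mm	1000
kg	g	1000
kg	mg	1000000
L	mL	1000
week	day	7
month	day	30.44
year	day	365.25
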