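symbol	tag
PACRG	cilia
TCTN2	cilia
DNAH10	cilia
TTC40	cilia
NUMB	pathway:Notch
RNF115	e3_ligase
ZIC3	known_htx
CFC1	known_htx
NKX2.5	known_htx
GDF1	known_htx
NODAL	known_htx
LEFTY1	known_htx
LEFTY2	known_htx
ACVR2B	known_htx
DNAH5	known_htx
DNAH11	known_htx
DNAI1	known_htx
FOXH1	known_htx
CRELD1	known_htx
GALNT11	known_htx
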