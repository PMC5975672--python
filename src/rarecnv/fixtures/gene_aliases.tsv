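alias	canonical
CFAP46	TTC40
DANH10	DNAH10
DANH5	DNAH5
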