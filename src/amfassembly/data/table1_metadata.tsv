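sample_id	patch	root_system
Lv-LD	LD	focal
Lv-MD	MD	focal
Lv-HD	HD	focal
Nb-Control	Control	neighborhood
Nb-LD	LD	neighborhood
Nb-MD	MD	neighborhood
Nb-HD	HD	neighborhood
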