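panel	gene
drg_neuron	Ntrk1
drg_neuron	Ret
drg_neuron	Scn7a
drg_neuron	Scn8a
drg_neuron	Scn10a
drg_neuron	Scn11a
myelination	Scip
myelination	Krox20
myelination	Pmp22
myelination	Mbp
myelination	Mag
myelination	Plp
cholesterol	Cyp51
cholesterol	Dhcr7
cholesterol	Lss
cholesterol	Nsdhl
cholesterol	Sc4mol
cholesterol	Sqle
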