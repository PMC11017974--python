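coi_species,n_colonies
H107,1
P113,6
H070,2
H102,1
P107,2
P112,16
P115,5
P150,1
P153,1
P177,2
Ph096,1
Ph116,1
Ph159,1
V141,6
V172,1
H127,1
Ph095,4
H104,1
P141,1
Ph100,1
Unknown,6
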