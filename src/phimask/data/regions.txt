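# Region vocabulary. Single-token region names, then two-token region
# phrases after the '--' separator.
London
Yorkshire
Merseyside
Essex
Kent
Surrey
Sussex
Norfolk
Devon
Cumbria
Dorset
Cheshire
Lancashire
Somerset
Wiltshire
Cornwall
Durham
Lincolnshire
--
Greater London
West Yorkshire
East Sussex
North Somerset
South Tyneside
West Midlands
East Anglia
North Yorkshire
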