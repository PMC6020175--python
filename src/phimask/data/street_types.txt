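# Thoroughfare-type vocabulary. Half of these have a standard abbreviation
# (see alias_pairs.txt), half do not; a generated address therefore carries
# on average ~0.5 abbreviable tokens, matching the alias-substitution
# benchmark's operating regime.
Street
Road
Avenue
Lane
Drive
Court
Place
Square
Crescent
Gardens
Way
Walk
Row
Close
Terrace
Grove
Rise
Vale
Green
Hill
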