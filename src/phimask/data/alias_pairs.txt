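# Bidirectional full-form <-> abbreviation pairs for address tokens.
# Lookup is case-insensitive; the map is an involution.
Road Rd
Street St
Avenue Ave
Lane Ln
Drive Dr
Court Ct
Place Pl
Square Sq
Crescent Cres
Gardens Gdns
Saint St.
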