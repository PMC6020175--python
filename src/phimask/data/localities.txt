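# Synthetic locality (town) vocabulary.
Barkingford
Ashcombe
Bradwell
Carleton
Dunmore
Elmswick
Farnleigh
Grimsdale
Hartfield
Ivydale
Kelbrook
Langmere
Marshton
Netherby
Oakhurst
Prestwick
Quenby
Rotherfield
Stanwick
Thornbury
Underwood
Wexcombe
Yarrowdale
Birchington
Caldmore
Draycott
Eastleigh
Fenwick
Gosforth
Haverton
Kirkstall
Ludworth
Milnthorpe
Norbury
Ormskirk
Padstow
Ravenscroft
Silverdale
Tadcaster
Wivenhoe
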