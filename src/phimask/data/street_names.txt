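# Synthetic street-name vocabulary (UK-flavoured), used for the 1-2 name
# words of a generated address.
Meadow
Victoria
Albert
Church
Mill
Station
Park
Oak
Elm
Willow
Holly
Rose
King
Queen
Castle
Bridge
Spring
Orchard
Manor
Grange
Abbey
Chapel
Tower
Windsor
York
Kent
Richmond
Clarence
Warwick
Brook
River
Garden
Field
Forest
Heath
Moor
Birch
Cedar
Maple
Juniper
Lavender
Primrose
Clifton
Harcourt
Pemberton
Ashworth
Whitfield
Stanmore
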