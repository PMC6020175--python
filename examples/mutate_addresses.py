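"""Show the four mutation models that the benchmark uses to corrupt
addresses before embedding them in documents."""

import random

from phimask import MutatorSpec, apply_mutator

address = "100 Meadow Street Barkingford Greater London London".split()
rng = random.Random(7)

for spec in [
    MutatorSpec(kind="keyboard", char_rate=0.20),
    MutatorSpec(kind="alias", token_rate=1.0),
    MutatorSpec(kind="truncate", token_rate=1.0, min_tokens=3),
    MutatorSpec(kind="ocr", char_rate=0.20, ws_rate=0.20),
]:
    mutated = apply_mutator(spec, address, rng)
    print(f"{spec.kind:9s} -> {' '.join(mutated)}")
# keyboard swaps characters for QWERTY neighbours, alias abbreviates
# thoroughfare words, truncate drops supplemental address lines, and ocr
# additionally fractures tokens with spurious whitespace.
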