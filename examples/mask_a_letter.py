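"""Mask one clinical letter using the patient's structured identifiers.

The masker never parses the text for names or addresses: it fuzzy-searches
the clean identifiers held in the administrative record, so the misspelt
street name below ("Meagow Streat") is still caught.
"""

from phimask import DeidConfig, Document, PhiRecord, deidentify

phi = PhiRecord(
    record_id="p-0042",
    address_tokens=["100", "Meadow", "Street", "Barkingford", "London"],
    other_phis={"last_name": ["Hartfield"]},
)

doc = Document(
    doc_id="letter-1",
    record_id="p-0042",
    date="2016-12-01",
    text=(
        "Dear colleague, I reviewed Ms Hartfeild at home "
        "(100 Meagow Streat, Barkingford) on Monday. She is recovering well."
    ),
)

masked = deidentify(doc, phi, DeidConfig())

print("original:", doc.text)
print("masked:  ", masked.text)
print(f"{len(masked.spans)} window matches; version hash {masked.version_hash[:12]}…")
# Every X in the masked line is a character the matcher attributed to a PHI
# token at similarity >= theta, despite the typos in the letter.
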