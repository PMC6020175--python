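# phimask

Structured-PHI-guided de-identification of clinical free text, with the
synthetic benchmark used to validate it.

## The problem

Hospitals hold a patient's protected health identifiers (PHIs) — names,
addresses, phone numbers, NHS numbers — as *structured* fields in
administrative tables, while the documents that need de-identifying mention
the same identifiers in free text, often misspelt, abbreviated, truncated or
mangled by OCR. `phimask` masks PHIs by fuzzy-searching the clean structured
identifiers in the text, rather than trying to recognize identifiers from
the text alone. No training data and no hand-crafted rules are needed; the
trade-off is that it only works where structured identifiers exist.

## The method

For each PHI token *q* (length *L*) and every character offset *i* of the
document, the Levenshtein distance *d* is computed between *q* and the
window *text[i : i+w]* for every width *w* in *[L−Δ, L+Δ]* with
*Δ = ⌈f·L⌉*. A window is a match when the normalized similarity

    sim(q, window) = 1 − d(q, window) / max(L, w)  ≥  θ

and the union of all matching windows' offsets is replaced by the mask
character, preserving text length (offset-stable output). Defaults:
θ = 0.75, *f* = 0.34, tokens shorter than 3 characters are never used as
queries, comparison is case-insensitive. Each masked document carries a
SHA-256 hash of (record id, canonical address, document date) for version
control.

The validation framework generates corpora of synthetic UK-style addresses
(7–10 tokens) wrapped in lorem-ipsum filler, corrupts the embedded copy with
one of four mutation models — QWERTY keyboard typos (3/10/20% per
character), full-form↔abbreviation aliasing (100% per token), truncation to
three tokens, and simulated OCR (keyboard typos plus intra-token whitespace
at 3/10/20%) — and scores masking per whitespace-delimited token unit:
a unit counts as detected when at least half of its characters are masked.

## Worked example

```python
from phimask import DeidConfig, Document, PhiRecord, deidentify

phi = PhiRecord(record_id="p-0042",
                address_tokens=["100", "Meadow", "Street", "Barkingford", "London"],
                other_phis={"last_name": ["Hartfield"]})
doc = Document(doc_id="letter-1", record_id="p-0042", date="2016-12-01",
               text="Dear colleague, I reviewed Ms Hartfeild at home "
                    "(100 Meagow Streat, Barkingford) on Monday. She is recovering well.")
print(deidentify(doc, phi, DeidConfig()).text)
```

prints

```
Dear colleague, I reviewed Ms XXXXXXXXX at home XXXXXXXXXXX XXXXXXXXXXXXXXXXXXXXXXn Monday. She is recovering well.
```

The misspelt surname ("Hartfeild") and street ("Meagow Streat") are masked
even though neither matches the stored identifiers exactly: each sits within
the distance budget of the similarity threshold. Fuzzy windows may slightly
overhang a match (the bracket swallowed above) — masking errs on the side of
removal.

A scaled-down benchmark (`python examples/run_small_benchmark.py`, 150
documents per condition, seed 42) prints:

```
condition        tp    fp     fn   prec    rec
keyboard_3     1236    41     37   96.8   97.1
keyboard_10    1119    45    162   96.1   87.4
keyboard_20     881    46    394   95.0   69.1
alias          1281    72     20   94.7   98.5
truncate        448    32      2   93.3   99.6
ocr_3_3        1338    57     81   95.9   94.3
ocr_10_10      1343    35    474   97.5   73.9
ocr_20_20       886    48   1358   94.9   39.5
```

`tp`/`fp`/`fn` are pooled token-unit counts; recall falls as noise rises
within each family, and the simulated-OCR family is the hardest because
whitespace insertion fragments tokens into separately scored units.

## Command line

```
deid gen --n-docs 1000 --mutator keyboard --char-rate 0.03 --seed 42 \
         --out corpus.jsonl --phis phis.csv
deid run --documents corpus.jsonl --phis phis.csv --out masked.jsonl --theta 0.75
deid benchmark --seed 42 --out table.csv          # 8 conditions + reference diff
deid mutate --kind ocr --char-rate 0.1 --ws-rate 0.1 --seed 7 --in a.txt --out b.txt
deid job --documents corpus.jsonl --phis phis.csv --partitions 4 \
         --state state.json --out masked.jsonl    # incremental, high-water mark
```

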