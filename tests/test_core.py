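import datetime
import random
from functools import lru_cache

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phimask.core import (
    DeidConfig,
    LinkageError,
    deidentify,
    edit_distance,
    scan_token,
    scan_token_reference,
    similarity,
    version_hash,
)
from phimask.data_model import Document, PhiRecord


@lru_cache(maxsize=None)
def _oracle(a: str, b: str) -> int:
    """Exhaustive-recursion Levenshtein oracle, independent of the DP path."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _oracle(a[1:], b[1:]) + (a[0] != b[0]),
        _oracle(a[1:], b) + 1,
        _oracle(a, b[1:]) + 1,
    )


short = st.text(alphabet="acgt", max_size=8)


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("Meadow", "Meagow", 1),
            ("abc", "abc", 0),
            ("Street", "Streat", 1),
            ("", "abcd", 4),
            ("kitten", "sitting", 3),
        ],
    )
    def test_examples(self, a, b, d):
        assert edit_distance(a, b) == d

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(short, short)
    def test_matches_exhaustive_oracle(self, a, b):
        assert edit_distance(a, b) == _oracle(a, b)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(short, short)
    def test_metric_axioms(self, a, b):
        d = edit_distance(a, b)
        assert d == edit_distance(b, a)
        assert edit_distance(a, a) == 0
        assert d >= abs(len(a) - len(b))
        assert d <= max(len(a), len(b))
        assert (d == 0) == (a == b)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(short, short, short)
    def test_triangle_inequality(self, a, b, c):
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    def test_cross_check_against_edlib(self):
        rng = random.Random(0)
        alphabet = "abcdefgh "
        for _ in range(300):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 12)))
            if not a or not b:  # edlib rejects empty queries
                continue
            assert edit_distance(a, b) == edlib.align(a, b)["editDistance"]


class TestSimilarity:
    def test_single_substitution(self):
        assert similarity("Meadow", "Meagow") == pytest.approx(5 / 6)

    @pytest.mark.parametrize("x", ["", "a", "Street", "100"])
    def test_identity_is_one(self, x):
        assert similarity(x, x) == 1.0

    def test_disjoint_is_zero(self):
        assert similarity("ab", "xy") == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(short, short)
    def test_bounds_and_equality_iff_one(self, a, b):
        s = similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (a == b)


class TestScanToken:
    def test_mutated_token_found(self, default_config):
        spans = scan_token("xx Meagow xx", "Meadow", default_config)
        assert any(
            s.start == 3 and s.end == 9 and s.similarity == pytest.approx(5 / 6)
            for s in spans
        )

    def test_verbatim_token_has_exact_span(self, default_config):
        text = "lorem Barkingford ipsum"
        spans = scan_token(text, "Barkingford", default_config)
        exact = [s for s in spans if s.similarity == 1.0]
        assert [(s.start, s.end) for s in exact] == [(6, 17)]

    def test_dissimilar_text_yields_nothing(self, default_config):
        assert scan_token("lorem ipsum", "Barkingford", default_config) == []

    def test_case_folding_toggle(self):
        on = DeidConfig(case_fold=True)
        off = DeidConfig(case_fold=False)
        assert any(s.similarity == 1.0 for s in scan_token("MEADOW", "meadow", on))
        assert all(s.similarity < 1.0 for s in scan_token("MEADOW", "meadow", off))

    @pytest.mark.parametrize("theta", [0.6, 0.75, 0.8, 0.9])
    def test_vectorized_scan_identical_to_reference(self, theta):
        rng = random.Random(99)
        alphabet = "abcd "
        config = DeidConfig(theta=theta)
        for _ in range(40):
            text = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 40)))
            token = "".join(rng.choice("abcd") for _ in range(rng.randint(3, 9)))
            fast = scan_token(text, token, config)
            ref = scan_token_reference(text, token, config)
            assert fast == ref


class TestDeidentify:
    def test_exact_address_fully_masked(self, doc_meadow, phi_meadow, default_config):
        masked = deidentify(doc_meadow, phi_meadow, default_config)
        for ann in doc_meadow.gold:
            assert set(range(ann.start, ann.end)) <= masked.masked_offsets
        assert "Meadow" not in masked.text and "Street" not in masked.text

    def test_house_number_masking_follows_min_token_length(self, doc_meadow, phi_meadow):
        short_ok = deidentify(doc_meadow, phi_meadow, DeidConfig(min_token_length=3))
        short_skipped = deidentify(doc_meadow, phi_meadow, DeidConfig(min_token_length=4))
        num = set(range(5, 8))  # span of "100"
        assert num <= short_ok.masked_offsets
        # skipped as a query: no span originates from it and it is not fully
        # masked (neighbouring tokens' wide windows may still graze its edge)
        assert not (num <= short_skipped.masked_offsets)
        assert all(s.token_index != 0 for s in short_skipped.spans)

    def test_length_preserved_and_mask_char_in_place(self, doc_meadow, phi_meadow, default_config):
        masked = deidentify(doc_meadow, phi_meadow, default_config)
        assert len(masked.text) == len(doc_meadow.text)
        for i in masked.masked_offsets:
            assert masked.text[i] == default_config.mask_char
        for i in set(range(len(masked.text))) - masked.masked_offsets:
            assert masked.text[i] == doc_meadow.text[i]

    def test_empty_document(self, phi_meadow, default_config):
        doc = Document(doc_id="d0", record_id="r1", date="2016-12-01", text="", gold=[])
        masked = deidentify(doc, phi_meadow, default_config)
        assert masked.text == "" and masked.spans == []

    def test_record_mismatch_raises(self, doc_meadow, default_config):
        other = PhiRecord(record_id="r2", address_tokens=["100", "Meadow", "Street"])
        with pytest.raises(LinkageError):
            deidentify(doc_meadow, other, default_config)

    def test_adding_phi_token_never_shrinks_mask(self, doc_meadow, default_config):
        base = PhiRecord(record_id="r1", address_tokens=["Meadow"])
        more = PhiRecord(record_id="r1", address_tokens=["Meadow", "Street"])
        m1 = deidentify(doc_meadow, base, default_config)
        m2 = deidentify(doc_meadow, more, default_config)
        assert m1.masked_offsets <= m2.masked_offsets

    def test_other_phis_are_masked_too(self, default_config):
        phi = PhiRecord(
            record_id="r1", address_tokens=["Meadow"],
            other_phis={"last_name": ["Smithers"]},
        )
        doc = Document(
            doc_id="d", record_id="r1", date="2016-01-01",
            text="Smithers of Meadow", gold=[],
        )
        masked = deidentify(doc, phi, default_config)
        assert set(range(0, 8)) <= masked.masked_offsets

    def test_lowering_theta_never_shrinks_mask(self, small_clean_corpus):
        docs, phis = small_clean_corpus
        phi_by_id = {p.record_id: p for p in phis}
        for doc in docs[:10]:
            phi = phi_by_id[doc.record_id]
            loose = deidentify(doc, phi, DeidConfig(theta=0.7)).masked_offsets
            tight = deidentify(doc, phi, DeidConfig(theta=0.85)).masked_offsets
            assert tight <= loose


class TestVersionHash:
    def test_deterministic(self, phi_meadow):
        d = datetime.date(2016, 12, 1)
        assert version_hash(phi_meadow, d) == version_hash(phi_meadow, d)

    def test_date_sensitive(self, phi_meadow):
        h1 = version_hash(phi_meadow, datetime.date(2016, 12, 1))
        h2 = version_hash(phi_meadow, datetime.date(2016, 12, 2))
        assert h1 != h2

    def test_sha256_hex_shape(self, phi_meadow):
        h = version_hash(phi_meadow, datetime.date(2016, 12, 1))
        assert len(h) == 64 and set(h) <= set("0123456789abcdef")
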