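"""Strand codec: base mapping, modulation, constraint screening, the
two RS layers, and full file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualstore import detailed_codec as dc
from dualstore._seq import InvalidAlphabetError

dna = st.text(alphabet="ACGT", min_size=1, max_size=64)
primers4 = st.text(alphabet="ACGT", min_size=4, max_size=4)


class TestBaseMapping:
    def test_forced_examples(self):
        assert dc.bytes_to_bases(b"") == ""
        assert dc.bytes_to_bases(b"\x1b") == "ACGT"  # bits 00 01 10 11
        assert dc.bytes_to_bases(b"\x00") == "AAAA"

    @given(st.binary(max_size=200))
    @settings(deadline=None)
    def test_round_trip(self, data):
        seq = dc.bytes_to_bases(data)
        assert len(seq) == 4 * len(data)
        assert dc.bases_to_bytes(seq) == data


class TestModulation:
    def test_identity_keystream(self):
        assert dc.modulate("ACGT", "AAAA") == "ACGT"

    def test_hand_addition(self):
        # 0+0, 0+1, 0+2, 0+3 mod 4
        assert dc.modulate("AAAA", "ACGT") == "ACGT"

    @given(dna, primers4)
    @settings(deadline=None)
    def test_inversion(self, seq, primer):
        assert dc.demodulate(dc.modulate(seq, primer), primer) == seq

    @given(dna, primers4, primers4)
    @settings(deadline=None)
    def test_group_action(self, seq, p, q):
        """Modulating by p then q equals one modulation by p+q (mod 4)."""
        pq = dc.modulate(p, q)
        assert dc.modulate(dc.modulate(seq, p), q) == dc.modulate(seq, pq)

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabetError):
            dc.modulate("ACGN", "AAAA")


class TestConstraints:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", False),  # homopolymer run of 4
            ("ACGT", True),  # GC 0.5, max run 1
            ("GGGCCC", False),  # GC 1.0 out of window (runs of 3 would pass)
            ("ACGTACGTAA", True),
        ],
    )
    def test_examples(self, seq, expected):
        assert dc.passes_constraints(seq) is expected

    def test_pool_words_all_compliant(self):
        pool = dc.modulation_primer_pool()
        assert len(pool) > 0
        assert all(dc.passes_constraints(w) for w in pool)
        assert pool == sorted(pool)  # deterministic order


class TestLayout:
    def test_default_region_sum_is_124(self):
        lay = dc.DEFAULT_LAYOUT
        assert (
            2 * lay.mod_primer_len
            + lay.index_len
            + lay.payload_len
            + lay.rs_inner_len
            + lay.seed_min_len
            == lay.min_core_len
            == 124
        )

    def test_inconsistent_layout_rejected(self):
        with pytest.raises(ValueError):
            dc.SequenceLayout(payload_len=96)  # breaks the 124-nt tiling


class TestBuildCore:
    def test_length_and_constraints(self, fixture_strands):
        lay = dc.DEFAULT_LAYOUT
        allowed = set(
            range(lay.min_core_len, lay.min_core_len + lay.seed_max_len - lay.seed_min_len + 1, 4)
        )
        for rec in fixture_strands:
            assert len(rec.core) in allowed
            assert len(rec.core) % 4 == 0
            assert dc.passes_constraints(rec.core)

    def test_all_zero_chunk_needs_nonidentity_primer(self):
        rec = dc.build_core(bytes(25), index=0, seed_rng=np.random.default_rng(0))
        # identity modulation of 25 zero bytes would be a 100-A homopolymer
        assert rec.mod_primer_a != "AAAA"
        assert dc.passes_constraints(rec.core)

    def test_deterministic_under_seed(self):
        pool = dc.modulation_primer_pool()
        a = dc.build_core(b"\x07" * 25, 3, primer_pool=pool,
                          seed_rng=np.random.default_rng(42))
        b = dc.build_core(b"\x07" * 25, 3, primer_pool=pool,
                          seed_rng=np.random.default_rng(42))
        assert a.core == b.core


class TestAssembleAndDecode:
    def test_minimal_core_gives_172nt_full(self, fixture_strands):
        for rec in fixture_strands:
            assert len(rec.full) == len(rec.core) + 48
        assert min(len(r.full) for r in fixture_strands) == 172

    def test_strict_decode_round_trip(self, fixture_strands, fixture_payload, primer_pair):
        framed = len(fixture_payload).to_bytes(2, "little") + fixture_payload
        for rec in fixture_strands:
            idx, chunk = dc.decode_strand(rec.full, primer_pair)
            assert idx == rec.index
            expected = framed[idx * 25 : (idx + 1) * 25].ljust(25, b"\x00")
            assert chunk == expected

    def test_single_substitution_in_core_corrected(self, fixture_strands, primer_pair):
        full = fixture_strands[2].full
        rng = np.random.default_rng(5)
        for pos in rng.choice(np.arange(20, len(full) - 20), size=40, replace=False):
            pos = int(pos)
            for b in "ACGT":
                if b == full[pos]:
                    continue
                idx, _ = dc.decode_strand(full[:pos] + b + full[pos + 1 :], primer_pair)
                assert idx == fixture_strands[2].index
                break

    def test_truncated_read_fails_cleanly(self, fixture_strands, primer_pair):
        with pytest.raises(dc.StrandDecodeError):
            dc.decode_strand(fixture_strands[0].full[:100], primer_pair)

    def test_wrong_primer_rejected(self, fixture_strands):
        other = dc.design_primer_pairs(1, seed=99)[0]
        with pytest.raises(dc.StrandDecodeError):
            dc.decode_strand(fixture_strands[0].full, other)


class TestEncodeFile:
    def test_fixture_strand_count(self, fixture_strands):
        # ceil((1999 + 2) / 25) strands for the 1,999-byte fixture
        assert len(fixture_strands) == 81

    def test_empty_file(self, primer_pair):
        strands = dc.encode_file(b"", primer_pair=primer_pair, seed=1)
        assert len(strands) == 1
        assert dc.decode_file([strands[0].full], primer_pair) == b""

    def test_round_trip_random_payloads(self, primer_pair, rng):
        for _ in range(6):
            n = int(rng.integers(0, 6000))
            data = rng.integers(0, 256, size=n, dtype=np.uint8).tobytes()
            strands = dc.encode_file(data, primer_pair=primer_pair, seed=int(rng.integers(2**31)))
            assert dc.decode_file([s.full for s in strands], primer_pair) == data

    def test_oversize_payload_rejected(self, primer_pair):
        with pytest.raises(ValueError):
            dc.encode_file(bytes(dc.DEFAULT_LAYOUT.max_file_bytes + 1),
                           primer_pair=primer_pair)

    def test_deterministic(self, primer_pair):
        a = dc.encode_file(b"hello world", primer_pair=primer_pair, seed=4)
        b = dc.encode_file(b"hello world", primer_pair=primer_pair, seed=4)
        assert [s.full for s in a] == [s.full for s in b]


class TestSequenceErrorRate:
    def test_identical_lists(self):
        assert dc.sequence_error_rate(["ACGT", "TTTT"], ["ACGT", "TTTT"]) == 0.0

    def test_hand_example(self):
        assert dc.sequence_error_rate(["ACGT", "TTTT"], ["ACGA", "TTTT"]) == 1 / 8

    def test_unmatched_original_penalty(self):
        rate = dc.sequence_error_rate(["ACGTACGTAC", "TGCATGCATG"], ["ACGTACGTAC"])
        assert rate >= 0.5

    def test_index_pairing(self):
        rate = dc.sequence_error_rate(
            ["AAAA", "CCCC"], ["CCCC", "AAAA"], recovered_indices=[1, 0]
        )
        assert rate == 0.0
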