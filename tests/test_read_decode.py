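"""Noisy-read pipeline: primer location, filtering, greedy sphere
clustering (vs a brute-force oracle), and graceful degradation."""

import numpy as np
import pytest

from dualstore import channel_sim as cs
from dualstore import read_decode as rd
from dualstore._seq import revcomp

# ---------------------------------------------------------------------------
# independent pure-Python oracles (no edlib)


def dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_locate(read: str, primer: str):
    """Best infix match by exhaustive substring DP."""
    best = None
    for start in range(len(read)):
        for end in range(start, len(read) + 1):
            d = dp_levenshtein(read[start:end], primer)
            if best is None or d < best[2] or (d == best[2] and start < best[0]):
                best = (start, end, d)
    return best


def greedy_cluster_oracle(reads, radius):
    from collections import Counter

    counts = Counter(reads)
    order = sorted(counts, key=lambda s: (-counts[s], s))
    assigned, out = set(), []
    for c in order:
        if c in assigned:
            continue
        assigned.add(c)
        size = counts[c]
        for o in order:
            if o not in assigned and dp_levenshtein(c, o) <= radius:
                assigned.add(o)
                size += counts[o]
        out.append((c, size))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# ---------------------------------------------------------------------------


class TestLocatePrimer:
    PRIMER = "ACGTACGTACGTACGTACGT"

    def test_exact_at_start(self):
        read = self.PRIMER + "TTTTGGGG"
        assert rd.locate_primer(read, self.PRIMER, 2) == (0, 20, 0)

    def test_one_substitution_mid_read(self):
        mutated = self.PRIMER[:10] + "T" + self.PRIMER[11:]  # G->T
        read = "CCAA" + mutated + "GGTT"
        hit = rd.locate_primer(read, self.PRIMER, 2)
        assert hit is not None and hit[2] == 1
        bstart, bend, bd = brute_locate(read, self.PRIMER)
        assert hit[2] == bd

    def test_not_found_beyond_max_edits(self, rng):
        for _ in range(10):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            brute = brute_locate(read, self.PRIMER)
            hit = rd.locate_primer(read, self.PRIMER, 4)
            if brute[2] > 4:
                assert hit is None
            else:
                assert hit is not None and hit[2] == brute[2]


class TestFilterAndTrim:
    def test_clean_strands_all_pass_and_trim_exactly(self, fixture_strands, primer_pair):
        fulls = [s.full for s in fixture_strands]
        trimmed = rd.filter_and_trim(fulls, primer_pair)
        assert len(trimmed) == len(fulls)
        assert trimmed == [f[20:-20] for f in fulls]

    def test_orientation_canonicalized(self, fixture_strands, primer_pair):
        fulls = [s.full for s in fixture_strands[:10]]
        flipped = [revcomp(f) if i % 2 else f for i, f in enumerate(fulls)]
        assert rd.filter_and_trim(flipped, primer_pair) == [f[20:-20] for f in fulls]

    def test_foreign_primer_pair_rejected(self, fixture_strands):
        from dualstore.detailed_codec import design_primer_pairs

        other = design_primer_pairs(2, seed=555)[1]
        fulls = [s.full for s in fixture_strands[:20]]
        assert rd.filter_and_trim(fulls, other) == []

    def test_truncated_reads_rejected(self, fixture_strands, primer_pair):
        stubs = [s.full[:100] for s in fixture_strands[:10]]
        assert rd.filter_and_trim(stubs, primer_pair) == []


class TestClusterReads:
    def test_hand_example(self):
        reads = ["ACGT"] * 10 + ["ACGA"] * 2 + ["TTTT"] * 5
        clusters = rd.cluster_reads(reads, radius=1)
        assert [(c.centroid, c.abundance) for c in clusters] == [
            ("ACGT", 12), ("TTTT", 5)]

    def test_radius_zero_is_histogram(self):
        reads = ["AA", "AA", "AT", "GG"]
        clusters = rd.cluster_reads(reads, radius=0)
        assert [(c.centroid, c.abundance) for c in clusters] == [
            ("AA", 2), ("AT", 1), ("GG", 1)]

    def test_all_identical_single_cluster(self):
        clusters = rd.cluster_reads(["ACGTAC"] * 7, radius=3)
        assert len(clusters) == 1 and clusters[0].abundance == 7

    def test_member_ids_partition_input(self):
        reads = ["ACGT", "ACGA", "TTTT", "ACGT", "TTTA"]
        clusters = rd.cluster_reads(reads, radius=1)
        ids = sorted(i for c in clusters for i in c.member_ids)
        assert ids == list(range(len(reads)))

    @pytest.mark.parametrize("radius", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, radius, rng):
        """Greedy sphere clustering equals the O(U^2) DP oracle."""
        for trial in range(4):
            n = int(rng.integers(20, 120))
            reads = []
            for _ in range(n):
                L = int(rng.integers(6, 14))
                reads.append("".join("ACGT"[i] for i in rng.integers(0, 4, L)))
            got = [(c.centroid, c.abundance) for c in rd.cluster_reads(reads, radius)]
            assert got == greedy_cluster_oracle(reads, radius)


class TestSelectTopN:
    def _clusters(self, n):
        return [rd.ReadCluster(f"SEQ{i:03d}", 100 - i, [i]) for i in range(n)]

    def test_top_n_sorted(self):
        picked, shortfall = rd.select_top_n(self._clusters(200), 81)
        assert len(picked) == 81 and shortfall == 0
        assert [c.abundance for c in picked] == sorted(
            (c.abundance for c in picked), reverse=True)

    def test_shortfall_flagged(self):
        picked, shortfall = rd.select_top_n(self._clusters(3), 10)
        assert len(picked) == 3 and shortfall == 7


class TestRecoverFile:
    def test_end_to_end_exact(self, fixture_strands, fixture_payload, primer_pair):
        reads = cs.simulate_reads([s.full for s in fixture_strands],
                                  cs.ChannelParams(seed=77))
        payload, report = rd.recover_file(reads, primer_pair, len(fixture_strands))
        assert payload == fixture_payload
        assert report.error_rate == 0.0
        assert report.n_strands_recovered == 81

    def test_pipeline_counts_monotone(self, fixture_strands, primer_pair):
        reads = cs.simulate_reads([s.full for s in fixture_strands[:10]],
                                  cs.ChannelParams(coverage=20, seed=5))
        _, rep = rd.recover_file(reads, primer_pair, 10)
        assert rep.n_reads_in >= rep.n_reads_passing_filter
        assert rep.n_reads_passing_filter >= rep.n_clusters >= rep.n_strands_recovered

    def test_orientation_invariance(self, fixture_strands, primer_pair, fixture_payload):
        reads = cs.simulate_reads([s.full for s in fixture_strands],
                                  cs.ChannelParams(seed=31, revcomp_prob=0.0))
        flipped = [revcomp(r) if i % 3 == 0 else r for i, r in enumerate(reads)]
        p1, _ = rd.recover_file(reads, primer_pair, len(fixture_strands))
        p2, _ = rd.recover_file(flipped, primer_pair, len(fixture_strands))
        assert p1 == p2 == fixture_payload

    def test_graceful_partial_recovery(self, fixture_strands, primer_pair):
        hard = cs.ChannelParams(sub_rate=0.1, ins_rate=0.08, del_rate=0.1,
                                coverage=2, seed=13)
        reads = cs.simulate_reads([s.full for s in fixture_strands], hard)
        payload, rep = rd.recover_file(reads, primer_pair, len(fixture_strands))
        assert isinstance(payload, bytes)
        assert rep.per_strand_status  # statuses populated, no crash
        assert rep.n_strands_recovered <= rep.n_strands_expected

    def test_zero_reads(self, primer_pair):
        payload, rep = rd.recover_file([], primer_pair, 5)
        assert payload == b"" and rep.n_reads_passing_filter == 0


class TestEvaluate:
    def test_delegates_to_error_rate(self):
        assert rd.evaluate_against_originals(["ACGT", "TTTT"], ["ACGA", "TTTT"]) == 1 / 8
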