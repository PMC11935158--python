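"""Recover files from noisy sequencing reads.

Pipeline (per accessed file): two-end primer filtering and trimming
with semi-global alignment -> abundance-greedy Levenshtein sphere
clustering -> top-n cluster selection (n = number of strands of the
file, supplied by the library manifest) -> per-cluster consensus
polishing -> strand decoding -> file reassembly, with a stage-by-stage
report.

The clustering itself follows the greedy sphere scheme: unique reads
sorted by multiplicity, the most abundant unassigned read seeds a
cluster and absorbs everything within a fixed edit-distance radius.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from ._seq import revcomp
from .detailed_codec import (
    DEFAULT_LAYOUT,
    PrimerPair,
    SequenceLayout,
    StrandDecodeError,
    decode_interior,
    sequence_error_rate,
)

__all__ = [
    "ReadCluster",
    "DecodeReport",
    "locate_primer",
    "filter_and_trim",
    "cluster_reads",
    "select_top_n",
    "consensus_polish",
    "recover_file",
    "evaluate_against_originals",
]


@dataclass
class ReadCluster:
    """One greedy sphere cluster of trimmed reads."""

    centroid: str
    abundance: int
    member_ids: list[int] = field(default_factory=list)


@dataclass
class DecodeReport:
    """Stage counts and outcome of one file recovery."""

    n_reads_in: int = 0
    n_reads_passing_filter: int = 0
    n_clusters: int = 0
    n_strands_expected: int = 0
    n_strands_recovered: int = 0
    error_rate: float = 0.0
    shortfall: int = 0
    per_strand_status: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_reads_in": self.n_reads_in,
            "n_reads_passing_filter": self.n_reads_passing_filter,
            "n_clusters": self.n_clusters,
            "n_strands_expected": self.n_strands_expected,
            "n_strands_recovered": self.n_strands_recovered,
            "error_rate": self.error_rate,
            "shortfall": self.shortfall,
            "per_strand_status": self.per_strand_status,
        }


def locate_primer(read: str, primer: str, max_edits: int):
    """Best semi-global (infix) occurrence of primer in read.

    Returns (start, end, edits) with end exclusive, or None when no
    occurrence has <= max_edits edits.  Ties go to the smallest start.
    """
    if len(primer) < 4:
        raise ValueError("primer must be at least 4 nt")
    if not read:
        return None
    res = edlib.align(primer, read, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    locs = sorted((s if s is not None else 0, e) for s, e in res["locations"])
    start, end = locs[0]
    return start, end + 1, res["editDistance"]


def filter_and_trim(
    reads: Sequence[str],
    primer_pair: PrimerPair,
    layout: SequenceLayout = DEFAULT_LAYOUT,
    max_edits: int = 4,
    length_window: Optional[tuple[int, int]] = None,
) -> list[str]:
    """Keep reads anchored by both end primers; return trimmed interiors.

    Each read is tried as-is and reverse-complemented; it passes when
    the forward primer sits near the 5' end, the reverse-complemented
    reverse primer near the 3' end, and the trimmed interior length
    falls inside ``length_window`` (default: expected interior span
    +/- 12 nt).  Output is in canonical (forward) orientation.
    """
    if length_window is None:
        lo = layout.min_core_len + layout.rs_outer_len - 12
        hi = lo + (layout.seed_max_len - layout.seed_min_len) + 24
        length_window = (lo, hi)
    fwd = primer_pair.forward
    rev_rc = revcomp(primer_pair.reverse)
    n_primer = layout.pcr_primer_len
    head_span = n_primer + max_edits + 8

    out = []
    for read in reads:
        for oriented in (read, revcomp(read)):
            hit5 = locate_primer(oriented[:head_span], fwd, max_edits)
            if hit5 is None:
                continue
            tail = oriented[-head_span:]
            hit3 = locate_primer(tail, rev_rc, max_edits)
            if hit3 is None:
                continue
            start = hit5[1]
            end = len(oriented) - len(tail) + hit3[0]
            interior = oriented[start:end]
            if length_window[0] <= len(interior) <= length_window[1]:
                out.append(interior)
                break
    return out


def _distance(a: str, b: str, k: int) -> int:
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def cluster_reads(trimmed_reads: Sequence[str], radius: int = 3) -> list[ReadCluster]:
    """Greedy sphere clustering on Levenshtein distance.

    Unique sequences are ordered by multiplicity (descending,
    lexicographic tiebreak); the first unassigned sequence becomes a
    centroid and absorbs every unassigned sequence within ``radius``
    edits.  Output is sorted by (abundance desc, centroid lex).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    members: dict[str, list[int]] = {}
    for i, r in enumerate(trimmed_reads):
        members.setdefault(r, []).append(i)
    order = sorted(members, key=lambda s: (-len(members[s]), s))
    assigned = set()
    clusters: list[ReadCluster] = []
    for centroid in order:
        if centroid in assigned:
            continue
        assigned.add(centroid)
        ids = list(members[centroid])
        for other in order:
            if other in assigned:
                continue
            if abs(len(other) - len(centroid)) > radius:
                continue
            if radius == 0:
                continue
            if _distance(centroid, other, radius) != -1:
                assigned.add(other)
                ids.extend(members[other])
        clusters.append(ReadCluster(centroid, len(ids), sorted(ids)))
    clusters.sort(key=lambda c: (-c.abundance, c.centroid))
    return clusters


def select_top_n(clusters: Sequence[ReadCluster], n: int):
    """First n centroids by abundance; shortfall when fewer exist."""
    if n < 1:
        raise ValueError("n must be >= 1")
    picked = list(clusters[:n])
    return picked, max(0, n - len(picked))


def consensus_polish(
    members: Sequence[str],
    draft: Optional[str] = None,
    max_rounds: int = 2,
) -> str:
    """Alignment-vote consensus of a read cluster.

    Every member is globally aligned to the draft (initially the most
    common member); per draft position a majority vote chooses keep /
    substitute / delete, and majority-supported insertions between
    positions are applied.  One or two rounds suffice at nanopore-like
    error rates because per-position errors are independent.
    """
    if not members:
        raise ValueError("empty cluster")
    if draft is None:
        draft = Counter(members).most_common(1)[0][0]
    if len(members) < 3:
        return draft
    for _ in range(max_rounds):
        L = len(draft)
        base_votes = [Counter() for _ in range(L)]  # base or '-' per draft pos
        ins_votes = [Counter() for _ in range(L + 1)]  # insertion before pos
        for m in members:
            res = edlib.align(m, draft, mode="NW", task="path")
            nice = edlib.getNiceAlignment(res, m, draft)
            q, t = nice["query_aligned"], nice["target_aligned"]
            dpos = 0
            pending_ins = ""
            for qc, tc in zip(q, t):
                if tc == "-":
                    pending_ins += qc
                    continue
                if pending_ins:
                    ins_votes[dpos][pending_ins] += 1
                    pending_ins = ""
                else:
                    ins_votes[dpos][""] += 1
                base_votes[dpos][qc] += 1
                dpos += 1
            ins_votes[dpos][pending_ins if pending_ins else ""] += 1
        half = len(members) / 2

        def _winning_insert(counter: Counter) -> str:
            # an insertion wins when a majority of members insert
            # *something* here; the plurality string is applied
            support = sum(v for k, v in counter.items() if k)
            if support <= half:
                return ""
            return max((k for k in counter if k), key=lambda k: (counter[k], k))

        new = []
        for pos in range(L):
            new.append(_winning_insert(ins_votes[pos]))
            base, _ = base_votes[pos].most_common(1)[0]
            if base != "-":
                new.append(base)
        new.append(_winning_insert(ins_votes[L]))
        polished = "".join(new)
        if polished == draft:
            break
        draft = polished
    return draft


def recover_file(
    reads: Sequence[str],
    primer_pair: PrimerPair,
    n_strands: int,
    layout: SequenceLayout = DEFAULT_LAYOUT,
    max_edits: int = 4,
    cluster_radius: Optional[int] = None,
    consensus: bool = True,
):
    """Full read path: filter/trim, cluster, select, polish, decode.

    Returns (payload_bytes, DecodeReport).  Missing or undecodable
    strands yield a partial payload (missing chunks zero-filled) and
    per-strand statuses instead of an exception.

    The report's error_rate is the residual edit-distance rate between
    each decoded sequence and its RS-corrected reconstruction — zero
    when consensus polishing removed every channel error.
    """
    report = DecodeReport(n_reads_in=len(reads), n_strands_expected=n_strands)
    if cluster_radius is None:
        # wide enough that two same-strand reads at nanopore-like error
        # rates fall in one sphere, far below the distance of unrelated
        # payloads (~half the interior length)
        cluster_radius = (layout.min_core_len + layout.rs_outer_len) // 4
    trimmed = filter_and_trim(reads, primer_pair, layout, max_edits=max_edits)
    report.n_reads_passing_filter = len(trimmed)
    if not trimmed:
        return b"", report
    clusters = cluster_reads(trimmed, radius=cluster_radius)
    report.n_clusters = len(clusters)
    picked, report.shortfall = select_top_n(clusters, n_strands)

    chunks: dict[int, bytes] = {}
    total_dist = 0
    total_len = 0
    for ci, cluster in enumerate(picked):
        seq = cluster.centroid
        if consensus:
            seq = consensus_polish([trimmed[i] for i in cluster.member_ids], seq)
        status = {"cluster": ci, "abundance": cluster.abundance}
        try:
            index, chunk, corrected = decode_interior(seq, layout)
            dist = edlib.align(seq, corrected, mode="NW", task="distance")["editDistance"]
            total_dist += dist
            total_len += len(corrected)
            if index in chunks:
                status.update(status="duplicate_index", index=index)
            else:
                chunks[index] = chunk
                status.update(status="decoded", index=index, residual_edits=dist)
        except StrandDecodeError as exc:
            total_dist += len(seq)
            total_len += len(seq)
            status.update(status="failed", reason=str(exc))
        report.per_strand_status.append(status)

    report.n_strands_recovered = len(chunks)
    report.error_rate = (total_dist / total_len) if total_len else 1.0
    if not chunks:
        return b"", report

    n_chunks = max(max(chunks) + 1, n_strands)
    framed = b"".join(
        chunks.get(i, b"\x00" * layout.payload_bytes) for i in range(n_chunks)
    )
    length = int.from_bytes(framed[:2], "little")
    payload = framed[2 : 2 + length] if length <= len(framed) - 2 else framed[2:]
    return payload, report


def evaluate_against_originals(
    original_strands: Sequence[str], centroids: Sequence[str]
) -> float:
    """Edit-distance error rate of selected chains vs the true strands
    (minimum-cost assignment; unmatched originals count full length)."""
    return sequence_error_rate(original_strands, centroids)
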