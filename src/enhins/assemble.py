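"""Greedy exact-overlap assembly of initially unmapped reads into contigs.

Reads (including their reverse complements) are merged longest-overlap-first
with exact suffix/prefix overlaps of at least ``min_overlap`` bases; no
mismatches are tolerated in overlaps, because downstream verification demands
zero mismatches anyway.  Contigs are trimmed so every retained base has read
depth >= ``min_coverage``, and units to which nothing assembled are dropped.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .core_io import Read, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class Contig:
    id: str
    sequence: str
    member_read_ids: list[str]
    coverage: np.ndarray  # per-base read depth

    def __post_init__(self):
        if len(self.coverage) != len(self.sequence):
            raise ValueError("coverage length != sequence length")


@dataclass
class _Unit:
    uid: int
    seq: str
    cov: np.ndarray
    members: list[str]      # read ids
    n_distinct: int         # distinct source sequences merged in
    tie: str                # lexicographically smallest member read id

    def oriented(self, orient: str) -> str:
        return self.seq if orient == "f" else reverse_complement(self.seq)


def truncate_reads(reads: list[Read], prefix_len: int = 25) -> list[Read]:
    """Replace each read by its first ``prefix_len`` bases; used to homogenize
    heterogeneous read lengths before assembly.  Shorter reads are dropped."""
    out = []
    for read in reads:
        if len(read) < prefix_len:
            logger.warning("dropping read %s: length %d < prefix %d", read.id, len(read), prefix_len)
            continue
        out.append(Read(read.id, read.sequence[:prefix_len]))
    return out


def _best_overlap(sa: str, sb: str, min_overlap: int) -> int:
    """Longest o with min_overlap <= o <= len(sb) and sa[-o:] == sb[:o]; 0 if none."""
    if min_overlap > min(len(sa), len(sb)):
        return 0
    probe = sb[:min_overlap]
    p = sa.find(probe, max(0, len(sa) - len(sb)))
    while p != -1:
        o = len(sa) - p
        if o >= min_overlap and sa[p:] == sb[:o]:
            return o
        p = sa.find(probe, p + 1)
    return 0


def assemble_contigs(reads: list[Read], min_overlap: int = 20, min_coverage: int = 5) -> list[Contig]:
    """Greedy longest-overlap-first merging of reads into coverage-trimmed contigs.

    Ties between equal-length overlaps break on the lexicographically
    smallest member read id, making the output deterministic for a fixed
    input set.  Requires homogeneous read lengths; see :func:`truncate_reads`.
    """
    if not reads:
        return []
    lengths = {len(r) for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"heterogeneous read lengths {sorted(lengths)}; apply truncate_reads first")
    read_len = lengths.pop()
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    # collapse duplicate sequences (either orientation) into units; duplicate
    # multiplicity becomes the unit's base coverage
    by_canon: dict[str, _Unit] = {}
    next_uid = 0
    for read in sorted(reads, key=lambda r: r.id):
        canon = min(read.sequence, reverse_complement(read.sequence))
        unit = by_canon.get(canon)
        if unit is None:
            unit = _Unit(next_uid, canon, np.zeros(read_len, dtype=np.int32), [], 1, read.id)
            by_canon[canon] = unit
            next_uid += 1
        unit.cov += 1
        unit.members.append(read.id)
        unit.tie = min(unit.tie, read.id)

    alive: dict[int, _Unit] = {u.uid: u for u in by_canon.values()}
    heap: list = []

    def push_candidates(unit: _Unit) -> None:
        """Find and enqueue every merge involving ``unit`` (both roles, both orientations)."""
        for orient in "fr":
            s = unit.oriented(orient)
            for other in alive.values():
                if other.uid == unit.uid:
                    continue
                for oorient in "fr":
                    t = other.oriented(oorient)
                    o = _best_overlap(s, t, min_overlap)
                    if o:
                        heapq.heappush(heap, (-o, unit.tie, other.tie, orient, oorient,
                                              unit.uid, other.uid))
                    o = _best_overlap(t, s, min_overlap)
                    if o:
                        heapq.heappush(heap, (-o, other.tie, unit.tie, oorient, orient,
                                              other.uid, unit.uid))

    for unit in list(alive.values()):
        push_candidates(unit)

    while heap:
        neg_o, _, _, lo_, ro_, luid, ruid = heapq.heappop(heap)
        if luid not in alive or ruid not in alive:
            continue  # one side already consumed; duplicates land here too
        o = -neg_o
        lu, ru = alive[luid], alive[ruid]
        ls, rs = lu.oriented(lo_), ru.oriented(ro_)
        lcov = lu.cov if lo_ == "f" else lu.cov[::-1]
        rcov = ru.cov if ro_ == "f" else ru.cov[::-1]
        if o >= len(rs):  # right unit is a suffix-contained fragment of the left
            merged_seq = ls
            merged_cov = lcov.copy()
            merged_cov[len(ls) - o:] += rcov
        else:
            merged_seq = ls + rs[o:]
            merged_cov = np.concatenate([lcov, np.zeros(len(rs) - o, dtype=np.int32)])
            merged_cov[len(ls) - o:] += rcov
        del alive[luid], alive[ruid]
        merged = _Unit(
            uid=next_uid, seq=merged_seq, cov=merged_cov,
            members=lu.members + ru.members,
            n_distinct=lu.n_distinct + ru.n_distinct,
            tie=min(lu.tie, ru.tie),
        )
        next_uid += 1
        alive[merged.uid] = merged
        push_candidates(merged)

    # coverage trimming and invariant filtering
    read_seq = {r.id: r.sequence for r in reads}
    contigs: list[Contig] = []
    for unit in sorted(alive.values(), key=lambda u: u.tie):
        if unit.n_distinct < 2:
            continue  # a lone (possibly duplicated) read is not a contig
        start, length = _longest_covered_run(unit.cov, min_coverage)
        if length < read_len:
            continue
        seq = unit.seq[start:start + length]
        cov = unit.cov[start:start + length]
        members = sorted(
            rid for rid in set(unit.members)
            if read_seq[rid] in seq or reverse_complement(read_seq[rid]) in seq
        )
        if len(members) < 2:
            continue
        contigs.append(Contig(f"contig_{len(contigs) + 1}", seq, members, cov))
    return contigs


def _longest_covered_run(cov: np.ndarray, min_coverage: int) -> tuple[int, int]:
    """(start, length) of the longest contiguous run with depth >= min_coverage."""
    ok = cov >= min_coverage
    best_start = best_len = 0
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    if start is not None and len(ok) - start > best_len:
        best_start, best_len = start, len(ok) - start
    return best_start, best_len


def contigs_to_fasta(contigs: list[Contig], path) -> None:
    """Export contigs as FASTA; the description carries min/median coverage."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(
                f">{c.id} reads={len(c.member_read_ids)}"
                f" min_cov={int(c.coverage.min())} median_cov={int(np.median(c.coverage))}\n"
            )
            fh.write(c.sequence + "\n")
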