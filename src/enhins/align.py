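"""Gapless and gapped read alignment plus the exhaustive verification step.

Three aligners cooperate:

* :func:`map_ungapped` — the first pass: unique best-stratum full-length
  gapless placement with a small mismatch budget (pigeonhole-seeded, exact).
* :func:`map_gapped` — the rescue pass: glocal alignment of the whole query
  against the genome permitting one gap run (a single insertion or a single
  deletion), the only structures any downstream consumer accepts.
* :func:`verify_hit` — an independent exhaustive re-alignment around the
  gapped hit's locus that accepts a hit only if the entire sequence places
  with exactly one insertion, zero mismatches, and an insertion no longer
  than the configured cap; accepted hits are left-normalized.

Scoring: match +1, mismatch -1; a gap of length L costs 2 + L
(open 2, extend 1 per base).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .core_io import GenomeSequence, Read, left_normalize, reverse_complement, ALPHABET

MATCH = 1
MISMATCH = -1
GAP_OPEN = 2
GAP_EXTEND = 1

_NEG = -(10 ** 6)


@dataclass(frozen=True)
class CigarOp:
    op: str  # M, I or D
    length: int

    def __post_init__(self):
        if self.op not in "MID":
            raise ValueError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR op length {self.length} < 1")


def cigar_string(cigar: list[CigarOp]) -> str:
    return "".join(f"{c.length}{c.op}" for c in cigar)


def parse_cigar(text: str) -> list[CigarOp]:
    ops, num = [], ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            ops.append(CigarOp(ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"trailing number in CIGAR {text!r}")
    return ops


def query_span(cigar: list[CigarOp]) -> int:
    return sum(c.length for c in cigar if c.op in "MI")


def reference_span(cigar: list[CigarOp]) -> int:
    return sum(c.length for c in cigar if c.op in "MD")


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a query on the genome, in plus-strand coordinates.

    ``aligned_sequence`` is the query as it reads on the reference plus
    strand (i.e. reverse-complemented when ``strand`` is '-'), so CIGAR
    arithmetic against it is strand-free.
    """

    query_id: str
    chrom: str
    start: int
    strand: str
    cigar: tuple[CigarOp, ...]
    mismatches: int
    score: int
    unique: bool
    aligned_sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if query_span(list(self.cigar)) != len(self.aligned_sequence):
            raise ValueError("CIGAR read-consuming length != query length")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")

    @property
    def end(self) -> int:
        return self.start + reference_span(list(self.cigar))

    @property
    def cigar_string(self) -> str:
        return cigar_string(list(self.cigar))


@dataclass(frozen=True)
class Unmapped:
    query_id: str
    reason: str  # no_hit | ambiguous

    def __post_init__(self):
        if self.reason not in ("no_hit", "ambiguous"):
            raise ValueError(f"bad unmapped reason {self.reason!r}")


MappingResult = AlignmentHit | Unmapped


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def _count_mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# gapless pass
# ---------------------------------------------------------------------------


def map_ungapped(read: Read | str, genome: GenomeSequence, max_mismatches: int = 2,
                 query_id: str = "query") -> MappingResult:
    """Unique best-stratum full-length gapless placement on either strand.

    Exact by pigeonhole seeding: the read is split into ``max_mismatches + 1``
    disjoint chunks; any placement within the mismatch budget matches at
    least one chunk exactly, so looking chunks up in a genome k-mer index
    enumerates every qualifying placement.  The best stratum is the minimal
    mismatch count; ties there are ambiguous (multireads are discarded).
    """
    if isinstance(read, Read):
        seq, query_id = read.sequence, read.id
    else:
        seq = read
    _check_alphabet(seq, f"read {query_id!r}")
    m = len(seq)
    k = m // (max_mismatches + 1)
    if k < 1:
        raise ValueError(f"read {query_id!r} too short for {max_mismatches} mismatches")
    index = genome.kmer_index(k)
    lengths = genome.lengths

    placements: list[tuple[int, str, int, str]] = []  # (mismatches, chrom, start, strand)
    seen: set[tuple[str, int, str]] = set()
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        for chunk in range(max_mismatches + 1):
            off = chunk * k
            for chrom, pos in index.get(oriented[off:off + k], ()):
                start = pos - off
                if start < 0 or start + m > lengths[chrom]:
                    continue
                site = (chrom, start, strand)
                if site in seen:
                    continue
                seen.add(site)
                mm = _count_mismatches(oriented, genome[chrom][start:start + m])
                if mm <= max_mismatches:
                    placements.append((mm, chrom, start, strand))

    if not placements:
        return Unmapped(query_id, "no_hit")
    best = min(p[0] for p in placements)
    top = [p for p in placements if p[0] == best]
    if len(top) > 1:
        return Unmapped(query_id, "ambiguous")
    mm, chrom, start, strand = top[0]
    aligned = seq if strand == "+" else reverse_complement(seq)
    return AlignmentHit(
        query_id=query_id, chrom=chrom, start=start, strand=strand,
        cigar=(CigarOp("M", m),), mismatches=mm,
        score=(m - mm) * MATCH + mm * MISMATCH, unique=True, aligned_sequence=aligned,
    )


# ---------------------------------------------------------------------------
# gapped pass (single-gap glocal DP, whole genome, both strands)
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _score_last_row(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Score-only single-gap glocal DP; returns the final-row best over end columns.

    The alignment automaton allows matches/mismatches plus at most ONE gap
    run (an insertion or a deletion), mirroring the single-insertion /
    single-deletion structure every downstream consumer demands.  States:
    A = no gap yet, X = in the insertion run, Y = in the deletion run,
    B = matching after the gap closed.  The whole query is consumed;
    reference start and end are free.
    """
    n = ref.size
    m = query.size
    open_ext = GAP_OPEN + GAP_EXTEND
    a_prev = np.zeros(n + 1, dtype=np.int32)       # A[0][j] = 0: free start
    x_prev = np.full(n + 1, _NEG, dtype=np.int32)
    y_prev = np.full(n + 1, _NEG, dtype=np.int32)
    b_prev = np.full(n + 1, _NEG, dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(m):
        sub = np.where(ref == query[i], MATCH, MISMATCH).astype(np.int32)
        a_row = np.full(n + 1, _NEG, dtype=np.int32)
        a_row[1:] = a_prev[:-1] + sub
        x_row = np.maximum(a_prev - open_ext, x_prev - GAP_EXTEND)
        # Y[i][j] = max_{k<j} (A[i][k] + k) - GAP_OPEN - j  (deletion run, same row)
        running = np.maximum.accumulate(a_row + idx)
        y_row = np.full(n + 1, _NEG, dtype=np.int32)
        y_row[1:] = running[:-1] - GAP_OPEN - idx[1:]
        b_row = np.full(n + 1, _NEG, dtype=np.int32)
        b_row[1:] = np.maximum(np.maximum(b_prev[:-1], x_prev[:-1]), y_prev[:-1]) + sub
        a_prev, x_prev, y_prev, b_prev = a_row, x_row, y_row, b_row
    return np.maximum(np.maximum(a_prev, x_prev), b_prev)


def _traceback(query: np.ndarray, ref: np.ndarray) -> tuple[int, list[CigarOp], int, int]:
    """Single-gap DP with stored matrices over a small reference window.

    Returns (ref start offset, cigar, mismatches, score).  State preference
    in traceback is deterministic: A (no gap) over B over X over Y.
    """
    n = ref.size
    m = query.size
    open_ext = GAP_OPEN + GAP_EXTEND
    A = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    B = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    A[0, :] = 0
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = np.where(ref == query[i - 1], MATCH, MISMATCH).astype(np.int32)
        A[i, 1:] = A[i - 1, :-1] + sub
        X[i, :] = np.maximum(A[i - 1, :] - open_ext, X[i - 1, :] - GAP_EXTEND)
        running = np.maximum.accumulate(A[i, :] + idx)
        Y[i, 1:] = running[:-1] - GAP_OPEN - idx[1:]
        B[i, 1:] = np.maximum(np.maximum(B[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1]) + sub

    final = np.maximum(np.maximum(A[m, :], X[m, :]), B[m, :])
    j = int(final.argmax())
    score = int(final[j])
    if A[m, j] == score:
        state = "A"
    elif B[m, j] == score:
        state = "B"
    else:
        state = "X"
    i = m
    ops: list[str] = []
    mismatches = 0
    while i > 0:
        if state in ("A", "B"):
            ops.append("M")
            if ref[j - 1] != query[i - 1]:
                mismatches += 1
            if state == "A":
                i, j = i - 1, j - 1
            else:
                prev = B[i, j] - (MATCH if ref[j - 1] == query[i - 1] else MISMATCH)
                i, j = i - 1, j - 1
                if B[i, j] == prev:
                    state = "B"
                elif X[i, j] == prev:
                    state = "X"
                else:
                    state = "Y"
        elif state == "X":
            ops.append("I")
            if X[i, j] == X[i - 1, j] - GAP_EXTEND:
                i -= 1
            else:
                i -= 1
                state = "A"
        else:  # Y: deletion run, consumes reference only
            ops.append("D")
            if j >= 2 and Y[i, j] == Y[i, j - 1] - GAP_EXTEND:
                j -= 1
            else:
                j -= 1
                state = "A"

    ops.reverse()
    cigar: list[CigarOp] = []
    for op in ops:
        if cigar and cigar[-1].op == op:
            cigar[-1] = CigarOp(op, cigar[-1].length + 1)
        else:
            cigar.append(CigarOp(op, 1))
    # strip leading/trailing deletions (free reference ends make them vacuous)
    start = j
    while cigar and cigar[0].op == "D":
        start += cigar[0].length
        cigar.pop(0)
    while cigar and cigar[-1].op == "D":
        cigar.pop()
    return start, cigar, mismatches, score


def map_gapped(seq: str, genome: GenomeSequence, query_id: str = "query") -> MappingResult:
    """Best single-gap glocal placement of the whole query, either strand.

    The DP is run over every chromosome on both strands; the single
    best-scoring end cell wins and ties (distinct best end cells) are
    ambiguous.  The returned CIGAR retains the I or D run and feeds the
    verification and extraction stages downstream.
    """
    _check_alphabet(seq, f"query {query_id!r}")
    if len(seq) < 20:
        raise ValueError(f"query {query_id!r}: gapped alignment needs length >= 20")

    m = len(seq)
    best_score = None
    n_best = 0
    best_site = None  # (chrom, strand, end_col)
    for chrom, ref_str in genome.sequences.items():
        ref = _encode(ref_str)
        for strand in "+-":
            oriented = seq if strand == "+" else reverse_complement(seq)
            final = _score_last_row(_encode(oriented), ref)
            top = int(final.max())
            if best_score is None or top > best_score:
                best_score = top
                n_best = int((final == top).sum())
                best_site = (chrom, strand, int(final.argmax()))
            elif top == best_score:
                n_best += int((final == top).sum())

    if best_site is None:
        return Unmapped(query_id, "no_hit")
    if n_best > 1:
        return Unmapped(query_id, "ambiguous")

    chrom, strand, end_col = best_site
    oriented = seq if strand == "+" else reverse_complement(seq)
    # window re-run for traceback: the alignment's reference span is bounded
    # by m plus the deletion budget a positive score permits
    ws = max(0, end_col - (2 * m + 8))
    ref_win = _encode(genome[chrom][ws:end_col])
    off, cigar, mismatches, score = _traceback(_encode(oriented), ref_win)
    assert score == best_score, "traceback window missed the optimum"
    return AlignmentHit(
        query_id=query_id, chrom=chrom, start=ws + off, strand=strand,
        cigar=tuple(cigar), mismatches=mismatches, score=score,
        unique=True, aligned_sequence=oriented,
    )


# ---------------------------------------------------------------------------
# verification (exhaustive zero-mismatch single-insertion realignment)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerifyResult:
    accepted: bool
    hit: AlignmentHit | None = None
    reason: str | None = None  # no_insertion | mismatch | too_long | ambiguous


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def verify_hit(seq: str, genome: GenomeSequence, hit: AlignmentHit,
               max_insertion: int = 20, window: int = 150) -> VerifyResult:
    """Independent exhaustive re-alignment around ``hit``'s locus.

    Every whole-sequence placement with at most one insertion (every
    reference start within ``window`` bp of the hit, every split point, every
    insertion length, mismatches scored) is enumerated directly; the best
    placement by score must consume the entire sequence with exactly one
    insertion, zero mismatches, an insertion no longer than ``max_insertion``
    and must be unique after left-normalization.  ``seq`` must be the
    plus-strand oriented sequence (``hit.aligned_sequence``).
    """
    L = len(seq)
    chrom_seq = genome[hit.chrom]
    lo = max(0, hit.start - window)
    hi = min(len(chrom_seq), hit.end + window)
    n_starts = hi - lo
    if n_starts <= 0:
        return VerifyResult(False, reason="mismatch")

    # cumulative per-offset mismatch table over the padded local window; the
    # '#' padding carries a prohibitive penalty so placements reaching past
    # the window (or the chromosome end) can never win
    local = chrom_seq[lo:min(len(chrom_seq), hi + L)]
    padded = ("#" * L) + local + ("#" * L)
    r = np.frombuffer(padded.encode(), dtype=np.uint8)
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    offsets = np.arange(len(local) + L + 1)
    cols = offsets[:, None] + np.arange(L)[None, :]
    neq = (r[cols] != q[None, :]).astype(np.int32)
    neq[r[cols] == ord("#")] = 10_000
    MM = np.concatenate(
        [np.zeros((neq.shape[0], 1), dtype=np.int32), np.cumsum(neq, axis=1)], axis=1
    )
    starts = np.arange(n_starts)  # local; global p = lo + start

    best_score = None
    best: list[tuple[int, int, int, int]] = []  # (p_global, left, ins_len, mismatches)
    for ins_len in range(0, L):
        aligned_len = L - ins_len
        gap_cost = 0 if ins_len == 0 else GAP_OPEN + ins_len * GAP_EXTEND
        lefts = range(0, aligned_len + 1) if ins_len else (aligned_len,)
        for left in lefts:
            mm_left = MM[starts + L, left]
            o_right = starts - ins_len + L
            mm = mm_left + MM[o_right, L] - MM[o_right, left + ins_len]
            score = (aligned_len - mm) * MATCH + mm * MISMATCH - gap_cost
            top = int(score.max())
            if best_score is None or top > best_score:
                best_score = top
                best = [(lo + int(p), left, ins_len, int(mm[p])) for p in np.nonzero(score == top)[0]]
            elif top == best_score:
                best.extend(
                    (lo + int(p), left, ins_len, int(mm[p])) for p in np.nonzero(score == top)[0]
                )

    if any(ins_len == 0 and mm == 0 for _, _, ins_len, mm in best):
        # a gapless zero-mismatch placement wins: there is no insertion to call
        return VerifyResult(False, reason="no_insertion")
    clean = [(p, left, i, mm) for p, left, i, mm in best if mm == 0 and i >= 1]
    if not clean:
        return VerifyResult(False, reason="mismatch")

    # collapse rotation-equivalent placements onto one left-normalized key
    keys = {}
    for p, left, i, _ in clean:
        anchor, inserted = left_normalize(chrom_seq, p + left - 1, seq[left:left + i])
        keys.setdefault((anchor, inserted), (p, left, i))
    if len(keys) > 1:
        return VerifyResult(False, reason="ambiguous")
    ((anchor, inserted), (p, left, i)) = next(iter(keys.items()))
    if i > max_insertion:
        return VerifyResult(False, reason="too_long")

    # canonical hit: the query is a window of the alternate haplotype starting
    # at ref position p, so the normalized insertion sits at query offset
    # anchor + 1 - p (clamped to 0 when the window starts inside the repeat run)
    left_len = max(0, anchor + 1 - p)
    cigar = []
    if left_len > 0:
        cigar.append(CigarOp("M", left_len))
    cigar.append(CigarOp("I", i))
    if L - i - left_len > 0:
        cigar.append(CigarOp("M", L - i - left_len))
    canonical = AlignmentHit(
        query_id=hit.query_id, chrom=hit.chrom, start=p, strand=hit.strand,
        cigar=tuple(cigar), mismatches=0, score=(L - i) * MATCH - GAP_OPEN - i * GAP_EXTEND,
        unique=True, aligned_sequence=seq,
    )
    return VerifyResult(True, hit=canonical)


def verify_deletion(seq: str, genome: GenomeSequence, hit: AlignmentHit,
                    window: int = 150) -> AlignmentHit | None:
    """Exhaustive zero-mismatch M-D-M check for the contig-only deletion caller.

    Returns the left-normalized canonical hit iff the whole sequence places
    with exactly one deletion, zero insertions and zero mismatches, uniquely
    (minimal deletion length, distinct normalized placements collapse).
    """
    L = len(seq)
    chrom_seq = genome[hit.chrom]
    lo = max(0, hit.start - window)
    hi = min(len(chrom_seq), hit.end + window)

    placements: list[tuple[int, int, int]] = []  # (del_len, ref_start, left_len)
    for p in range(lo, hi):
        lcp = _common_prefix(seq, chrom_seq[p:p + L])
        if lcp == L:
            return None  # exact match: no deletion
        for d in range(1, hi - p):
            e = p + L + d
            if e > len(chrom_seq):
                break
            right = _common_suffix(seq, chrom_seq[max(0, e - L):e])
            need = L
            lo_left = max(1, need - right)   # both M segments non-empty
            hi_left = min(lcp, L - 1)
            if lo_left <= hi_left:
                placements.append((d, p, lo_left))
    if not placements:
        return None
    best_d = min(p[0] for p in placements)
    spans = set()
    chosen = None
    for d, p, left in placements:
        if d != best_d:
            continue
        del_start, del_end = p + left, p + left + d
        while del_start > 0 and chrom_seq[del_start - 1] == chrom_seq[del_end - 1]:
            del_start -= 1
            del_end -= 1
        if (del_start, del_end) not in spans:
            spans.add((del_start, del_end))
            chosen = (d, del_start, del_end)
    if len(spans) > 1:
        return None
    d, del_start, del_end = chosen
    # recover the left segment length consistent with the normalized deletion span:
    # seq = ref[start:del_start] + ref[del_end:del_end + (L - left_len)]
    for cand in range(1, L):
        s0 = del_start - cand
        if s0 < 0:
            break
        if chrom_seq[s0:del_start] == seq[:cand] and chrom_seq[del_end:del_end + L - cand] == seq[cand:]:
            left_len = cand
            start = s0
            break
    else:
        return None
    cigar = (CigarOp("M", left_len), CigarOp("D", d), CigarOp("M", L - left_len))
    return AlignmentHit(
        query_id=hit.query_id, chrom=hit.chrom, start=start, strand=hit.strand,
        cigar=cigar, mismatches=0, score=L * MATCH - GAP_OPEN - d * GAP_EXTEND,
        unique=True, aligned_sequence=seq,
    )


def hits_consistent(hit_a: AlignmentHit, hit_b: AlignmentHit, tolerance: int = 100) -> bool:
    """True iff two placements of the same query are on one chromosome within ``tolerance`` bp."""
    if hit_a.query_id != hit_b.query_id:
        raise ValueError(f"hits are for different queries: {hit_a.query_id!r} vs {hit_b.query_id!r}")
    return hit_a.chrom == hit_b.chrom and abs(hit_a.start - hit_b.start) <= tolerance


def reconstruct_query(hit: AlignmentHit, genome: GenomeSequence) -> str:
    """Rebuild the plus-strand query from reference plus CIGAR (I segments from the query)."""
    out = []
    rpos, qpos = hit.start, 0
    for op in hit.cigar:
        if op.op == "M":
            out.append(genome[hit.chrom][rpos:rpos + op.length])
            rpos += op.length
            qpos += op.length
        elif op.op == "I":
            out.append(hit.aligned_sequence[qpos:qpos + op.length])
            qpos += op.length
        else:
            rpos += op.length
    return "".join(out)


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------


def write_sam(hits: Iterable[AlignmentHit], genome: GenomeSequence, path: str | Path) -> None:
    """Write hits as a plain-text SAM file (NM carries the mismatch count)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths.items()],
    }
    names = list(genome.lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hit in hits:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = hit.query_id
            seg.query_sequence = hit.aligned_sequence
            seg.flag = 16 if hit.strand == "-" else 0
            seg.reference_id = names.index(hit.chrom)
            seg.reference_start = hit.start
            seg.mapping_quality = 255
            seg.cigarstring = hit.cigar_string
            seg.set_tag("NM", hit.mismatches)
            seg.set_tag("AS", hit.score)
            out.write(seg)
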