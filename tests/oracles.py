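"""Independent brute-force oracles used to check the production code paths.

These deliberately share nothing with the implementations they validate
except the published scoring constants.
"""

from __future__ import annotations

import numpy as np

from enhins.core_io import GenomeSequence, reverse_complement


def brute_force_ungapped(seq: str, genome: GenomeSequence, max_mismatches: int):
    """Every full-length gapless placement (both strands) within the budget,
    by scanning every offset and counting mismatches directly."""
    m = len(seq)
    placements = []
    for strand, oriented in (("+", seq), ("-", reverse_complement(seq))):
        for chrom, ref in genome.sequences.items():
            for start in range(len(ref) - m + 1):
                mm = sum(a != b for a, b in zip(oriented, ref[start:start + m]))
                if mm <= max_mismatches:
                    placements.append((mm, chrom, start, strand))
    return placements


def split_point_align(seq: str, genome: GenomeSequence):
    """Exhaustive split-point oracle over single-gap decompositions.

    Enumerates every (reference start, left-length, gap-length) decomposition
    of the query on both strands: gapless, one insertion (M-I-M, any split
    including a gap at either end) and one deletion (M-D-M, both M segments
    non-empty).  Scores match +1 / mismatch -1 and charge 2 + L for a gap of
    length L.  Mismatch counts come from per-offset cumulative tables, so
    this is a direct enumeration, not a DP.

    Returns (best_score, placements); each placement is
    (chrom, start, strand, left_len, gap_op, gap_len) with gap_op in
    {None, 'I', 'D'}.
    """
    L = len(seq)
    best = None
    placements: list[tuple] = []

    # boundary penalty: large enough that no invalid placement can win, small
    # enough that cumulative sums stay within int16
    PEN = 300

    def block_mm(MM, n, kind, param):
        """Mismatch matrix (n_starts x n_lefts) for one gap configuration.

        kind None: gapless; 'I': insertion of length param, splits 0..L-param;
        'D': deletion of length param, splits 1..L-1.
        """
        ML = MM[L:L + n, :]
        if kind is None:
            return ML[:, L][:, None]
        if kind == "I":
            i = param
            MR = MM[L - i:L - i + n, :]
            return ML[:, : L - i + 1] + MR[:, L][:, None] - MR[:, i:L + 1]
        d = param
        MR = MM[L + d:L + d + n, :]
        return ML[:, 1:L] + MR[:, L][:, None] - MR[:, 1:L]

    def block_base(kind, param):
        """Score when mismatches are zero."""
        if kind is None:
            return L
        if kind == "I":
            return (L - param) - (2 + param)
        return L - (2 + param)

    blocks = [(None, 0, L)] + [("I", i, 0) for i in range(1, L)] + \
             [("D", d, 1) for d in range(1, L + 1)]
    tables = {}
    for strand in "+-":
        oriented = seq if strand == "+" else reverse_complement(seq)
        q = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for chrom, ref in genome.sequences.items():
            n = len(ref)
            padded = ("#" * L) + ref + ("#" * (2 * L))
            r = np.frombuffer(padded.encode(), dtype=np.uint8)
            offsets = np.arange(n + 2 * L + 1)
            cols = offsets[:, None] + np.arange(L)[None, :]
            neq = (r[cols] != q[None, :]).astype(np.int16)
            neq[r[cols] == ord("#")] = PEN  # out of range: placement invalid
            MM = np.concatenate(
                [np.zeros((neq.shape[0], 1), dtype=np.int16), np.cumsum(neq, axis=1, dtype=np.int16)],
                axis=1,
            )
            tables[(strand, chrom)] = (MM, n)
            for kind, param, _ in blocks:
                top = block_base(kind, param) - 2 * int(block_mm(MM, n, kind, param).min())
                if best is None or top > best:
                    best = top

    # second pass: collect placements only from blocks achieving the optimum
    for (strand, chrom), (MM, n) in tables.items():
        for kind, param, left0 in blocks:
            delta = block_base(kind, param) - best
            if delta < 0 or delta % 2:
                continue
            mm_needed = delta // 2
            mm = block_mm(MM, n, kind, param)
            if int(mm.min()) == mm_needed:
                placements.extend(
                    (chrom, int(p), strand, left0 + int(c), kind, param)
                    for p, c in np.argwhere(mm == mm_needed)
                )

    return best, placements


def smallest_containing_loop(chrom: str, pos: int, loops):
    """Brute-force minimum-span containing loop (leftmost, then input order on ties)."""
    containing = [
        (lp.span_length, lp.span[0], idx, lp)
        for idx, lp in enumerate(loops)
        if lp.chrom == chrom and lp.span[0] <= pos < lp.span[1]
    ]
    if not containing:
        return None
    return min(containing)[3]
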