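"""Per-sample insertion discovery: peaks, rescue of unmapped reads/contigs,
insertion extraction and filtering, catalogue construction, and the
contig-only deletion caller.

The rescue flow for every initially unmapped read and every contig assembled
from them is: gapped alignment -> exhaustive zero-mismatch verification ->
positional consistency between the two placements (<= 100 bp) -> CIGAR-based
insertion extraction.  Read- and contig-derived calls with the same
left-normalized key are merged with support summed.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .align import (
    AlignmentHit,
    Unmapped,
    hits_consistent,
    map_gapped,
    map_ungapped,
    verify_deletion,
    verify_hit,
)
from .assemble import Contig, assemble_contigs
from .core_io import CatalogueEntry, GenomeSequence, Peak, Read, VariantKey, left_normalize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InsertionCall:
    key: VariantKey
    sample: str
    source: str  # read | contig
    query_id: str
    hit: AlignmentHit

    def __post_init__(self):
        if self.source not in ("read", "contig"):
            raise ValueError(f"bad source {self.source!r}")


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int
    end: int  # deleted reference interval, 0-based half-open
    sample: str
    contig_id: str

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("deletion interval must span >= 1 base")


@dataclass
class StageCounts:
    """Structured per-stage accounting for one sample run."""

    total_reads: int = 0
    mapped: int = 0
    unmapped_no_hit: int = 0
    unmapped_ambiguous: int = 0
    contigs: int = 0
    rescued: int = 0
    verified: int = 0
    in_enhancer: int = 0
    rejections: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "rejections"}
        d["rejections"] = dict(self.rejections)
        return d


# ---------------------------------------------------------------------------
# peak calling (sliding-window Poisson stand-in for MACS)
# ---------------------------------------------------------------------------


def call_peaks(
    aligned_read_positions: list[tuple[str, int]],
    genome: GenomeSequence,
    control_positions: list[tuple[str, int]] | None = None,
    p_threshold: float = 1e-9,
    window: int = 500,
    step: int = 50,
) -> list[Peak]:
    """Sliding-window Poisson enrichment against a local/global background.

    Duplicate reads at a single position are capped at the count expected by
    chance plus a margin (the keep-dup analogue).  Windows with upper-tail
    probability below ``p_threshold`` are merged into peaks.  A supplied peak
    BED bypasses this stage entirely.
    """
    if not aligned_read_positions:
        return []

    def binned_counts(positions: list[tuple[str, int]], cap: int | None) -> dict[str, np.ndarray]:
        per_chrom: dict[str, Counter] = defaultdict(Counter)
        for chrom, pos in positions:
            per_chrom[chrom][pos] += 1
        out = {}
        for chrom, counts in per_chrom.items():
            arr = np.zeros(genome.lengths[chrom], dtype=np.int64)
            for pos, c in counts.items():
                arr[pos] = min(c, cap) if cap else c
            out[chrom] = arr
        return out

    total_len = genome.total_length
    n_reads = len(aligned_read_positions)
    lam_pos = n_reads / total_len
    dup_cap = max(1, int(poisson.ppf(1 - 1e-5, lam_pos)) + 1)
    treat = binned_counts(aligned_read_positions, dup_cap)
    n_treat = int(sum(arr.sum() for arr in treat.values()))

    ctrl = None
    n_ctrl = 0
    if control_positions:
        ctrl = binned_counts(control_positions, None)
        n_ctrl = len(control_positions)

    peaks: list[Peak] = []
    for chrom, arr in treat.items():
        length = len(arr)
        csum = np.concatenate([[0], np.cumsum(arr)])
        if ctrl is not None and chrom in ctrl:
            ccum = np.concatenate([[0], np.cumsum(ctrl[chrom])])
        else:
            ccum = None
        sig_windows = []
        for ws in range(0, max(1, length - window + 1), step):
            we = min(ws + window, length)
            count = csum[we] - csum[ws]
            if count == 0:
                continue
            if ccum is not None and n_ctrl > 0:
                lam = (ccum[we] - ccum[ws]) * (n_treat / n_ctrl)
                lam = max(lam, n_treat * (we - ws) / total_len)  # floor at genome-wide rate
            else:
                lam = n_treat * (we - ws) / total_len
            if poisson.sf(count - 1, lam) < p_threshold:
                sig_windows.append((ws, we))
        for ws, we in sig_windows:
            if peaks and peaks[-1].chrom == chrom and ws <= peaks[-1].end:
                peaks[-1] = Peak(chrom, peaks[-1].start, max(peaks[-1].end, we))
            else:
                peaks.append(Peak(chrom, ws, we))
    return peaks


# ---------------------------------------------------------------------------
# insertion extraction and rescue
# ---------------------------------------------------------------------------


def extract_insertion(
    hit: AlignmentHit,
    genome: GenomeSequence,
    sample: str,
    source: str = "read",
    min_flank: int = 5,
    max_insertion: int | None = None,
) -> InsertionCall | None:
    """Turn a verified single-insertion hit into a left-normalized call.

    The hit's CIGAR is authoritative: the single I op's query segment becomes
    the inserted sequence, anchored at the reference base preceding the op.
    Requires >= ``min_flank`` aligned bases on each side of the insertion
    (an insertion at a read end is indistinguishable from a clipped edge).
    """
    i_ops = [op for op in hit.cigar if op.op == "I"]
    if len(i_ops) != 1:
        return None
    qpos = rlen = 0
    left_flank = right_flank = 0
    seen_i = False
    ins_qstart = ins_len = 0
    for op in hit.cigar:
        if op.op == "M":
            if seen_i:
                right_flank += op.length
            else:
                left_flank += op.length
            qpos += op.length
            rlen += op.length
        elif op.op == "I":
            ins_qstart, ins_len = qpos, op.length
            qpos += op.length
            seen_i = True
        else:
            rlen += op.length
    if left_flank < min_flank or right_flank < min_flank:
        return None
    if max_insertion is not None and ins_len > max_insertion:
        return None

    ref_offset = sum(op.length for op in hit.cigar[: next(
        i for i, op in enumerate(hit.cigar) if op.op == "I")] if op.op in "MD")
    anchor = hit.start + ref_offset - 1
    inserted = hit.aligned_sequence[ins_qstart:ins_qstart + ins_len]
    anchor, inserted = left_normalize(genome[hit.chrom], anchor, inserted)
    if ins_len > 31:
        return None  # outside the representable key range
    key = VariantKey(hit.chrom, anchor, inserted)
    return InsertionCall(key=key, sample=sample, source=source, query_id=hit.query_id, hit=hit)


def _rescue_one(
    seq: str,
    query_id: str,
    genome: GenomeSequence,
    sample: str,
    source: str,
    max_insertion: int,
    min_flank: int,
    tolerance: int,
    counts: StageCounts,
) -> InsertionCall | None:
    gapped = map_gapped(seq, genome, query_id=query_id)
    if isinstance(gapped, Unmapped):
        counts.rejections[f"gapped_{gapped.reason}"] += 1
        return None
    if not any(op.op == "I" for op in gapped.cigar):
        counts.rejections["no_I_in_cigar"] += 1
        return None
    counts.rescued += 1
    verdict = verify_hit(gapped.aligned_sequence, genome, gapped, max_insertion=max_insertion)
    if not verdict.accepted:
        counts.rejections[f"verify_{verdict.reason}"] += 1
        return None
    if not hits_consistent(gapped, verdict.hit, tolerance):
        counts.rejections["inconsistent_hits"] += 1
        return None
    counts.verified += 1
    # extract from the canonical verified hit: it is zero-mismatch and
    # left-normalized, whereas the DP hit may have tie-broken onto an
    # equivalent-scoring mismatched path
    call = extract_insertion(verdict.hit, genome, sample, source=source,
                             min_flank=min_flank, max_insertion=max_insertion)
    if call is None:
        counts.rejections["extraction_failed"] += 1
    return call


def rescue_unmapped(
    unmapped_reads: list[Read],
    genome: GenomeSequence,
    sample: str = "sample",
    min_overlap: int = 20,
    min_coverage: int = 5,
    max_insertion: int = 20,
    min_flank: int = 5,
    tolerance: int = 100,
    counts: StageCounts | None = None,
) -> tuple[list[InsertionCall], list[Contig]]:
    """Rescue insertions from initially unmapped reads and from contigs
    assembled out of those same reads; calls are merged per key downstream."""
    counts = counts if counts is not None else StageCounts()
    contigs = assemble_contigs(unmapped_reads, min_overlap=min_overlap, min_coverage=min_coverage)
    counts.contigs = len(contigs)

    calls: list[InsertionCall] = []
    for read in unmapped_reads:
        call = _rescue_one(read.sequence, read.id, genome, sample, "read",
                           max_insertion, min_flank, tolerance, counts)
        if call is not None:
            calls.append(call)
    for contig in contigs:
        call = _rescue_one(contig.sequence, contig.id, genome, sample, "contig",
                           max_insertion, min_flank, tolerance, counts)
        if call is not None:
            calls.append(call)
    return calls, contigs


def filter_enhancer_overlap(calls: list[InsertionCall], peaks: list[Peak]) -> list[InsertionCall]:
    """Keep calls whose anchor lies within [start, end) of some peak."""
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for peak in peaks:
        by_chrom[peak.chrom].append(peak)
    kept = []
    for call in calls:
        pos = call.key.position
        if any(p.start <= pos < p.end for p in by_chrom.get(call.key.chrom, ())):
            kept.append(call)
    return kept


def build_catalogue(per_sample_calls: list[InsertionCall]) -> list[CatalogueEntry]:
    """Group calls by key across samples into catalogue entries."""
    grouped: dict[VariantKey, list[InsertionCall]] = defaultdict(list)
    for call in per_sample_calls:
        grouped[call.key].append(call)
    entries = []
    for key in sorted(grouped):
        calls = grouped[key]
        entries.append(
            CatalogueEntry(
                key=key,
                samples=frozenset(c.sample for c in calls),
                support=len(calls),
                sources=frozenset(c.source for c in calls),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# contig-only deletion calling
# ---------------------------------------------------------------------------


def call_deletions(contigs: list[Contig], genome: GenomeSequence, sample: str = "sample") -> list[DeletionCall]:
    """Deletions are called from contigs only: the alignment must be exactly
    one D between two Ms, zero I ops and zero mismatches."""
    calls = []
    for contig in contigs:
        gapped = map_gapped(contig.sequence, genome, query_id=contig.id)
        if isinstance(gapped, Unmapped):
            continue
        ops = [op.op for op in gapped.cigar]
        if ops.count("I") != 0 or ops.count("D") != 1 or ops != ["M", "D", "M"]:
            continue
        canonical = verify_deletion(gapped.aligned_sequence, genome, gapped)
        if canonical is None:
            continue
        del_start = canonical.start + canonical.cigar[0].length
        del_end = del_start + canonical.cigar[1].length
        calls.append(DeletionCall(gapped.chrom, del_start, del_end, sample, contig.id))
    return calls


# ---------------------------------------------------------------------------
# whole-sample driver
# ---------------------------------------------------------------------------


def run_sample(
    reads: list[Read],
    genome: GenomeSequence,
    sample: str,
    peaks: list[Peak] | None = None,
    control_reads: list[Read] | None = None,
    max_mismatches: int = 2,
    max_insertion: int = 20,
    min_flank: int = 5,
    min_overlap: int = 20,
    min_coverage: int = 5,
    rescue_ambiguous: bool = True,
    peak_p_threshold: float = 1e-9,
) -> tuple[list[InsertionCall], list[Contig], list[Peak], StageCounts]:
    """Full single-sample discovery: gapless pass, peak definition, rescue,
    enhancer-overlap filtering.  Returns (calls, contigs, peaks, counts)."""
    counts = StageCounts(total_reads=len(reads))
    aligned_positions: list[tuple[str, int]] = []
    unmapped: list[Read] = []
    for read in reads:
        result = map_ungapped(read, genome, max_mismatches=max_mismatches)
        if isinstance(result, Unmapped):
            if result.reason == "no_hit":
                counts.unmapped_no_hit += 1
                unmapped.append(read)
            else:
                counts.unmapped_ambiguous += 1
                if rescue_ambiguous:
                    unmapped.append(read)
        else:
            counts.mapped += 1
            aligned_positions.append((result.chrom, result.start))

    if peaks is None:
        control_positions = None
        if control_reads is not None:
            control_positions = []
            for read in control_reads:
                result = map_ungapped(read, genome, max_mismatches=max_mismatches)
                if isinstance(result, AlignmentHit):
                    control_positions.append((result.chrom, result.start))
        peaks = call_peaks(aligned_positions, genome, control_positions,
                           p_threshold=peak_p_threshold)

    calls, contigs = rescue_unmapped(
        unmapped, genome, sample=sample,
        min_overlap=min_overlap, min_coverage=min_coverage,
        max_insertion=max_insertion, min_flank=min_flank, counts=counts,
    )
    calls = filter_enhancer_overlap(calls, peaks)
    counts.in_enhancer = len(calls)
    logger.info("sample %s: %s", sample, counts.as_dict())
    return calls, contigs, peaks, counts
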