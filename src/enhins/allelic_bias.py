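"""Allele-specific ChIP-seq coverage at predicted insertions.

For each insertion two mini-genomes are built: a reference window of twice
the read length centred on the anchor, and the same window with the inserted
sequence spliced in.  Sample reads are aligned gaplessly to both; a read is
informative for an allele only when it aligns uniquely to exactly one
mini-genome (reads not spanning the insertion junction align to both and
carry no allelic information).  The bias ratio uses a single pseudocount so
zero-denominator loci stay finite; raw counts are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentHit, map_ungapped
from .core_io import GenomeSequence, Read, VariantKey

PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class MiniGenome:
    """A per-allele window; records its actual extent after boundary clipping."""

    sequence: str
    chrom: str
    window_start: int  # reference coordinate of the first window base
    window_end: int    # reference coordinate past the last reference base used

    def as_genome(self, name: str = "mini") -> GenomeSequence:
        return GenomeSequence({name: self.sequence})


@dataclass(frozen=True)
class AllelicCoverage:
    key: VariantKey
    ref_reads: int
    alt_reads: int

    def __post_init__(self):
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("negative read count")

    @property
    def bias_ratio(self) -> float:
        return (self.alt_reads + PSEUDOCOUNT) / (self.ref_reads + PSEUDOCOUNT)


def build_mini_genomes(
    genome: GenomeSequence, key: VariantKey, read_len: int
) -> tuple[MiniGenome, MiniGenome]:
    """Reference and insertion windows of 2x read length centred on the anchor.

    Windows are clipped at chromosome ends (the recorded extent shrinks); an
    anchor within ``read_len`` of both ends of a tiny chromosome leaves no
    usable junction flank and is an error.
    """
    chrom_seq = genome[key.chrom]
    if not 0 <= key.position < len(chrom_seq):
        raise ValueError(f"anchor {key.position} outside {key.chrom}")
    lo = key.position + 1 - read_len
    hi = key.position + 1 + read_len
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(chrom_seq))
    if clipped_lo > lo and clipped_hi < hi:
        raise ValueError(
            f"window around {key.serialize()} clipped at both chromosome ends; "
            f"chromosome too short for read length {read_len}"
        )
    window = chrom_seq[clipped_lo:clipped_hi]
    ref_mini = MiniGenome(window, key.chrom, clipped_lo, clipped_hi)
    splice_at = key.position + 1 - clipped_lo
    alt_mini = MiniGenome(
        window[:splice_at] + key.sequence + window[splice_at:],
        key.chrom, clipped_lo, clipped_hi,
    )
    return ref_mini, alt_mini


def count_allele_reads(
    reads: list[Read],
    ref_mini: MiniGenome,
    alt_mini: MiniGenome,
    key: VariantKey,
    max_mismatches: int = 2,
) -> AllelicCoverage:
    """Count reads uniquely assignable to exactly one allele mini-genome.

    Each read is aligned gaplessly (both strands, <= ``max_mismatches``,
    unique within each mini-genome); reads aligning to both minis or to
    neither are uninformative and ignored.
    """
    ref_genome = ref_mini.as_genome()
    alt_genome = alt_mini.as_genome()
    ref_count = alt_count = 0
    for read in reads:
        if len(read) > len(ref_mini.sequence):
            continue
        on_ref = isinstance(map_ungapped(read, ref_genome, max_mismatches), AlignmentHit)
        on_alt = isinstance(map_ungapped(read, alt_genome, max_mismatches), AlignmentHit)
        if on_ref and not on_alt:
            ref_count += 1
        elif on_alt and not on_ref:
            alt_count += 1
    return AllelicCoverage(key=key, ref_reads=ref_count, alt_reads=alt_count)


def compute_coverage(
    genome: GenomeSequence,
    keys: list[VariantKey],
    reads: list[Read],
    read_len: int,
    max_mismatches: int = 2,
) -> list[AllelicCoverage]:
    out = []
    for key in keys:
        ref_mini, alt_mini = build_mini_genomes(genome, key, read_len)
        out.append(count_allele_reads(reads, ref_mini, alt_mini, key, max_mismatches))
    return out


def filter_bias(coverages: list[AllelicCoverage], min_ratio: float = 2.0) -> list[AllelicCoverage]:
    """Keep entries whose insertion-over-reference bias is at least ``min_ratio``."""
    return [cov for cov in coverages if cov.bias_ratio >= min_ratio]
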