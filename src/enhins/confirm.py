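"""Amplicon-sequencing confirmation of predicted insertions.

Amplicon reads are assembled into contigs; each contig must align gaplessly
with ZERO mismatches to a per-allele custom genome (reference window of
``flank`` bases either side of the anchor, and the same window with the
insertion spliced in).  An allele counts as present only when a uniquely
aligning contig's interval contacts the prediction: it strictly contains the
anchor base (reference allele) or the full inserted span (insertion allele).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentHit, map_ungapped
from .assemble import assemble_contigs
from .core_io import GenomeSequence, Read, VariantKey


@dataclass(frozen=True)
class CustomGenome:
    sequence: str
    chrom: str
    window_start: int
    anchor_offset: int      # offset of the anchor base inside the window
    inserted_length: int    # 0 for the reference version

    def as_genome(self, name: str = "custom") -> GenomeSequence:
        return GenomeSequence({name: self.sequence})


@dataclass(frozen=True)
class AlleleCallResult:
    key: VariantKey
    ref_present: bool
    alt_present: bool

    @property
    def zygosity(self) -> str:
        if self.ref_present and self.alt_present:
            return "het"
        if self.alt_present:
            return "alt_only"
        if self.ref_present:
            return "ref_only"
        return "undetermined"


def build_confirmation_genomes(
    genome: GenomeSequence, key: VariantKey, flank: int = 250
) -> tuple[CustomGenome, CustomGenome]:
    """Per-allele custom genomes with ``flank`` bases up- and downstream.

    The reference version spans ``[anchor - flank, anchor + flank + 1)`` —
    2 x flank plus the anchor base itself under our left-anchor convention;
    windows are clipped (and the clipped extent recorded) near chromosome
    ends.
    """
    chrom_seq = genome[key.chrom]
    if not 0 <= key.position < len(chrom_seq):
        raise ValueError(f"anchor {key.position} outside {key.chrom}")
    lo = max(0, key.position - flank)
    hi = min(len(chrom_seq), key.position + flank + 1)
    window = chrom_seq[lo:hi]
    anchor_offset = key.position - lo
    ref_custom = CustomGenome(window, key.chrom, lo, anchor_offset, 0)
    alt_custom = CustomGenome(
        window[: anchor_offset + 1] + key.sequence + window[anchor_offset + 1:],
        key.chrom, lo, anchor_offset, len(key.sequence),
    )
    return ref_custom, alt_custom


def _contig_supports(custom: CustomGenome, genome: GenomeSequence,
                     contig_seq: str, allele: str) -> bool:
    """Does this contig align uniquely with zero mismatches and contact the site?"""
    if len(contig_seq) > len(custom.sequence):
        return False
    hit = map_ungapped(contig_seq, genome, max_mismatches=0, query_id="contig")
    if not isinstance(hit, AlignmentHit):
        return False
    start, end = hit.start, hit.end
    if allele == "ref":
        # strictly contains the anchor base: flanking sequence on both sides
        return start < custom.anchor_offset and end > custom.anchor_offset + 1
    ins_start = custom.anchor_offset + 1
    ins_end = ins_start + custom.inserted_length
    return start < ins_start and end > ins_end


def call_allele_presence(
    amplicon_reads: list[Read],
    ref_custom: CustomGenome,
    alt_custom: CustomGenome,
    key: VariantKey,
    min_overlap: int = 20,
    min_coverage: int = 5,
) -> AlleleCallResult:
    """Assemble amplicon reads and score per-allele contig support."""
    contigs = assemble_contigs(amplicon_reads, min_overlap=min_overlap, min_coverage=min_coverage)
    if not contigs:
        return AlleleCallResult(key, False, False)
    ref_genome = ref_custom.as_genome()
    alt_genome = alt_custom.as_genome()
    ref_present = any(_contig_supports(ref_custom, ref_genome, c.sequence, "ref") for c in contigs)
    alt_present = any(_contig_supports(alt_custom, alt_genome, c.sequence, "alt") for c in contigs)
    return AlleleCallResult(key, ref_present, alt_present)


def confirm_insertion(
    genome: GenomeSequence,
    key: VariantKey,
    amplicon_reads: list[Read],
    flank: int = 250,
    min_overlap: int = 20,
    min_coverage: int = 5,
) -> AlleleCallResult:
    ref_custom, alt_custom = build_confirmation_genomes(genome, key, flank)
    return call_allele_presence(amplicon_reads, ref_custom, alt_custom, key,
                                min_overlap=min_overlap, min_coverage=min_coverage)
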