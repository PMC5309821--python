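"""Synthetic data: toy genomes, planted insertions with zygosity, enhancer
peaks, ChIP-seq-like and amplicon-like reads, and loop/gene fixtures.

Everything is bit-reproducible from (seed, parameters); reads are error-free
by default (the pipeline's zero-mismatch verification makes error modelling
a separate concern) with an optional uniform substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    GenomeSequence,
    Loop,
    Peak,
    Read,
    VariantKey,
    left_normalize,
    reverse_complement,
)
from .neighbourhoods import GeneModel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    zygosity: str  # het | hom
    peak: Peak
    allele_fraction: float

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if not (self.peak.chrom, self.key.position) in self.peak:
            raise ValueError("truth key outside its peak")

    def serialize(self) -> str:
        return f"{self.key.serialize()}\t{self.zygosity}\t{self.peak.start}\t{self.peak.end}\t{self.allele_fraction}"


def write_truth(records: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tzygosity\tpeak_start\tpeak_end\tallele_fraction\n")
        for rec in records:
            fh.write(rec.serialize() + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            key_s, zyg, ps, pe, af = line.rstrip("\n").split("\t")
            key = VariantKey.parse(key_s)
            records.append(TruthRecord(key, zyg, Peak(key.chrom, int(ps), int(pe)), float(af)))
    return records


def make_genome(seed: int, n_chrom: int = 1, lengths: list[int] | int = 100_000,
                gc: float = 0.45) -> GenomeSequence:
    """Random genome with the requested GC content, deterministic per seed."""
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return GenomeSequence({
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=length, p=p))
        for i, length in enumerate(lengths)
    })


def make_peaks(genome: GenomeSequence, n_peaks: int, peak_len: int, seed: int,
               margin: int = 500) -> list[Peak]:
    """Non-overlapping equal-length peaks placed away from chromosome ends."""
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    chroms = list(genome)
    slots_per_chrom = max(1, n_peaks // len(chroms) + (n_peaks % len(chroms) > 0))
    for chrom in chroms:
        usable = genome.lengths[chrom] - 2 * margin - peak_len
        if usable <= 0:
            raise ValueError(f"{chrom} too short for peaks of {peak_len} bp")
        n_here = min(slots_per_chrom, n_peaks - len(peaks))
        spacing = usable // max(n_here, 1)
        if spacing < peak_len:
            raise ValueError("too many peaks for genome size")
        for i in range(n_here):
            jitter = int(rng.integers(0, max(1, spacing - peak_len)))
            start = margin + i * spacing + jitter
            peaks.append(Peak(chrom, start, start + peak_len))
        if len(peaks) >= n_peaks:
            break
    return sorted(peaks)


class Haplotype:
    """A genome with insertions spliced in, plus reference->haplotype lifting."""

    def __init__(self, genome: GenomeSequence, insertions: list[VariantKey]):
        self.insertions = sorted(insertions)
        seqs = {}
        self._shifts: dict[str, list[tuple[int, int]]] = {}  # (ref anchor, ins length)
        for chrom, seq in genome.sequences.items():
            keys = [k for k in self.insertions if k.chrom == chrom]
            parts, prev = [], 0
            for k in keys:
                parts.append(seq[prev:k.position + 1])
                parts.append(k.sequence)
                prev = k.position + 1
            parts.append(seq[prev:])
            seqs[chrom] = "".join(parts)
            self._shifts[chrom] = [(k.position, len(k.sequence)) for k in keys]
        self.genome = GenomeSequence(seqs)

    def lift(self, chrom: str, ref_pos: int) -> int:
        """Reference coordinate -> haplotype coordinate (left of any insertion at the point)."""
        shift = 0
        for anchor, length in self._shifts[chrom]:
            if anchor < ref_pos:
                shift += length
        return ref_pos + shift


def plant_insertions(
    genome: GenomeSequence,
    peaks: list[Peak],
    n: int,
    seed: int,
    size_range: tuple[int, int] = (1, 31),
    het_fraction: float = 0.5,
) -> tuple[Haplotype, Haplotype, list[TruthRecord]]:
    """Plant ``n`` insertions, one per chosen peak, with mixed zygosity.

    Returns two haplotype genomes (hap_a carries every insertion, hap_b only
    the homozygous ones) plus serialized truth.  Sizes are drawn skewed
    towards small values within ``size_range``; keys are left-normalized
    before recording, so truth keys match caller keys exactly.
    """
    if n > len(peaks):
        raise ValueError(f"cannot plant {n} insertions into {len(peaks)} peaks")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(peaks), size=n, replace=False))
    lo, hi = size_range
    truth: list[TruthRecord] = []
    keys_a: list[VariantKey] = []
    keys_b: list[VariantKey] = []
    for idx in chosen:
        peak = peaks[idx]
        # geometric-ish skew to small sizes, clamped into range
        size = lo + min(int(rng.geometric(0.25)) - 1, hi - lo)
        margin = 50
        anchor = int(rng.integers(peak.start + margin, peak.end - margin))
        inserted = "".join(rng.choice(_BASES, size=size))
        anchor, inserted = left_normalize(genome[peak.chrom], anchor, inserted)
        key = VariantKey(peak.chrom, anchor, inserted)
        if not (peak.chrom, anchor) in peak:
            continue  # normalization escaped the peak; rare, skip this site
        zygosity = "het" if rng.random() < het_fraction else "hom"
        keys_a.append(key)
        if zygosity == "hom":
            keys_b.append(key)
        truth.append(TruthRecord(key, zygosity, peak, 0.5 if zygosity == "het" else 1.0))
    hap_a = Haplotype(genome, keys_a)
    hap_b = Haplotype(genome, keys_b)
    return hap_a, hap_b, truth


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < error_rate
    for i in np.nonzero(hits)[0]:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)


def simulate_chip_reads(
    haplotypes: tuple[Haplotype, Haplotype],
    peaks: list[Peak],
    depth_in_peak: float,
    seed: int,
    background_rate: float = 0.0,
    read_len: int = 40,
    error_rate: float = 0.0,
) -> list[Read]:
    """Error-free reads drawn uniformly within peaks from both haplotypes
    (depth split evenly), plus optional genome-wide background."""
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    counter = 0
    for hap_idx, hap in enumerate(haplotypes):
        for peak in peaks:
            lifted_start = hap.lift(peak.chrom, peak.start)
            lifted_end = hap.lift(peak.chrom, peak.end)
            chrom_len = hap.genome.lengths[peak.chrom]
            span = lifted_end - lifted_start + read_len - 1
            n_reads = int(round((depth_in_peak / 2) * span / read_len))
            starts = rng.integers(
                max(0, lifted_start - read_len + 1),
                min(chrom_len - read_len, lifted_end - 1) + 1,
                size=n_reads,
            )
            for s in starts:
                seq = hap.genome[peak.chrom][s:s + read_len]
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                seq = _apply_errors(seq, rng, error_rate)
                reads.append(Read(f"read_{hap_idx}_{counter}", seq))
                counter += 1
        if background_rate > 0:
            for chrom, length in hap.genome.lengths.items():
                n_bg = int(round((background_rate / 2) * length / read_len))
                for s in rng.integers(0, length - read_len + 1, size=n_bg):
                    seq = hap.genome[chrom][s:s + read_len]
                    if rng.random() < 0.5:
                        seq = reverse_complement(seq)
                    seq = _apply_errors(seq, rng, error_rate)
                    reads.append(Read(f"bg_{hap_idx}_{counter}", seq))
                    counter += 1
    return reads


def simulate_amplicon_reads(
    custom_genomes: tuple[str, str],
    zygosity: str,
    depth: float,
    seed: int,
    read_len: int = 150,
    error_rate: float = 0.0,
) -> list[Read]:
    """Reads from per-allele custom genome sequences according to zygosity.

    het draws 50/50 from (ref, alt); hom (or 'alt_only') draws from alt only,
    'ref_only' from ref only.  Paired-end mates are emitted as independent
    single reads.
    """
    if depth < 10:
        raise ValueError("amplicon depth must be >= 10")
    ref_seq, alt_seq = custom_genomes
    if zygosity == "het":
        sources = [ref_seq, alt_seq]
    elif zygosity in ("hom", "alt_only"):
        sources = [alt_seq]
    elif zygosity == "ref_only":
        sources = [ref_seq]
    else:
        raise ValueError(f"bad zygosity {zygosity!r}")
    rng = np.random.default_rng(seed)
    reads = []
    counter = 0
    for src in sources:
        if len(src) < read_len:
            raise ValueError(f"custom genome shorter ({len(src)}) than read length {read_len}")
        n_reads = int(round((depth / len(sources)) * len(src) / read_len))
        for s in rng.integers(0, len(src) - read_len + 1, size=n_reads):
            seq = src[s:s + read_len]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            seq = _apply_errors(seq, rng, error_rate)
            reads.append(Read(f"amp_{counter}", seq))
            counter += 1
    return reads


def make_loop_gene_fixture(
    seed: int,
    genome_length: int = 1_000_000,
    n_loops: int = 30,
    nest_fraction: float = 0.3,
    oncogene_fraction: float = 0.3,
    chrom: str = "chr1",
) -> tuple[list[Loop], list[GeneModel]]:
    """Nested loop sets and TSS placements for neighbourhood tests.

    Every loop passes the confidence filter (FDR 0.05, CTCF at both anchors)
    and holds one active gene at its midpoint; a configurable fraction of
    those genes are oncogenes.  A fraction of loops get a nested inner loop
    sharing the oncogene status decision independently.
    """
    rng = np.random.default_rng(seed)
    anchor_w = 500
    loops: list[Loop] = []
    genes: list[GeneModel] = []
    spacing = genome_length // (n_loops + 1)
    for i in range(n_loops):
        start = i * spacing + int(rng.integers(0, spacing // 4))
        span = int(rng.integers(spacing // 2, spacing - 2 * anchor_w))
        outer = Loop(chrom, (start, start + anchor_w), (start + span - anchor_w, start + span),
                     fdr=0.05, ctcf1=True, ctcf2=True)
        loops.append(outer)
        mid = start + span // 2
        genes.append(GeneModel(
            name=f"gene_{i}", chrom=chrom, tss=mid, strand="+",
            active=True, oncogene=bool(rng.random() < oncogene_fraction),
        ))
        if rng.random() < nest_fraction and span > 8 * anchor_w:
            inner_start = start + span // 4
            inner_end = start + 3 * span // 4
            loops.append(Loop(chrom, (inner_start, inner_start + anchor_w),
                              (inner_end - anchor_w, inner_end),
                              fdr=0.05, ctcf1=True, ctcf2=True))
    return loops, genes
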