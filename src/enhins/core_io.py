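"""Canonical data model and readers/writers for the formats the pipeline touches.

Coordinate conventions used throughout the package:

* all intervals are 0-based, half-open ``[start, end)``;
* an insertion is anchored at the 0-based index of the reference base
  immediately **left** of the insertion point, so the inserted bases sit
  between ``anchor`` and ``anchor + 1``;
* insertion keys are left-normalized (shifted to the leftmost equivalent
  anchor in repetitive context) before any matching or grouping, so that
  identical events in repeats share one canonical ``chrom:pos:sequence`` key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class GenomeSequence:
    """An in-memory genome: unique chromosome names mapped to A/C/G/T/N strings.

    K-mer position indexes (used by the gapless mapper) are built lazily and
    cached per k.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}")
            clean[name] = seq
        self.sequences = clean
        self._kmer_indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.sequences == other.sequences

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][max(start, 0):end]

    def kmer_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k < 1:
            raise ValueError("k must be >= 1")
        index = self._kmer_indexes.get(k)
        if index is None:
            index = {}
            for name, seq in self.sequences.items():
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i:i + k], []).append((name, i))
            self._kmer_indexes[k] = index
        return index


@dataclass(frozen=True)
class Read:
    """A single-end sequencing read; qualities are parsed but never used."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 20:
            raise ValueError(f"read {self.id!r}: length {len(self.sequence)} < 20")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r} contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Peak:
    """A 0-based half-open genomic interval (an enhancer region)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    def __contains__(self, pos_pair: tuple[str, int]) -> bool:
        chrom, pos = pos_pair
        return chrom == self.chrom and self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of an insertion: chromosome, left anchor, inserted sequence.

    ``position`` is the 0-based index of the reference base immediately left
    of the insertion point.  Two keys are equal iff all three fields are
    equal, which is exactly string equality of :meth:`serialize`.
    """

    chrom: str
    position: int
    sequence: str

    def __post_init__(self):
        if not 1 <= len(self.sequence) <= 31:
            raise ValueError(f"inserted sequence length {len(self.sequence)} outside [1, 31]")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"inserted sequence contains non-ACGTN characters: {sorted(bad)}")

    def serialize(self) -> str:
        return f"{self.chrom}:{self.position}:{self.sequence}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        try:
            chrom, pos, seq = text.rsplit(":", 2)
            return cls(chrom, int(pos), seq)
        except ValueError as exc:
            raise FormatError(f"malformed variant key {text!r}") from exc


def left_normalize(ref: str, anchor: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion to its leftmost equivalent anchor.

    While the reference base at ``anchor`` equals the last inserted base the
    insertion can be rotated one base left without changing the alternate
    haplotype.  ``anchor`` may end at -1 (insertion before the first base).
    """
    while anchor >= 0 and ref[anchor] == inserted[-1]:
        inserted = inserted[-1] + inserted[:-1]
        anchor -= 1
    return anchor, inserted


@dataclass(frozen=True)
class Loop:
    """A cohesin loop (insulated neighbourhood): two anchors plus metadata.

    The neighbourhood span is the anchors' outer extent
    ``[anchor1_start, anchor2_end)``.
    """

    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]
    fdr: float
    ctcf1: bool
    ctcf2: bool

    def __post_init__(self):
        a1s, a1e = self.anchor1
        a2s, a2e = self.anchor2
        if a1s < 0 or a2s < 0:
            raise ValueError("negative anchor coordinate")
        if a1s >= a1e or a2s >= a2e:
            raise ValueError("empty/inverted anchor interval")
        if a1e > a2s:
            raise ValueError(f"anchors overlap or are out of order: {self.anchor1} vs {self.anchor2}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")

    @property
    def ctcf_both(self) -> bool:
        return self.ctcf1 and self.ctcf2

    @property
    def span(self) -> tuple[int, int]:
        return (self.anchor1[0], self.anchor2[1])

    @property
    def span_length(self) -> int:
        return self.anchor2[1] - self.anchor1[0]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.anchor1[0] <= pos < self.anchor2[1]


@dataclass
class CatalogueEntry:
    """One distinct insertion key and the evidence behind it."""

    key: VariantKey
    samples: frozenset[str]
    support: int
    sources: frozenset[str] = frozenset()
    germline_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        self.samples = frozenset(self.samples)
        self.sources = frozenset(self.sources)
        self.germline_flags = frozenset(self.germline_flags)
        if not self.samples:
            raise ValueError(f"{self.key.serialize()}: empty sample set")
        if self.support < 1:
            raise ValueError(f"{self.key.serialize()}: support {self.support} < 1")
        if not self.sources <= {"read", "contig"}:
            raise ValueError(f"unknown sources {sorted(self.sources)}")
        if not self.germline_flags <= {"dbsnp", "recurrent"}:
            raise ValueError(f"unknown germline flags {sorted(self.germline_flags)}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CatalogueEntry)
            and self.key == other.key
            and self.samples == other.samples
            and self.support == other.support
            and self.sources == other.sources
            and self.germline_flags == other.germline_flags
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (case-folded to upper)."""
    sequences: dict[str, str] = {}
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise FormatError(f"{path}: duplicate record name {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA ({exc})") from exc
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    try:
        return GenomeSequence(sequences)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file."""
    try:
        for record in SeqIO.parse(str(path), "fastq"):
            yield Read(record.id, str(record.seq).upper())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTQ ({exc})") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def _data_lines(fh: IO[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def read_bed(path: str | Path) -> list[Peak]:
    """Read 0-based half-open intervals from a BED file (first three columns)."""
    peaks = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                peak = Peak(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for peak in peaks:
            fh.write(f"{peak.chrom}\t{peak.start}\t{peak.end}\n")


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read loops from BEDPE with two extra columns: FDR and ``ctcf1,ctcf2`` flags."""
    loops = []
    with open(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected >=8 columns (BEDPE + fdr + ctcf flags)")
            c1, s1, e1, c2, s2, e2, fdr_s, ctcf_s = fields[:8]
            if c1 != c2:
                raise FormatError(f"{path}:{lineno}: trans-chromosomal loop not supported ({c1} vs {c2})")
            try:
                flags = ctcf_s.split(",")
                if len(flags) != 2 or set(flags) - {"0", "1"}:
                    raise ValueError(f"bad CTCF flag field {ctcf_s!r}, expected e.g. '1,1'")
                loop = Loop(
                    chrom=c1,
                    anchor1=(int(s1), int(e1)),
                    anchor2=(int(s2), int(e2)),
                    fdr=float(fdr_s),
                    ctcf1=flags[0] == "1",
                    ctcf2=flags[1] == "1",
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            loops.append(loop)
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.chrom}\t{lp.anchor1[0]}\t{lp.anchor1[1]}"
                f"\t{lp.chrom}\t{lp.anchor2[0]}\t{lp.anchor2[1]}"
                f"\t{lp.fdr:g}\t{int(lp.ctcf1)},{int(lp.ctcf2)}\n"
            )


# ---------------------------------------------------------------------------
# catalogue TSV
# ---------------------------------------------------------------------------

CATALOGUE_HEADER = ["chrom", "position", "sequence", "samples", "support", "sources", "germline_flags"]


def _join(values: frozenset[str]) -> str:
    return ",".join(sorted(values)) if values else "."


def _split(text: str) -> frozenset[str]:
    return frozenset() if text == "." else frozenset(text.split(","))


def write_catalogue(entries: Iterable[CatalogueEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOGUE_HEADER) + "\n")
        for e in sorted(entries, key=lambda e: e.key):
            fh.write(
                f"{e.key.chrom}\t{e.key.position}\t{e.key.sequence}"
                f"\t{_join(e.samples)}\t{e.support}\t{_join(e.sources)}\t{_join(e.germline_flags)}\n"
            )


def read_catalogue(path: str | Path) -> list[CatalogueEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CATALOGUE_HEADER:
            raise FormatError(f"{path}: unexpected catalogue header {header}")
        for lineno, fields in _data_lines(fh):
            if len(fields) != len(CATALOGUE_HEADER):
                raise FormatError(f"{path}:{lineno + 1}: expected {len(CATALOGUE_HEADER)} columns")
            chrom, pos, seq, samples, support, sources, flags = fields
            try:
                entries.append(
                    CatalogueEntry(
                        key=VariantKey(chrom, int(pos), seq),
                        samples=_split(samples),
                        support=int(support),
                        sources=_split(sources),
                        germline_flags=_split(flags),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno + 1}: {exc}") from exc
    return entries


# ---------------------------------------------------------------------------
# key files and VCF interoperability
# ---------------------------------------------------------------------------


def read_key_file(path: str | Path) -> set[VariantKey]:
    """Read serialized ``chrom:pos:sequence`` keys, one per line."""
    keys = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                keys.add(VariantKey.parse(line))
    return keys


def write_key_file(keys: Iterable[VariantKey], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(keys):
            fh.write(key.serialize() + "\n")


def write_vcf(entries: Iterable[CatalogueEntry], genome: GenomeSequence, path: str | Path) -> None:
    """Export catalogue entries as minimal VCF 4.2 insertion records.

    REF is the (left-normalized) anchor base, ALT the anchor base followed by
    the inserted sequence; POS is 1-based.  Keys whose anchor lies before the
    first reference base cannot be represented and are skipped.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads and contigs">\n')
        for name, length in genome.lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in sorted(entries, key=lambda e: e.key):
            key = e.key
            if key.position < 0 or key.chrom not in genome:
                continue
            ref_base = genome[key.chrom][key.position]
            fh.write(
                f"{key.chrom}\t{key.position + 1}\t.\t{ref_base}\t{ref_base}{key.sequence}"
                f"\t.\tPASS\tSUPPORT={e.support}\n"
            )


def read_vcf_insertion_keys(path: str | Path, genome: GenomeSequence | None = None) -> set[VariantKey]:
    """Extract insertion keys from a VCF (e.g. a dbSNP export).

    Only records where ALT extends REF on the right by 1-31 inserted bases are
    kept.  If ``genome`` is given, keys are left-normalized with the same rule
    the caller uses, so membership tests are meaningful.
    """
    import pysam

    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if not alt.startswith(ref) or not 1 <= len(alt) - len(ref) <= 31:
                    continue
                inserted = alt[len(ref):]
                if set(inserted) - ALPHABET:
                    continue
                anchor = rec.pos - 1 + len(ref) - 1  # base left of the insertion point
                chrom = rec.chrom
                if genome is not None and chrom in genome:
                    anchor, inserted = left_normalize(genome[chrom], anchor, inserted)
                keys.add(VariantKey(chrom, anchor, inserted))
    return keys
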