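"""Deprioritization of likely-germline insertions.

An entry is flagged germline when its exact key (position AND sequence) is
present in a dbSNP key set, or when it was identified in more than
``max_samples`` distinct samples — either condition alone suffices, and the
flags are reported rather than turned into a somatic verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import CatalogueEntry, Peak, VariantKey


@dataclass(frozen=True)
class GermlineAnnotation:
    key: VariantKey
    in_dbsnp: bool
    recurrent: bool

    @property
    def germline(self) -> bool:
        return self.in_dbsnp or self.recurrent


@dataclass(frozen=True)
class GermlineSummary:
    """Accounting over one annotated catalogue; union obeys inclusion-exclusion."""

    total_unique: int
    dbsnp_flagged: int
    recurrent_flagged: int
    both_flagged: int
    union_flagged: int
    remaining: int

    def __post_init__(self):
        assert self.union_flagged == self.dbsnp_flagged + self.recurrent_flagged - self.both_flagged
        assert self.remaining == self.total_unique - self.union_flagged

    def combined_with_prior(self, prior_count: int) -> int:
        """Total catalogue size after adding previously reported insertions."""
        return prior_count + self.remaining


def annotate_dbsnp(catalogue: list[CatalogueEntry], dbsnp_keys: set[VariantKey]) -> dict[VariantKey, bool]:
    """Exact key membership: same chromosome, position and sequence."""
    return {entry.key: entry.key in dbsnp_keys for entry in catalogue}


def flag_recurrent(catalogue: list[CatalogueEntry], max_samples: int = 2) -> dict[VariantKey, bool]:
    """Recurrent = identified in more than ``max_samples`` distinct samples."""
    return {entry.key: len(entry.samples) > max_samples for entry in catalogue}


def annotate(
    catalogue: list[CatalogueEntry],
    dbsnp_keys: set[VariantKey],
    max_samples: int = 2,
) -> list[GermlineAnnotation]:
    dbsnp = annotate_dbsnp(catalogue, dbsnp_keys)
    recurrent = flag_recurrent(catalogue, max_samples)
    return [
        GermlineAnnotation(entry.key, dbsnp[entry.key], recurrent[entry.key])
        for entry in catalogue
    ]


def apply_annotations(
    catalogue: list[CatalogueEntry], annotations: list[GermlineAnnotation]
) -> list[CatalogueEntry]:
    """Return entries with their germline_flags fields populated."""
    by_key = {a.key: a for a in annotations}
    out = []
    for entry in catalogue:
        ann = by_key.get(entry.key)
        flags = set()
        if ann is not None:
            if ann.in_dbsnp:
                flags.add("dbsnp")
            if ann.recurrent:
                flags.add("recurrent")
        out.append(
            CatalogueEntry(
                key=entry.key, samples=entry.samples, support=entry.support,
                sources=entry.sources, germline_flags=frozenset(flags),
            )
        )
    return out


def partition_somatic(
    catalogue: list[CatalogueEntry], annotations: list[GermlineAnnotation]
) -> tuple[list[CatalogueEntry], GermlineSummary]:
    """Split off non-germline entries and report the germline accounting."""
    by_key = {a.key: a for a in annotations}
    missing = [e.key for e in catalogue if e.key not in by_key]
    if missing:
        raise ValueError(f"annotations missing for {len(missing)} entries, e.g. {missing[0].serialize()}")
    n_dbsnp = n_recurrent = n_both = 0
    non_germline = []
    for entry in catalogue:
        ann = by_key[entry.key]
        if ann.in_dbsnp:
            n_dbsnp += 1
        if ann.recurrent:
            n_recurrent += 1
        if ann.in_dbsnp and ann.recurrent:
            n_both += 1
        if not ann.germline:
            non_germline.append(entry)
    union = n_dbsnp + n_recurrent - n_both
    summary = GermlineSummary(
        total_unique=len(catalogue),
        dbsnp_flagged=n_dbsnp,
        recurrent_flagged=n_recurrent,
        both_flagged=n_both,
        union_flagged=union,
        remaining=len(catalogue) - union,
    )
    return non_germline, summary


def intersect_external_catalogue(
    catalogue: list[CatalogueEntry],
    external_keys: set[VariantKey],
    enhancer_union: list[Peak],
) -> list[CatalogueEntry]:
    """Strict intersection with an external key catalogue.

    External keys are first restricted to those lying inside the collapsed
    enhancer union; matching is then exact key equality.
    """
    inside = {
        key for key in external_keys
        if any(p.chrom == key.chrom and p.start <= key.position < p.end for p in enhancer_union)
    }
    return [entry for entry in catalogue if entry.key in inside]


def collapse_peak_union(peak_sets: list[list[Peak]]) -> list[Peak]:
    """Merge overlapping/adjacent peaks across samples into a collapsed union."""
    all_peaks = sorted(p for peaks in peak_sets for p in peaks)
    union: list[Peak] = []
    for peak in all_peaks:
        if union and union[-1].chrom == peak.chrom and peak.start <= union[-1].end:
            union[-1] = Peak(peak.chrom, union[-1].start, max(union[-1].end, peak.end))
        else:
            union.append(peak)
    return union
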