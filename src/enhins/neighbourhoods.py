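"""Insulated-neighbourhood gene assignment and oncogene enrichment.

Insertions are assigned to the smallest CTCF/cohesin loop containing their
anchor; candidate target genes are the active genes whose TSS lies in that
loop's span.  Enrichment of insertions in oncogene-containing neighbourhoods
is tested by permutation: each permutation re-places every insertion
uniformly at random within the collapsed enhancer union and recomputes the
count of insertions whose neighbourhood contains an oncogene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Loop, Peak, VariantKey


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    tss: int
    strand: str
    active: bool
    oncogene: bool

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.tss < 0:
            raise ValueError("negative TSS")


@dataclass(frozen=True)
class GeneAssignment:
    key: VariantKey
    loop: Loop | None
    genes: tuple[str, ...]
    contains_oncogene: bool

    def __post_init__(self):
        if self.loop is None and self.genes:
            raise ValueError("genes assigned without a containing loop")


def filter_loops(loops: list[Loop], max_fdr: float = 0.2) -> list[Loop]:
    """High-confidence loops: FDR below threshold and CTCF at both anchors."""
    return [lp for lp in loops if lp.fdr < max_fdr and lp.ctcf_both]


def assign_smallest_loop(key: VariantKey, loops: list[Loop]) -> Loop | None:
    """The smallest (by outer span) filtered loop containing the anchor.

    Ties on identical minimal span length break deterministically: leftmost
    span start, then input order.
    """
    best = None
    best_rank = None
    for idx, loop in enumerate(loops):
        if not loop.contains(key.chrom, key.position):
            continue
        rank = (loop.span_length, loop.span[0], idx)
        if best_rank is None or rank < best_rank:
            best, best_rank = loop, rank
    return best


def assign_genes(key: VariantKey, loop: Loop | None, genes: list[GeneModel]) -> GeneAssignment:
    """Active genes whose TSS falls within the loop span share the neighbourhood."""
    if loop is None:
        return GeneAssignment(key, None, (), False)
    span_start, span_end = loop.span
    in_loop = [
        g for g in genes
        if g.active and g.chrom == loop.chrom and span_start <= g.tss < span_end
    ]
    return GeneAssignment(
        key=key, loop=loop,
        genes=tuple(sorted(g.name for g in in_loop)),
        contains_oncogene=any(g.oncogene for g in in_loop),
    )


def assign(keys: list[VariantKey], loops: list[Loop], genes: list[GeneModel],
           max_fdr: float = 0.2) -> list[GeneAssignment]:
    kept = filter_loops(loops, max_fdr)
    return [assign_genes(k, assign_smallest_loop(k, kept), genes) for k in keys]


def mark_active_genes(genes: list[GeneModel], peaks: list[Peak], window: int = 1000) -> list[GeneModel]:
    """Helper activity criterion: a gene is active iff a peak overlaps +/- window around its TSS."""
    out = []
    for g in genes:
        active = any(
            p.chrom == g.chrom and p.start < g.tss + window and p.end > g.tss - window
            for p in peaks
        )
        out.append(GeneModel(g.name, g.chrom, g.tss, g.strand, active, g.oncogene))
    return out


class _OncogeneLookup:
    """Precomputed position -> 'smallest containing loop has an oncogene' map.

    The genome is decomposed per chromosome into elementary segments between
    loop-span breakpoints; within a segment the containing-loop set, hence
    the flag, is constant.  Permuted positions then resolve via binary search.
    """

    def __init__(self, loops: list[Loop], genes: list[GeneModel]):
        self.breaks: dict[str, np.ndarray] = {}
        self.flags: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[Loop]] = {}
        for lp in loops:
            by_chrom.setdefault(lp.chrom, []).append(lp)
        for chrom, chrom_loops in by_chrom.items():
            pts = sorted({b for lp in chrom_loops for b in lp.span})
            breaks = np.array(pts, dtype=np.int64)
            flags = np.zeros(len(pts) + 1, dtype=bool)
            for seg in range(len(pts) - 1):
                pos = pts[seg]  # segment [pts[seg], pts[seg+1]) — any point works
                loop = assign_smallest_loop(VariantKey(chrom, pos, "A"), chrom_loops)
                flags[seg + 1] = assign_genes(VariantKey(chrom, pos, "A"), loop, genes).contains_oncogene
            self.breaks[chrom] = breaks
            self.flags[chrom] = flags

    def flag(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self.breaks:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self.breaks[chrom], positions, side="right")
        return self.flags[chrom][idx]


def oncogene_enrichment_test(
    keys: list[VariantKey],
    loops: list[Loop],
    genes: list[GeneModel],
    enhancer_union: list[Peak],
    n_perm: int = 10000,
    seed: int | None = None,
    max_fdr: float = 0.2,
) -> tuple[float, int, np.ndarray]:
    """Permutation test for insertions landing in oncogene neighbourhoods.

    Observed statistic: number of keys whose smallest containing loop holds
    an active oncogene.  Null: every key re-placed uniformly within the
    enhancer union.  Returns (p_value, observed, null_statistics) with
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if not enhancer_union:
        raise ValueError("enhancer union is empty; no permutation domain")
    kept = filter_loops(loops, max_fdr)
    lookup = _OncogeneLookup(kept, genes)

    observed = sum(
        lookup.flag(k.chrom, np.array([k.position]))[0] for k in keys
    )

    # flatten the union into a sampling domain of total length sum(|peak|)
    chroms = [p.chrom for p in enhancer_union]
    starts = np.array([p.start for p in enhancer_union], dtype=np.int64)
    lengths = np.array([len(p) for p in enhancer_union], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total, size=(n_perm, len(keys)))
    peak_idx = np.searchsorted(cum, draws, side="right") - 1
    positions = starts[peak_idx] + (draws - cum[peak_idx])

    null = np.zeros(n_perm, dtype=np.int64)
    chrom_arr = np.array(chroms)
    for chrom in set(chroms):
        mask = chrom_arr[peak_idx] == chrom
        flat_flags = np.zeros(draws.shape, dtype=bool)
        flat_flags[mask] = lookup.flag(chrom, positions[mask])
        null += flat_flags.sum(axis=1)
    p_value = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return p_value, int(observed), null
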