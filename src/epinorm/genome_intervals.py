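"""Interval arithmetic over peaks and gene models.

Peak pairing between two samples, read counting in regions, genomic
compartment classification (distal/proximal promoter, exon, intron,
intergenic), nearest-TSS gene assignment, multi-set Venn overlap and
target-gene grouping by binding location.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_io import GeneAnnotation, GeneModel, Peak, PeakSet

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

COMPARTMENTS = ("proximal_promoter", "distal_promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class CompartmentConfig:
    """TSS-relative windows, in transcription direction (negative = upstream).

    Defaults follow the common definition of distal promoters as −10 kb to
    −4 kb of the TSS and proximal promoters as −4 kb to +2 kb.
    """

    distal_promoter_window: tuple[int, int] = (-10000, -4000)
    proximal_promoter_window: tuple[int, int] = (-4000, 2000)

    def __post_init__(self) -> None:
        for lo, hi in (self.distal_promoter_window, self.proximal_promoter_window):
            if lo >= hi:
                raise ValueError("compartment windows must be non-empty")


@dataclass
class PeakPairing:
    """One-to-one matching of peaks between two samples."""

    common_pairs: list[tuple[Peak, Peak]]
    unique_a: list[Peak]
    unique_b: list[Peak]


@dataclass
class TargetGroup:
    label: str  # distal_and_promoter | distal_only | promoter_only
    genes: set[str] = field(default_factory=set)


def _overlap(a: Peak, b: Peak) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def pair_peaks(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> PeakPairing:
    """Match each peak of ``a`` to the ``b`` peak of maximal overlap.

    A pair is common iff the interval overlap is at least ``min_overlap_bp``.
    Ties go to the leftmost candidate; a matched ``b`` peak is removed from
    further matching (one-to-one).  Every peak of each set appears exactly
    once across pairs and uniques.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    pairs: list[tuple[Peak, Peak]] = []
    unique_a: list[Peak] = []
    matched_b: set[int] = set()
    b_by_chrom = b.by_chrom()
    for pa in a:
        candidates = b_by_chrom.get(pa.chrom, [])
        best: Peak | None = None
        best_ov = 0
        for pb in candidates:
            if pb.start >= pa.end:
                break
            if id(pb) in matched_b:
                continue
            ov = _overlap(pa, pb)
            if ov >= min_overlap_bp and ov > best_ov:
                best, best_ov = pb, ov
        if best is None:
            unique_a.append(pa)
        else:
            matched_b.add(id(best))
            pairs.append((pa, best))
    unique_b = [pb for pb in b if id(pb) not in matched_b]
    return PeakPairing(pairs, unique_a, unique_b)


def count_reads_in_regions(
    reads: pd.DataFrame, regions: PeakSet, shift_bp: int = 0
) -> np.ndarray:
    """Count strand-shifted read midpoints falling in each region.

    ``reads`` is a BED-like frame with columns chrom, start, end, strand.
    A read is counted in a region iff its midpoint, shifted ``+shift_bp`` on
    the + strand and ``−shift_bp`` on the − strand, lies in [start, end).
    """
    if shift_bp < 0:
        raise ValueError("shift_bp must be >= 0")
    counts = np.zeros(len(regions), dtype=np.int64)
    if len(reads) == 0:
        return counts
    mids = (reads["start"].to_numpy() + reads["end"].to_numpy()) // 2
    if shift_bp:
        sign = np.where(reads["strand"].to_numpy() == "-", -1, 1)
        mids = mids + sign * shift_bp
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp_idx in reads.groupby("chrom").indices.items():
        by_chrom[chrom] = np.sort(mids[grp_idx])
    for i, region in enumerate(regions):
        m = by_chrom.get(region.chrom)
        if m is None:
            continue
        counts[i] = np.searchsorted(m, region.end, "left") - np.searchsorted(
            m, region.start, "left"
        )
    return counts


def _tss_offset(anchor: int, gene: GeneModel) -> int:
    """Signed distance of anchor from TSS in transcription direction."""
    if gene.strand == "+":
        return anchor - gene.tss
    return gene.tss - anchor


def classify_compartment(
    peak: Peak, annotation: GeneAnnotation, config: CompartmentConfig | None = None
) -> str:
    """Assign one compartment label to a peak's anchor position.

    Precedence when the anchor hits several annotations:
    proximal_promoter > distal_promoter > exon > intron > intergenic.
    Promoter windows are strand-oriented.
    """
    config = config or CompartmentConfig()
    anchor = peak.anchor
    hit = {label: False for label in COMPARTMENTS}
    for gene in annotation.by_chrom().get(peak.chrom, []):
        d = _tss_offset(anchor, gene)
        lo, hi = config.proximal_promoter_window
        if lo <= d < hi:
            hit["proximal_promoter"] = True
        lo, hi = config.distal_promoter_window
        if lo <= d < hi:
            hit["distal_promoter"] = True
        if gene.tx_start <= anchor < gene.tx_end:
            in_exon = any(
                s <= anchor < e for s, e in zip(gene.exon_starts, gene.exon_ends)
            )
            hit["exon" if in_exon else "intron"] = True
    for label in COMPARTMENTS[:-1]:
        if hit[label]:
            return label
    return "intergenic"


def compartment_distribution(
    peaks: PeakSet, annotation: GeneAnnotation, config: CompartmentConfig | None = None
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-compartment counts and fractions over a peak set."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    counts = {label: 0 for label in COMPARTMENTS}
    for p in peaks:
        counts[classify_compartment(p, annotation, config)] += 1
    n = len(peaks)
    fractions = {label: c / n for label, c in counts.items()}
    return fractions, counts


class _TssIndex:
    """Sorted-TSS index per chromosome for nearest-gene queries."""

    def __init__(self, annotation: GeneAnnotation) -> None:
        self.by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom, genes in annotation.by_chrom().items():
            # ties at one TSS resolved by lexicographically smaller symbol
            ordered = sorted(genes, key=lambda g: (g.tss, g.name.upper()))
            self.by_chrom[chrom] = ([g.tss for g in ordered], ordered)

    def nearest(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        tss_list, genes = entry
        i = bisect_left(tss_list, pos)
        best: GeneModel | None = None
        best_key: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(genes):
                g = genes[j]
                key = (abs(g.tss - pos), g.name.upper())
                if best_key is None or key < best_key:
                    best, best_key = g, key
        return best


def nearest_gene(
    peak: Peak, annotation: GeneAnnotation, _index: _TssIndex | None = None
) -> str:
    """Symbol of the gene whose TSS is closest to the peak anchor.

    Ties break to the lexicographically smaller symbol; a chromosome without
    genes yields the sentinel ``"unassigned"``.
    """
    index = _index or _TssIndex(annotation)
    g = index.nearest(peak.chrom, peak.anchor)
    if g is None:
        logger.info("no gene on %s; peak at %d unassigned", peak.chrom, peak.anchor)
        return UNASSIGNED
    return g.name.upper()


def map_peaks_to_targets(peaks: PeakSet, annotation: GeneAnnotation) -> set[str]:
    """Union of nearest genes over all peaks, excluding unassigned."""
    index = _TssIndex(annotation)
    out = {nearest_gene(p, annotation, index) for p in peaks}
    out.discard(UNASSIGNED)
    return out


def venn_overlap(
    sets: list[PeakSet], min_overlap_bp: int = 1
) -> dict[str, dict[frozenset[int], int]]:
    """Per-set partition of peaks by which other sets they overlap.

    For each peak of each set, membership is the frozenset of other set
    indices it overlaps by at least ``min_overlap_bp``.  Counts within a set
    sum to that set's size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_overlap requires 2 or 3 peak sets")
    result: dict[str, dict[frozenset[int], int]] = {}
    chrom_maps = [ps.by_chrom() for ps in sets]
    for i, ps in enumerate(sets):
        partition: dict[frozenset[int], int] = {}
        for p in ps:
            members = set()
            for j, other_map in enumerate(chrom_maps):
                if j == i:
                    continue
                for q in other_map.get(p.chrom, []):
                    if q.start >= p.end:
                        break
                    if _overlap(p, q) >= min_overlap_bp:
                        members.add(j)
                        break
            partition[frozenset(members)] = partition.get(frozenset(members), 0) + 1
        result[ps.sample_label] = partition
    return result


def group_targets_by_location(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    config: CompartmentConfig | None = None,
) -> dict[str, TargetGroup]:
    """Partition target genes by where their peaks bind.

    A peak is a "promoter" peak of its nearest gene when its anchor lies in
    that gene's proximal promoter window, otherwise "distal".  Genes with
    both kinds go to ``distal_and_promoter``; the three groups are disjoint
    and cover all target genes.
    """
    config = config or CompartmentConfig()
    index = _TssIndex(annotation)
    gene_lookup = {g.name.upper(): g for g in annotation}
    has_promoter: dict[str, bool] = {}
    has_distal: dict[str, bool] = {}
    for p in peaks:
        sym = nearest_gene(p, annotation, index)
        if sym == UNASSIGNED:
            continue
        gene = gene_lookup[sym]
        d = _tss_offset(p.anchor, gene)
        lo, hi = config.proximal_promoter_window
        if lo <= d < hi:
            has_promoter[sym] = True
            has_distal.setdefault(sym, False)
        else:
            has_distal[sym] = True
            has_promoter.setdefault(sym, False)
    groups = {
        label: TargetGroup(label)
        for label in ("distal_and_promoter", "distal_only", "promoter_only")
    }
    for sym in set(has_promoter) | set(has_distal):
        if has_promoter.get(sym) and has_distal.get(sym):
            groups["distal_and_promoter"].genes.add(sym)
        elif has_distal.get(sym):
            groups["distal_only"].genes.add(sym)
        else:
            groups["promoter_only"].genes.add(sym)
    return groups


def annotate_peaks(
    peaks: PeakSet, annotation: GeneAnnotation, config: CompartmentConfig | None = None
) -> pd.DataFrame:
    """Annotated-peak table: compartment, nearest gene, TSS distance."""
    config = config or CompartmentConfig()
    index = _TssIndex(annotation)
    gene_lookup = {g.name.upper(): g for g in annotation}
    rows = []
    for p in peaks:
        sym = nearest_gene(p, annotation, index)
        dist = (
            abs(p.anchor - gene_lookup[sym].tss) if sym != UNASSIGNED else np.nan
        )
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "anchor": p.anchor,
                "compartment": classify_compartment(p, annotation, config),
                "nearest_gene": sym,
                "distance_to_tss": dist,
            }
        )
    return pd.DataFrame(rows)
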