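"""Synthetic experiment generator with known ground truth.

Emulates the structure the comparison pipeline assumes: two ChIP samples
(knockout and wild type) sharing a catalog of common peaks whose raw M
values follow a latent linear scaling law M = c0 + c1·A plus additive log2
noise, a differential subset whose knockout density is shifted by ±delta_m,
a toy single-chromosome gene annotation, a gene signature enriched for the
knockout-specific target genes, and replicate expression matrices with
upregulation at those targets.

Everything is deterministic under ``SimulationParams.seed``; per-stage
generators are spawned from one seed sequence so stages can be regenerated
independently.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneModel,
    GeneSet,
    Peak,
    PeakSet,
)

PEAK_NULL = "null_common"
PEAK_KO = "true_ko_specific"
PEAK_WT = "true_wt_specific"

GENE_KO = "ko_target"
GENE_WT = "wt_target"
GENE_BG = "background"

_GENE_MARGIN = 10_000  # upstream room inside each gene slot
_MAX_GENE_SPAN = 26_000  # margin + max length + max jitter
_MIN_SPACING = 30_000


@dataclass
class SimulationParams:
    """All knobs of the synthetic experiment.

    The scaling law is M = c0 + c1·A with Normal(0, noise_sd) log2 noise;
    differential peaks shift the knockout log2 density by ±delta_m.
    ``rho`` is the odds multiplier for drawing signature genes from the
    knockout-specific target genes; ``beta`` the log2 upregulation of those
    genes in the knockout expression replicates.
    """

    seed: int = 20130618
    n_genes: int = 1000
    chrom_length: int = 50_000_000
    chrom: str = "chr1"
    n_common: int = 2000
    n_diff_ko: int = 200
    n_diff_wt: int = 200
    c0: float = 0.4
    c1: float = 0.1
    noise_sd: float = 0.3
    delta_m: float = 2.5
    signature_size: int = 150
    rho: float = 8.0
    beta: float = 1.0
    n_reps: int = 4
    expr_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_common", "n_diff_ko", "n_diff_wt",
                     "signature_size", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.expr_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if self.delta_m == 0:
            raise ValueError("delta_m must be nonzero")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.n_genes * _MIN_SPACING > self.chrom_length:
            raise ValueError(
                f"cannot place {self.n_genes} genes on {self.chrom_length} bp "
                f"(need {_MIN_SPACING} bp per gene)"
            )
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds number of genes")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent per-stage generators derived from the single seed."""
        names = ("annotation", "peaks", "reads", "signature", "expression")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class Truth:
    """Ground-truth labels emitted alongside the generated data."""

    peak_labels: dict[tuple[str, int, int], str]
    gene_labels: dict[str, str]
    signature_members: set[str] = field(default_factory=set)

    @property
    def ko_targets(self) -> set[str]:
        return {g for g, l in self.gene_labels.items() if l == GENE_KO}

    @property
    def wt_targets(self) -> set[str]:
        return {g for g, l in self.gene_labels.items() if l == GENE_WT}

    def to_frame(self) -> pd.DataFrame:
        peak_rows = [
            {"kind": "peak", "id": f"{c}:{s}-{e}", "label": lab}
            for (c, s, e), lab in sorted(self.peak_labels.items())
        ]
        gene_rows = [
            {"kind": "gene", "id": g, "label": lab}
            for g, lab in sorted(self.gene_labels.items())
        ]
        sig_rows = [
            {"kind": "signature_member", "id": g, "label": "signature_member"}
            for g in sorted(self.signature_members)
        ]
        return pd.DataFrame(peak_rows + gene_rows + sig_rows)


def generate_annotation(params: SimulationParams,
                        rng: np.random.Generator | None = None) -> GeneAnnotation:
    """Uniformly spaced non-overlapping genes with random strand and exons."""
    rng = rng if rng is not None else params.rngs()["annotation"]
    spacing = params.chrom_length // params.n_genes
    width = max(4, len(str(params.n_genes)))
    genes: list[GeneModel] = []
    for i in range(params.n_genes):
        slot = i * spacing
        length = int(rng.integers(4000, 12001))
        jitter = int(rng.integers(0, 4001))
        tx_start = slot + _GENE_MARGIN + jitter
        tx_end = tx_start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        # breakpoints carve alternating exon/intron blocks inside the gene
        inner = np.sort(
            rng.choice(np.arange(tx_start + 1, tx_end - 1), size=2 * n_exons - 2,
                       replace=False)
        )
        bounds = [tx_start, *inner.tolist(), tx_end]
        exon_starts = tuple(bounds[0::2][:n_exons])
        exon_ends = tuple(bounds[1::2][:n_exons])
        genes.append(
            GeneModel(
                name=f"G{i + 1:0{width}d}",
                chrom=params.chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            )
        )
    return GeneAnnotation(genes)


def _place_nonoverlapping(rng: np.random.Generator, occupied: list[tuple[int, int]],
                          chrom_length: int, length: int) -> tuple[int, int]:
    """Rejection-sample an interval disjoint from all accepted intervals."""
    for _ in range(1000):
        start = int(rng.integers(1000, chrom_length - length - 1000))
        end = start + length
        i = bisect_left(occupied, (start, end))
        clash = (i > 0 and occupied[i - 1][1] > start) or (
            i < len(occupied) and occupied[i][0] < end
        )
        if not clash:
            insort(occupied, (start, end))
            return start, end
    raise RuntimeError("could not place a non-overlapping peak; genome too crowded")


def generate_peak_experiment(
    params: SimulationParams,
    annotation: GeneAnnotation,
    rng: np.random.Generator | None = None,
) -> tuple[PeakSet, PeakSet, dict, dict, Truth]:
    """Paired peak catalogs with known scaling law and differential subset.

    The ``n_common`` null peaks appear in both catalogs with identical
    coordinates; differential peaks are called only in the sample where they
    are enriched (knockout-specific peaks in the knockout catalog, wild-type-
    specific in the wild-type catalog), as a peak caller would see them.
    Counts for *both* samples are emitted for every region of the union
    catalog so unique peaks can still be normalized.  For each peak
    A ~ Uniform(4, 12) reads/kb (log2); log2 densities are
    ko = A + L/2 + eps/2 and wt = A − L/2 − eps/2 with L = c0 + c1·A and
    eps ~ Normal(0, noise_sd), so the raw M is exactly c0 + c1·A + eps and
    the average log2 density is exactly A.  Differential peaks add ±delta_m
    to the knockout side and sit in a promoter or distal window of their
    designated target gene; null peaks are placed uniformly, avoiding
    overlap.  Counts are densities times length/1000, rounded; peak widths
    are 1.5-2.5 kb, the typical scale of histone-mark enrichment regions.

    Returns (ko_peaks, wt_peaks, counts_ko, counts_wt, truth) with counts
    keyed by (chrom, start, end).
    """
    rng = rng if rng is not None else params.rngs()["peaks"]
    genes = list(annotation)
    idx = rng.choice(len(genes), size=params.n_diff_ko + params.n_diff_wt,
                     replace=False)
    ko_genes = [genes[i] for i in idx[: params.n_diff_ko]]
    wt_genes = [genes[i] for i in idx[params.n_diff_ko:]]

    occupied: list[tuple[int, int]] = []
    specs: list[tuple[int, int, str, str | None]] = []  # start, end, label, gene

    def _diff_peak(gene: GeneModel, label: str) -> None:
        length = int(rng.integers(1500, 2501))
        if rng.random() < 0.5:  # proximal promoter window of the target
            d = int(rng.integers(-3500, 1500))
        else:  # distal window
            d = int(rng.integers(-9500, -4500))
        anchor = gene.tss + d if gene.strand == "+" else gene.tss - d
        start = max(1000, anchor - length // 2)
        end = start + length
        i = bisect_left(occupied, (start, end))
        clash = (i > 0 and occupied[i - 1][1] > start) or (
            i < len(occupied) and occupied[i][0] < end
        )
        if clash:  # nudge into free space near the gene
            start, end = _place_nonoverlapping(rng, occupied, params.chrom_length, length)
        else:
            insort(occupied, (start, end))
        specs.append((start, end, label, gene.name.upper()))

    for g in ko_genes:
        _diff_peak(g, PEAK_KO)
    for g in wt_genes:
        _diff_peak(g, PEAK_WT)
    for _ in range(params.n_common):
        length = int(rng.integers(1500, 2501))
        start, end = _place_nonoverlapping(rng, occupied, params.chrom_length, length)
        specs.append((start, end, PEAK_NULL, None))

    n = len(specs)
    a = rng.uniform(4.0, 12.0, size=n)
    eps = rng.normal(0.0, params.noise_sd, size=n)
    scale = params.c0 + params.c1 * a
    log2_ko = a + scale / 2 + eps / 2
    log2_wt = a - scale / 2 - eps / 2
    labels = np.array([s[2] for s in specs])
    log2_ko = log2_ko + np.where(labels == PEAK_KO, params.delta_m, 0.0)
    log2_ko = log2_ko - np.where(labels == PEAK_WT, params.delta_m, 0.0)

    ko_peaks, wt_peaks = [], []
    counts_ko: dict[tuple[str, int, int], int] = {}
    counts_wt: dict[tuple[str, int, int], int] = {}
    peak_labels: dict[tuple[str, int, int], str] = {}
    for (start, end, label, _gene), lk, lw in zip(specs, log2_ko, log2_wt):
        length = end - start
        c_ko = int(round(2.0 ** lk * length / 1000.0))
        c_wt = int(round(2.0 ** lw * length / 1000.0))
        key = (params.chrom, start, end)
        counts_ko[key] = c_ko
        counts_wt[key] = c_wt
        peak_labels[key] = label
        # differential peaks are called only in their enriched sample
        if label != PEAK_WT:
            ko_peaks.append(Peak(params.chrom, start, end, read_count=c_ko))
        if label != PEAK_KO:
            wt_peaks.append(Peak(params.chrom, start, end, read_count=c_wt))

    gene_labels = {g.name.upper(): GENE_BG for g in genes}
    for g in ko_genes:
        gene_labels[g.name.upper()] = GENE_KO
    for g in wt_genes:
        gene_labels[g.name.upper()] = GENE_WT

    truth = Truth(peak_labels=peak_labels, gene_labels=gene_labels)
    return (
        PeakSet("ko", ko_peaks),
        PeakSet("wt", wt_peaks),
        counts_ko,
        counts_wt,
        truth,
    )


def generate_reads(
    counts: dict[tuple[str, int, int], int],
    regions: PeakSet,
    read_length: int = 36,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place exactly ``counts[region]`` reads with midpoints uniform in each
    region; counting midpoints back with zero shift recovers the counts."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    half = read_length // 2
    chroms, starts, strands = [], [], []
    for p in regions:
        c = counts.get(p.key, 0)
        if c <= 0:
            continue
        mids = rng.integers(p.start, p.end, size=c)
        chroms.append(np.full(c, p.chrom, dtype=object))
        starts.append(mids - half)
        strands.append(np.where(rng.random(c) < 0.5, "+", "-"))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    start_arr = np.concatenate(starts)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": start_arr,
            "end": start_arr + read_length,
            "strand": np.concatenate(strands),
        }
    )


def generate_signature(
    truth: Truth,
    annotation: GeneAnnotation,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    name: str = "SYN_SIGNATURE",
) -> GeneSet:
    """Signature of ``signature_size`` genes drawn with odds ``rho`` for
    knockout-specific target genes over background."""
    rng = rng if rng is not None else params.rngs()["signature"]
    symbols = sorted(g.name.upper() for g in annotation)
    ko = truth.ko_targets
    if not ko:
        raise ValueError("no ko_target genes in truth")
    weights = np.array([params.rho if s in ko else 1.0 for s in symbols])
    chosen = rng.choice(symbols, size=params.signature_size, replace=False,
                        p=weights / weights.sum())
    sig = GeneSet(name, set(chosen.tolist()))
    truth.signature_members |= sig.genes
    return sig


def generate_expression(
    truth: Truth,
    annotation: GeneAnnotation,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Replicate log2 expression: baseline Normal(7, 1) per gene, plus
    ``beta`` in knockout replicates at ko_target genes, plus residual
    Normal(0, expr_sd) per cell."""
    rng = rng if rng is not None else params.rngs()["expression"]
    symbols = sorted(g.name.upper() for g in annotation)
    n = len(symbols)
    baseline = rng.normal(7.0, 1.0, size=n)
    effect = np.array([params.beta if s in truth.ko_targets else 0.0 for s in symbols])
    wt_cols = {f"wt_{i + 1}": baseline + rng.normal(0, params.expr_sd, n)
               for i in range(params.n_reps)}
    ko_cols = {f"ko_{i + 1}": baseline + effect + rng.normal(0, params.expr_sd, n)
               for i in range(params.n_reps)}
    values = pd.DataFrame({**wt_cols, **ko_cols}, index=symbols)
    group = {c: "wt" for c in wt_cols} | {c: "ko" for c in ko_cols}
    return ExpressionMatrix(values, group)


def generate_all(params: SimulationParams):
    """Run every generator stage with per-stage seeds derived from one seed.

    Returns (annotation, ko_peaks, wt_peaks, counts_ko, counts_wt, reads_ko,
    reads_wt, signature, expression, truth).
    """
    rngs = params.rngs()
    annotation = generate_annotation(params, rngs["annotation"])
    ko, wt, counts_ko, counts_wt, truth = generate_peak_experiment(
        params, annotation, rngs["peaks"]
    )
    reads_ko = generate_reads(counts_ko, ko, rng=rngs["reads"])
    reads_wt = generate_reads(counts_wt, wt, rng=rngs["reads"])
    signature = generate_signature(truth, annotation, params, rngs["signature"])
    expression = generate_expression(truth, annotation, params, rngs["expression"])
    return annotation, ko, wt, counts_ko, counts_wt, reads_ko, reads_wt, signature, expression, truth
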