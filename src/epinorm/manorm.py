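"""Quantitative between-sample peak normalization on the M-A plane.

For every peak region the log2 ratio of knockout over wild-type read density
(M) is plotted against the average log2 density (A).  Assuming the true
intensities of most common peaks are the same in the two samples, a robust
linear regression of M on A over common peaks captures the global scaling
relationship between the libraries; the fitted line is then used as the
normalization reference and extrapolated to all peaks, including each
sample's unique peaks.  The normalized M value is the quantitative measure
of differential binding: peaks with normalized M > 1 (at least twofold
higher density in the knockout) are KO-specific, peaks with normalized
M < −1 are wild-type-specific, and the rest are common.

An optional exclusion mask removes common peaks overlapping a given peak set
from the fit (e.g. peaks of the factor under study, when normalizing histone
marks expected to change at its binding sites).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome_intervals import PeakPairing, pair_peaks
from .peak_io import Peak, PeakSet

logger = logging.getLogger(__name__)

MIN_FIT_SIZE = 10

LABEL_KO = "ko_specific"
LABEL_WT = "wt_specific"
LABEL_COMMON = "common"


@dataclass(frozen=True)
class MAPoint:
    m: float  # log2(density_ko / density_wt)
    a: float  # 0.5 * log2(density_ko * density_wt)


@dataclass(frozen=True)
class NormalizationModel:
    """Intercept and slope of the robust M-on-A fit over common peaks."""

    intercept: float
    slope: float
    n_fit: int
    excluded_n: int = 0
    method: str = "huber"

    def predict(self, a: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(a)


@dataclass
class ComparisonResult:
    """Full two-sample comparison over the union peak catalog."""

    pairing: PeakPairing
    table: pd.DataFrame  # per union-catalog region (see column docs below)
    model: NormalizationModel

    # table columns: chrom, start, end, count_ko, count_wt, density_ko,
    # density_wt, M_raw, A, M_normalized, label, origin, in_fit

    @property
    def label_counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def density(
    count: float,
    length_bp: int,
    pseudocount: float = 1.0,
    per_kb: bool = True,
    additive: bool = False,
) -> float:
    """Read density of a region, per kb by default.

    The pseudocount keeps unique-peak regions (zero reads in the other
    sample) at a finite log density.  By default it acts as a floor,
    ``max(count, pseudocount)``, which leaves non-degenerate counts -- and
    hence the M-A regression -- untouched; ``additive=True`` adds it to
    every count instead (slightly biasing M downward wherever counts are
    small in one sample).
    """
    c = count + pseudocount if additive else max(count, pseudocount)
    if c <= 0:
        raise ValueError("non-positive density; enable a pseudocount")
    return c / length_bp * 1000.0 if per_kb else c


def compute_ma(density_ko: float, density_wt: float) -> MAPoint:
    """M/A coordinates of one region from its two sample densities.

    Exactly invertible: densities are recoverable as ``2**(a ± m/2)``.
    """
    if density_ko <= 0 or density_wt <= 0:
        raise ValueError("densities must be positive (apply a pseudocount)")
    return MAPoint(
        m=math.log2(density_ko / density_wt),
        a=0.5 * math.log2(density_ko * density_wt),
    )


def fit_normalization(
    common_ma: Sequence[MAPoint],
    exclude: Sequence[bool] | None = None,
    method: str = "huber",
) -> NormalizationModel:
    """Robust linear regression of M on A over common peaks.

    Iteratively reweighted least squares with Huber weights (tuning constant
    1.345; ``method="bisquare"`` for Tukey's biweight), at most 50 iterations,
    convergence when the coefficient change drops below 1e-8.  Peaks flagged
    in ``exclude`` are removed before fitting.
    """
    mask = np.zeros(len(common_ma), dtype=bool) if exclude is None else np.asarray(exclude, bool)
    pts = [p for p, ex in zip(common_ma, mask) if not ex]
    excluded_n = len(common_ma) - len(pts)
    if len(pts) < MIN_FIT_SIZE:
        raise ValueError(
            f"insufficient common peaks for normalization fit: {len(pts)} < {MIN_FIT_SIZE}"
        )
    m = np.array([p.m for p in pts])
    a = np.array([p.a for p in pts])
    if method == "huber":
        norm = sm.robust.norms.HuberT(t=1.345)
    elif method == "bisquare":
        norm = sm.robust.norms.TukeyBiweight()
    else:
        raise ValueError(f"unknown robust method {method!r}")
    rlm = sm.RLM(m, sm.add_constant(a), M=norm)
    fit = rlm.fit(maxiter=50, tol=1e-8)
    logger.info(
        "normalization fit: intercept=%.4f slope=%.4f on %d peaks (%d excluded)",
        fit.params[0], fit.params[1], len(pts), excluded_n,
    )
    return NormalizationModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        n_fit=len(pts),
        excluded_n=excluded_n,
        method=method,
    )


def normalize(ma: MAPoint, model: NormalizationModel) -> float:
    """Normalized M: raw M minus the fitted reference line at this A."""
    return ma.m - (model.intercept + model.slope * ma.a)


def classify_peaks(m_normalized: Sequence[float], threshold: float = 1.0) -> list[str]:
    """Label peaks by normalized M: strictly above +threshold → KO-specific,
    strictly below −threshold → wild-type-specific, else common."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = []
    for m in m_normalized:
        if m > threshold:
            labels.append(LABEL_KO)
        elif m < -threshold:
            labels.append(LABEL_WT)
        else:
            labels.append(LABEL_COMMON)
    return labels


def _overlaps_any(peak: Peak, mask_by_chrom: dict[str, list[Peak]]) -> bool:
    for q in mask_by_chrom.get(peak.chrom, []):
        if q.start >= peak.end:
            break
        if min(peak.end, q.end) - max(peak.start, q.start) >= 1:
            return True
    return False


def run_comparison(
    ko: PeakSet,
    wt: PeakSet,
    counts_ko: Mapping[tuple[str, int, int], float],
    counts_wt: Mapping[tuple[str, int, int], float],
    mask: PeakSet | None = None,
    min_overlap_bp: int = 1,
    pseudocount: float = 1.0,
    per_kb: bool = True,
    additive_pseudocount: bool = False,
    method: str = "huber",
    threshold: float = 1.0,
) -> ComparisonResult:
    """End-to-end comparison: pair → M-A → robust fit → normalize → classify.

    ``counts_ko``/``counts_wt`` give, for every peak region of both catalogs
    (keyed by (chrom, start, end)), the read count of each sample measured
    over that region.  Common pairs are represented by the KO peak's region.
    Peaks overlapping ``mask`` are excluded from the fit but still normalized
    and classified.
    """
    pairing = pair_peaks(ko, wt, min_overlap_bp=min_overlap_bp)

    regions: list[Peak] = []
    origins: list[str] = []
    is_common: list[bool] = []
    for pa, _pb in pairing.common_pairs:
        regions.append(pa)
        origins.append("common")
        is_common.append(True)
    for p in pairing.unique_a:
        regions.append(p)
        origins.append("unique_ko")
        is_common.append(False)
    for p in pairing.unique_b:
        regions.append(p)
        origins.append("unique_wt")
        is_common.append(False)

    rows = []
    ma_points: list[MAPoint] = []
    n_zero = 0
    for p in regions:
        c_ko = counts_ko[p.key]
        c_wt = counts_wt[p.key]
        if c_ko == 0 or c_wt == 0:
            n_zero += 1
        d_ko = density(c_ko, p.length, pseudocount, per_kb, additive_pseudocount)
        d_wt = density(c_wt, p.length, pseudocount, per_kb, additive_pseudocount)
        ma = compute_ma(d_ko, d_wt)
        ma_points.append(ma)
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "count_ko": c_ko,
                "count_wt": c_wt,
                "density_ko": d_ko,
                "density_wt": d_wt,
                "M_raw": ma.m,
                "A": ma.a,
            }
        )
    if n_zero:
        logger.warning("%d regions had a zero count in one sample; pseudocount applied", n_zero)

    common_ma = [ma for ma, c in zip(ma_points, is_common) if c]
    common_regions = [p for p, c in zip(regions, is_common) if c]
    if mask is not None:
        mask_by_chrom = mask.by_chrom()
        exclude = [_overlaps_any(p, mask_by_chrom) for p in common_regions]
    else:
        exclude = None
    model = fit_normalization(common_ma, exclude=exclude, method=method)

    m_norm = [normalize(ma, model) for ma in ma_points]
    labels = classify_peaks(m_norm, threshold=threshold)

    ex_iter = iter(exclude if exclude is not None else [False] * len(common_ma))
    in_fit = [bool(c and not next(ex_iter)) if c else False for c in is_common]

    df = pd.DataFrame(rows)
    df["M_normalized"] = m_norm
    df["label"] = labels
    df["origin"] = origins
    df["in_fit"] = in_fit
    return ComparisonResult(pairing=pairing, table=df, model=model)
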