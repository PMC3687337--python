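"""Differential expression and its integration with peak targets.

Genes pass the differential filter when they change at least ``fold_cutoff``
(1.5-fold by default, on the geometric-mean scale: |mean log2 difference| >=
log2(fold_cutoff)) with a two-tailed t-test p <= ``p_cutoff``.  No multiple
testing correction is applied by the default filter; Benjamini-Hochberg
q-values can be reported alongside.  Welch's unequal-variance t is the
default; the pooled-variance form is available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peak_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    log2fc: float  # mean_ko - mean_wt in log2 units
    p: float  # two-tailed t-test
    passes: bool


def differential_genes(
    expr: ExpressionMatrix,
    fold_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    direction: str = "both",
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Two-tailed t-test per gene on log2 values with a fold-change filter.

    ``direction`` restricts which sign of change may pass: "up" (higher in
    ko), "down", or "both".
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    ko = expr.condition("ko")
    wt = expr.condition("wt")
    if ko.shape[1] < 2 or wt.shape[1] < 2:
        raise ValueError("each condition needs >=2 replicates")
    log2fc = (ko.mean(axis=1) - wt.mean(axis=1)).to_numpy()
    _, p = stats.ttest_ind(ko.to_numpy(), wt.to_numpy(), axis=1, equal_var=equal_var)
    fc_min = math.log2(fold_cutoff)
    results = []
    for gene, fc, pv in zip(expr.genes, log2fc, p):
        ok_dir = (
            (direction == "both")
            or (direction == "up" and fc > 0)
            or (direction == "down" and fc < 0)
        )
        passes = bool(abs(fc) >= fc_min and pv <= p_cutoff and ok_dir)
        results.append(DifferentialResult(gene, float(fc), float(pv), passes))
    return results


def differential_table(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "passes": [r.passes for r in results],
        }
    )


def fraction_bound(
    up_genes: set[str], target_genes: set[str]
) -> tuple[float, int, int]:
    """Fraction of differentially expressed genes whose loci are peak targets.

    Returns (fraction, n_overlap, n_up).
    """
    if not up_genes:
        raise ValueError("empty differential gene set")
    up = {g.upper() for g in up_genes}
    targets = {g.upper() for g in target_genes}
    k = len(up & targets)
    return k / len(up), k, len(up)


def ratio_by_group(
    expr_ko: ExpressionMatrix,
    expr_wt: ExpressionMatrix,
    groups: dict[str, set[str]],
) -> pd.DataFrame:
    """Five-number summaries of per-gene ko/wt log2 expression ratios by group.

    The per-gene ratio is the mean log2 value over ko samples minus the mean
    over wt samples; a group with no genes matched in both matrices is
    skipped with a warning.
    """
    mean_ko = expr_ko.values.mean(axis=1)
    mean_wt = expr_wt.values.mean(axis=1)
    shared = mean_ko.index.intersection(mean_wt.index)
    ratio = (mean_ko.loc[shared] - mean_wt.loc[shared]).astype(float)
    rows = []
    for name, genes in groups.items():
        members = ratio.loc[ratio.index.isin({g.upper() for g in genes})]
        if members.empty:
            logger.warning("group %r has no genes matched in both matrices; skipped", name)
            continue
        q1, med, q3 = np.percentile(members, [25, 50, 75])
        rows.append(
            {
                "group": name,
                "n": len(members),
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": members.min(),
                "max": members.max(),
            }
        )
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^−ΔΔCt from four qPCR cycle-threshold values.

    ΔΔCt = (Ct_target − Ct_reference)_treated − (Ct_target − Ct_reference)_control.
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
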