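"""Gene-signature statistics.

Two complementary views of signature association:

* :func:`overlap_enrichment` — the ratio of observed to randomly expected
  overlap between a target gene set and a signature within a gene universe,
  with a Fisher's exact p-value on the 2x2 membership table.
* :func:`gsea` — a running enrichment score over a ranked gene list (signal
  to noise between conditions), normalized against a gene-set permutation
  null (random same-size sets drawn from the ranked genes), with nominal
  permutation p-values and a ratio-of-tails FDR over the set collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peak_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float  # observed / expected overlap
    p: float  # Fisher's exact
    n_target: int
    n_signature: int
    n_overlap: int
    n_universe: int


@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    p_nominal: float
    fdr: float
    n_hits: int


def overlap_enrichment(
    target: GeneSet,
    signature: GeneSet,
    universe: set[str],
    alternative: str = "greater",
) -> EnrichmentResult:
    """Observed/expected overlap ratio with Fisher's exact test.

    Symbols outside the universe are dropped with a warning.  The expected
    overlap at random is |T|·|S|/|U|; the p-value is one-sided (enrichment)
    by default.
    """
    if not universe:
        raise ValueError("empty universe")
    universe = {g.upper() for g in universe}
    t = target.genes & universe
    s = signature.genes & universe
    dropped = (len(target.genes) - len(t)) + (len(signature.genes) - len(s))
    if dropped:
        logger.warning(
            "overlap_enrichment(%s vs %s): dropped %d symbols outside universe",
            target.name, signature.name, dropped,
        )
    n_u, n_t, n_s = len(universe), len(t), len(s)
    k = len(t & s)
    expected = n_t * n_s / n_u
    if expected == 0:
        raise ValueError("expected overlap is zero (empty target or signature)")
    table = [[k, n_t - k], [n_s - k, n_u - n_t - n_s + k]]
    _, p = stats.fisher_exact(table, alternative=alternative)
    return EnrichmentResult(
        name=signature.name,
        es=k / expected,
        p=float(p),
        n_target=n_t,
        n_signature=n_s,
        n_overlap=k,
        n_universe=n_u,
    )


def rank_genes(expr: ExpressionMatrix, sd_floor: float = 0.2) -> pd.Series:
    """Rank genes by signal-to-noise ratio between ko and wt conditions.

    score = (mean_ko − mean_wt) / (sd_ko + sd_wt), with each sd floored at
    max(sd_floor·|mean|, sd_floor).  Returns scores sorted descending, ties
    broken by symbol.
    """
    ko = expr.condition("ko")
    wt = expr.condition("wt")
    if ko.shape[1] < 2 or wt.shape[1] < 2:
        raise ValueError("each condition needs >=2 replicates for ranking")
    mean_ko, mean_wt = ko.mean(axis=1), wt.mean(axis=1)
    sd_ko = np.maximum(ko.std(axis=1, ddof=1), np.maximum(sd_floor * mean_ko.abs(), sd_floor))
    sd_wt = np.maximum(wt.std(axis=1, ddof=1), np.maximum(sd_floor * mean_wt.abs(), sd_floor))
    score = (mean_ko - mean_wt) / (sd_ko + sd_wt)
    order = pd.DataFrame({"score": score, "symbol": score.index})
    order = order.sort_values(["score", "symbol"], ascending=[False, True])
    return order["score"]


def running_es(
    ranked: pd.Series, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Running enrichment score over a ranked gene list.

    Walking the list top to bottom, hits increment the running sum in
    proportion to |score|^weight_p (normalized so hit increments sum to 1)
    and misses decrement by 1/(N − n_hits).  The enrichment score is the
    signed extremum of the running sum; the full profile is also returned.
    """
    symbols = ranked.index.to_numpy()
    is_hit = np.isin(symbols, list(gene_set.genes))
    n_hits = int(is_hit.sum())
    n = len(symbols)
    if n_hits == 0:
        raise ValueError(f"no member of {gene_set.name!r} present in ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy()) ** weight_p
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_hit) / (n - n_hits)
    profile = np.cumsum(steps)
    es = profile[np.argmax(np.abs(profile))]
    return float(es), profile


def _es_only(scores: np.ndarray, is_hit: np.ndarray, weight_p: float) -> float:
    n = scores.size
    n_hits = int(is_hit.sum())
    w = np.abs(scores) ** weight_p
    hit_w = np.where(is_hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    profile = np.cumsum(hit_w / total - (~is_hit) / (n - n_hits))
    return float(profile[np.argmax(np.abs(profile))])


def gsea(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    ranked: pd.Series | None = None,
) -> list[GseaResult]:
    """Gene-set permutation GSEA over a collection of signatures.

    The null for each set draws ``n_perm`` random gene sets of the same size
    from the ranked genes.  NES divides the observed ES by the mean |ES| of
    same-signed permutations; the nominal p is the same-signed tail fraction;
    FDR compares observed |NES| to the pooled permuted |NES| distribution
    (ratio of tails, clipped to [0, 1]).  Pass ``ranked`` directly for
    preranked mode.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    if ranked is None:
        ranked = rank_genes(expr)
    rng = np.random.default_rng(seed)
    scores = ranked.to_numpy()
    symbols = ranked.index.to_numpy()
    n = len(symbols)

    observed: list[tuple[str, float, int]] = []
    null_nes_pool: list[np.ndarray] = []
    per_set: list[tuple[float, np.ndarray]] = []
    for gs in sets:
        is_hit = np.isin(symbols, list(gs.genes))
        n_hits = int(is_hit.sum())
        if n_hits == 0 or n_hits == n:
            raise ValueError(f"gene set {gs.name!r} empty or saturating after intersection")
        es = _es_only(scores, is_hit, weight_p)
        perm_es = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n, size=n_hits, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[idx] = True
            perm_es[i] = _es_only(scores, hit, weight_p)
        observed.append((gs.name, es, n_hits))
        per_set.append((es, perm_es))
        # permutation NES for the FDR pool, normalized within sign
        pos, neg = perm_es[perm_es > 0], perm_es[perm_es < 0]
        parts = []
        if pos.size:
            parts.append(pos / pos.mean())
        if neg.size:
            parts.append(neg / np.abs(neg).mean())
        null_nes_pool.append(np.abs(np.concatenate(parts)) if parts else np.array([]))

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_nes: list[float] = []
    results: list[GseaResult] = []
    for (name, es, n_hits), (_, perm_es) in zip(observed, per_set):
        same_sign = perm_es[perm_es > 0] if es >= 0 else perm_es[perm_es < 0]
        if same_sign.size == 0:
            nes = np.nan
            p_nom = 1.0 / n_perm
        else:
            nes = es / np.abs(same_sign).mean()
            n_extreme = int((np.abs(same_sign) >= abs(es)).sum())
            p_nom = n_extreme / same_sign.size if n_extreme else 1.0 / n_perm
        obs_nes.append(nes)
        results.append(GseaResult(name, es, float(nes), float(p_nom), np.nan, n_hits))

    abs_obs = np.abs(np.array(obs_nes, dtype=float))
    final: list[GseaResult] = []
    for r, a in zip(results, abs_obs):
        if not np.isfinite(a) or pooled.size == 0:
            fdr = 1.0
        else:
            tail_null = (pooled >= a).mean()
            tail_obs = (abs_obs[np.isfinite(abs_obs)] >= a).mean()
            fdr = float(np.clip(tail_null / tail_obs, 0.0, 1.0)) if tail_obs > 0 else 1.0
        final.append(
            GseaResult(r.name, r.es, r.nes, r.p_nominal, fdr, r.n_hits)
        )
    return final
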