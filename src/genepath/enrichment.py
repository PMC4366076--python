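"""Pathway enrichment on gene-based association results.

Two permutation-calibrated statistics over a ranked gene list:

* **WKST** — the GSEA-style weighted Kolmogorov-Smirnov running sum.
  Walking down the list, the running sum rises by ``r_i / sum_{g in S} r_g``
  at pathway members and falls by ``1/(N - N_S)`` elsewhere; the
  enrichment score ES is the maximum deviation from zero (sign kept).
* **WRST** — the Wilcoxon rank-sum statistic, the sum of the 1-based list
  ranks of the member genes (small = enriched at the top).

The null distribution comes from phenotype permutation: the phenotype is
shuffled, the entire gene-based test and ranking is recomputed, and both
statistics are re-evaluated per pathway on the permuted ranking.  One
shared permutation stream serves all pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import GbstEngine

_MIN_P = float(np.nextafter(0, 1))


@dataclass
class RankedGeneList:
    """Genes sorted by a non-increasing importance metric r = -log10(p)."""

    genes: list
    metric: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("ranking metric must be non-increasing")
        if np.any(self.metric < 0):
            raise ValueError("ranking metric must be non-negative")

    def __len__(self) -> int:
        return len(self.genes)

    def ranks_of(self, members) -> np.ndarray:
        """1-based list ranks of the member genes present in the list."""
        pos = {g: i + 1 for i, g in enumerate(self.genes)}
        return np.array(sorted(pos[g] for g in members if g in pos), dtype=int)


def rank_genes(pvalues, positions: pd.DataFrame | None = None) -> RankedGeneList:
    """Rank genes by r = -log10(p), descending.

    ``pvalues`` is a Series (single phenotype) or DataFrame (joint mode:
    one column per phenotype, the metric is -log10 of the product, i.e. the
    sum of the per-phenotype metrics).  Ties are broken by chromosome then
    start position when ``positions`` (indexed by gene id, with
    ``chromosome``/``start`` columns) is given, else by gene id; the sort
    is stable.  Zero p-values are capped at the smallest positive float
    with a warning.
    """
    if isinstance(pvalues, pd.DataFrame):
        frame = pvalues.astype(float)
    else:
        frame = pd.Series(pvalues, dtype=float).to_frame("p")
    frame = frame.dropna()
    if ((frame < 0) | (frame > 1)).any().any():
        raise ValueError("p-values must lie in [0, 1]")
    if (frame == 0).any().any():
        warnings.warn("p = 0 encountered; capping at the smallest positive float")
        frame = frame.clip(lower=_MIN_P)
    metric = (-np.log10(frame)).sum(axis=1)

    order = pd.DataFrame({"metric": metric})
    if positions is not None:
        order = order.join(positions[["chromosome", "start"]], how="left")
    else:
        order["chromosome"] = ""
        order["start"] = 0
    order = order.sort_values(
        ["metric", "chromosome", "start"],
        ascending=[False, True, True],
        kind="stable",
    )
    return RankedGeneList(genes=list(order.index), metric=order["metric"].to_numpy())


@dataclass
class EnrichmentScore:
    es: float
    trace: np.ndarray  # running sum after each list position


def enrichment_score(ranked: RankedGeneList, members) -> EnrichmentScore:
    """Weighted KS running sum and its maximum deviation.

    Raises when the pathway covers the whole list (the decrement is then
    undefined) or shares no gene with it.  The running sum always returns
    to zero at the end of the list because increments and decrements each
    total one.
    """
    member_set = set(members)
    in_set = np.array([g in member_set for g in ranked.genes], dtype=bool)
    n = len(ranked)
    n_s = int(in_set.sum())
    if n_s == 0:
        raise ValueError("pathway shares no gene with the ranked list")
    if n_s == n:
        raise ValueError("pathway contains every listed gene; decrement undefined")
    r_sum = ranked.metric[in_set].sum()
    steps = np.empty(n)
    if r_sum > 0:
        steps[in_set] = ranked.metric[in_set] / r_sum
    else:
        # all member p-values are 1: fall back to uniform increments
        steps[in_set] = 1.0 / n_s
    steps[~in_set] = -1.0 / (n - n_s)
    trace = np.cumsum(steps)
    i = int(np.argmax(np.abs(trace)))
    return EnrichmentScore(es=float(trace[i]), trace=trace)


def wrst_statistic(ranked: RankedGeneList, members) -> int:
    """Sum of the 1-based list ranks of the member genes."""
    ranks = ranked.ranks_of(members)
    if ranks.size == 0:
        raise ValueError("pathway shares no gene with the ranked list")
    return int(ranks.sum())


def _pathway_members_in_universe(pathways, universe) -> dict:
    uni = set(universe)
    out = {}
    for pid, genes in pathways.members.items():
        kept = [g for g in genes if g in uni]
        if kept and len(kept) < len(uni):
            out[pid] = kept
    return out


def permutation_null(
    y,
    dosage: np.ndarray,
    Z,
    gene_map: dict,
    pathways,
    positions: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    methods: tuple = ("wkst", "wrst"),
    residual_permutation: bool = False,
) -> pd.DataFrame:
    """Phenotype-permutation p-values for every pathway and method.

    Per permutation the phenotype entries are shuffled and the full
    gene-test -> ranking -> statistic pipeline is recomputed (the
    projected genotype covariances are phenotype-free and reused).  For
    the WKST, enrichment means a large ES: ``p_raw = #{ES_perm >=
    ES_obs}/n_perm``; for the WRST a small rank sum:
    ``p_raw = #{RS_perm <= RS_obs}/n_perm``.  The bias-corrected
    ``(1 + #)/(1 + n_perm)`` estimate is reported alongside.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    y = np.asarray(y, dtype=float)
    engine = GbstEngine(np.asarray(dosage, dtype=float), gene_map, Z)

    def ranking_for(vec) -> RankedGeneList:
        _, pvals = engine.statistics(vec)
        p = pd.Series(pvals, index=engine.gene_ids).dropna().clip(lower=_MIN_P)
        return rank_genes(p, positions=positions)

    obs_list = ranking_for(y)
    members = _pathway_members_in_universe(pathways, obs_list.genes)
    if not members:
        raise ValueError("no pathway overlaps the tested gene universe")

    obs = {}
    for pid, genes in members.items():
        obs[pid] = {
            "wkst": enrichment_score(obs_list, genes).es,
            "wrst": wrst_statistic(obs_list, genes),
            "n_s": len(set(genes) & set(obs_list.genes)),
        }

    if residual_permutation:
        q = engine.q
        base = y - q @ (q.T @ y)
    else:
        base = y
    rng = np.random.default_rng(seed)
    counts = {pid: {"wkst": 0, "wrst": 0} for pid in members}
    n = len(y)
    for _ in range(n_perm):
        perm_list = ranking_for(base[rng.permutation(n)])
        for pid, genes in members.items():
            if "wkst" in methods:
                es = enrichment_score(perm_list, genes).es
                if es >= obs[pid]["wkst"] - 1e-12:
                    counts[pid]["wkst"] += 1
            if "wrst" in methods:
                rs = wrst_statistic(perm_list, genes)
                if rs <= obs[pid]["wrst"]:
                    counts[pid]["wrst"] += 1

    rows = []
    for pid in members:
        for method in methods:
            k = counts[pid][method]
            rows.append(
                {
                    "pathway_id": pid,
                    "method": method,
                    "n_s": obs[pid]["n_s"],
                    "statistic": obs[pid][method],
                    "p_raw": k / n_perm,
                    "p_corrected": (1 + k) / (1 + n_perm),
                }
            )
    out = pd.DataFrame(rows)
    # rank within each method: smaller corrected p first, ties by a more
    # extreme statistic (larger ES, smaller RS)
    ranks = []
    for method, sub in out.groupby("method"):
        tiebreak = -sub["statistic"] if method == "wkst" else sub["statistic"]
        order = np.lexsort((tiebreak.to_numpy(), sub["p_corrected"].to_numpy()))
        r = np.empty(len(sub), dtype=int)
        r[order] = np.arange(1, len(sub) + 1)
        ranks.append(pd.Series(r, index=sub.index))
    out["rank"] = pd.concat(ranks).sort_index()
    return out.sort_values(["method", "rank"], kind="stable").reset_index(drop=True)


def permutation_null_joint(
    ys: dict,
    dosage: np.ndarray,
    Z,
    gene_map: dict,
    pathways,
    positions: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    methods: tuple = ("wkst", "wrst"),
) -> pd.DataFrame:
    """Joint-metric permutation enrichment over several phenotypes.

    ``ys`` maps phenotype name -> vector on one shared sample set.  Genes
    are ranked by the product of their per-phenotype p-values
    (r = -log10(prod p) = sum of the single-phenotype metrics); one
    permutation of the sample indices is applied to every phenotype
    simultaneously, preserving their cross-correlation.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    vecs = {k: np.asarray(v, dtype=float) for k, v in ys.items()}
    engine = GbstEngine(np.asarray(dosage, dtype=float), gene_map, Z)

    def ranking_for(perm=None) -> RankedGeneList:
        cols = {}
        for name, v in vecs.items():
            _, pvals = engine.statistics(v if perm is None else v[perm])
            cols[name] = pd.Series(pvals, index=engine.gene_ids)
        frame = pd.DataFrame(cols).dropna().clip(lower=_MIN_P)
        return rank_genes(frame, positions=positions)

    obs_list = ranking_for()
    members = _pathway_members_in_universe(pathways, obs_list.genes)
    if not members:
        raise ValueError("no pathway overlaps the tested gene universe")
    obs = {
        pid: {
            "wkst": enrichment_score(obs_list, genes).es,
            "wrst": wrst_statistic(obs_list, genes),
            "n_s": len(set(genes) & set(obs_list.genes)),
        }
        for pid, genes in members.items()
    }
    rng = np.random.default_rng(seed)
    counts = {pid: {"wkst": 0, "wrst": 0} for pid in members}
    n = len(next(iter(vecs.values())))
    for _ in range(n_perm):
        perm_list = ranking_for(rng.permutation(n))
        for pid, genes in members.items():
            if "wkst" in methods and (
                enrichment_score(perm_list, genes).es >= obs[pid]["wkst"] - 1e-12
            ):
                counts[pid]["wkst"] += 1
            if "wrst" in methods and (
                wrst_statistic(perm_list, genes) <= obs[pid]["wrst"]
            ):
                counts[pid]["wrst"] += 1
    rows = [
        {
            "pathway_id": pid,
            "method": method,
            "n_s": obs[pid]["n_s"],
            "statistic": obs[pid][method],
            "p_raw": counts[pid][method] / n_perm,
            "p_corrected": (1 + counts[pid][method]) / (1 + n_perm),
        }
        for pid in members
        for method in methods
    ]
    out = pd.DataFrame(rows)
    ranks = []
    for method, sub in out.groupby("method"):
        tiebreak = -sub["statistic"] if method == "wkst" else sub["statistic"]
        order = np.lexsort((tiebreak.to_numpy(), sub["p_corrected"].to_numpy()))
        r = np.empty(len(sub), dtype=int)
        r[order] = np.arange(1, len(sub) + 1)
        ranks.append(pd.Series(r, index=sub.index))
    out["rank"] = pd.concat(ranks).sort_index()
    return out.sort_values(["method", "rank"], kind="stable").reset_index(drop=True)


def rank_pathways(results: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Top pathways per method (and per phenotype column when present).

    Ordered by corrected p, ties broken by the more extreme statistic.
    Returns fewer rows with a warning when fewer pathways exist.
    """
    if results.empty:
        raise ValueError("no enrichment results to rank")
    keys = [c for c in ("phenotype", "method") if c in results.columns]
    frames = []
    for _, sub in results.groupby(keys) if keys else [((), results)]:
        method = sub["method"].iloc[0] if "method" in sub.columns else "wkst"
        tiebreak = -sub["statistic"] if method == "wkst" else sub["statistic"]
        order = np.lexsort((tiebreak.to_numpy(), sub["p_corrected"].to_numpy()))
        if len(sub) < top_k:
            warnings.warn(
                f"requested top {top_k} but only {len(sub)} pathways available"
            )
        frames.append(sub.iloc[order[:top_k]])
    return pd.concat(frames).reset_index(drop=True)
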