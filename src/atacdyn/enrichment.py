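"""Gene-set over-representation and preranked enrichment with reversibility.

Two complementary analyses over user-supplied GMT gene sets:

* hypergeometric over-representation (ORA) of an unranked gene list, with
  BH adjustment across sets;
* preranked GSEA over peak-level differential statistics: each
  significant peak contributes one (gene, log2FC) entry (a gene may
  appear several times, one entry per peak), the enrichment score is the
  maximum deviation of the weighted running sum, and the null comes from
  permuting entry-to-set membership labels (equivalently, redrawing the
  hit positions uniformly), which is the appropriate null for a
  preranked list. NES normalizes by the mean same-sign permutation ES;
  the FDR follows the standard same-sign NES ratio procedure. Sets with
  FDR <= 0.1 are called significant.

A gene set is flagged "reversible" when it is enriched with opposite NES
signs in the selection-onset (day 0 vs 3) and selection-release
(day 7 vs 10) comparisons, whether or not both enrichments clear the FDR
threshold.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (set name, description, members...); empty sets dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            members = [g for g in fields[2:] if g]
            if members:
                sets[fields[0]] = members
    return sets


def hypergeometric_ora(
    gene_list: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set."""
    uni = set(universe)
    genes = set(gene_list) & uni
    if not genes:
        logger.warning("gene list has no overlap with the universe; all p = 1")
    M, N = len(uni), len(genes)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & uni
        k = len(genes & inset)
        n = len(inset)
        if n == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N > 0 else 1.0
        rows.append({"set": name, "set_size": n, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] <= 0.1
    return out


def build_ranked_list(
    differential: pd.DataFrame,
    annotations: pd.DataFrame,
    padj_threshold: float = 0.05,
    collapse: str = "none",
) -> pd.DataFrame:
    """Build the peak-level preranked list for one day pair.

    Keeps peaks with padj below the threshold and an assigned gene; each
    retained peak contributes one (gene_id, log2FC) entry, so a gene with
    several significant peaks appears several times (each peak considered
    separately). ``collapse='max_abs'`` instead keeps one entry per gene,
    the one with the largest |log2FC|. Sorted descending by log2FC, ties
    broken by peak_id.
    """
    if collapse not in ("none", "max_abs"):
        raise ValueError("collapse must be 'none' or 'max_abs'")
    sig = differential[differential["padj"] < padj_threshold]
    merged = sig.join(annotations[["gene_id"]], how="inner")
    merged = merged[merged["gene_id"].astype(str) != ""]
    if merged.empty:
        logger.warning("no significant annotated peaks; ranked list is empty")
        return pd.DataFrame(columns=["peak_id", "gene_id", "stat"])
    out = pd.DataFrame(
        {
            "peak_id": merged.index,
            "gene_id": merged["gene_id"].to_numpy(),
            "stat": merged["log2FC"].to_numpy(),
        }
    )
    if collapse == "max_abs":
        out = (
            out.reindex(out["stat"].abs().sort_values(ascending=False).index)
            .drop_duplicates("gene_id")
        )
    return out.sort_values(["stat", "peak_id"], ascending=[False, True]).reset_index(drop=True)


def _running_es(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Signed extremum of the GSEA running sum; vectorized over rows of ``hits``."""
    hits = np.atleast_2d(hits).astype(float)
    w = weights[None, :] * hits
    wsum = w.sum(axis=1, keepdims=True)
    wsum[wsum == 0] = 1.0
    nh = hits.sum(axis=1, keepdims=True)
    nmiss = hits.shape[1] - nh
    nmiss[nmiss == 0] = 1.0
    dev = np.cumsum(w / wsum - (1.0 - hits) / nmiss, axis=1)
    idx = np.abs(dev).argmax(axis=1)
    return dev[np.arange(len(dev)), idx]


def preranked_gsea(
    ranked_list: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted running-sum enrichment with an entry-label permutation null.

    Returns one row per retained set: ES, NES, perm_p, FDR, direction and
    the significance flag (FDR <= 0.1).
    """
    if ranked_list.empty:
        logger.warning("empty ranked list; GSEA skipped")
        return pd.DataFrame(
            columns=["set", "size", "ES", "NES", "perm_p", "FDR", "direction", "significant"]
        )
    rng = np.random.default_rng(seed)
    genes = ranked_list["gene_id"].to_numpy()
    stats_ = ranked_list["stat"].to_numpy(dtype=float)
    N = len(genes)
    weights = np.abs(stats_) ** weight if weight > 0 else np.ones(N)

    records = []
    perm_nes_all: list[np.ndarray] = []
    for name, members in gene_sets.items():
        hit = np.isin(genes, list(members))
        nh = int(hit.sum())
        if nh < min_size or nh == N:
            continue
        es = float(_running_es(weights, hit)[0])
        # entry-label permutation: redraw nh hit positions uniformly
        order = rng.random((n_perm, N)).argsort(axis=1)
        perm_hits = np.zeros((n_perm, N), dtype=bool)
        rows_idx = np.repeat(np.arange(n_perm), nh)
        perm_hits[rows_idx, order[:, :nh].ravel()] = True
        perm_es = _running_es(weights, perm_hits)

        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, perm_p, perm_nes = np.sign(es) * np.inf, 1.0 / (n_perm + 1.0), np.array([])
        else:
            denom = np.abs(perm_es[same_sign]).mean()
            denom = denom if denom > 0 else 1.0
            nes = es / denom
            exceed = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
            perm_p = (1.0 + exceed) / (1.0 + n_same)
            perm_nes = perm_es / denom  # all perms normalized by this set's factor
        records.append(
            {"set": name, "size": nh, "ES": es, "NES": float(nes), "perm_p": float(perm_p)}
        )
        perm_nes_all.append(perm_nes)

    out = pd.DataFrame(records)
    if out.empty:
        out["FDR"] = out["direction"] = out["significant"] = None
        return out

    pooled = np.concatenate([p for p in perm_nes_all if len(p)]) if perm_nes_all else np.array([])
    obs = out["NES"].to_numpy()
    fdr = np.ones(len(out))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            fdr[i] = 0.0
            continue
        if nes >= 0:
            pos = pooled[pooled >= 0]
            num = (pos >= nes).mean() if len(pos) else 0.0
            obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
            den = (obs_pos >= nes).mean() if len(obs_pos) else 1.0
        else:
            neg = pooled[pooled < 0]
            num = (neg <= nes).mean() if len(neg) else 0.0
            obs_neg = obs[np.isfinite(obs) & (obs < 0)]
            den = (obs_neg <= nes).mean() if len(obs_neg) else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 0.0
    out["FDR"] = fdr
    out["direction"] = np.where(out["NES"] >= 0, "increased", "decreased")
    out["significant"] = out["FDR"] <= 0.1
    return out.sort_values("NES", ascending=False).reset_index(drop=True)


def top_sets(results: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Top-n positively and top-n negatively enriched sets by NES."""
    if results.empty:
        return results
    pos = results[results["NES"] >= 0].nlargest(n, "NES")
    neg = results[results["NES"] < 0].nsmallest(n, "NES")
    return pd.concat([pos, neg]).reset_index(drop=True)


def flag_reversible_sets(
    results_pair_03: pd.DataFrame, results_pair_710: pd.DataFrame
) -> pd.DataFrame:
    """Flag sets enriched with opposite NES signs in the two wave comparisons."""
    cols = ["set", "NES", "FDR", "significant"]
    a = results_pair_03[cols].rename(
        columns={"NES": "NES_03", "FDR": "FDR_03", "significant": "sig_03"}
    )
    b = results_pair_710[cols].rename(
        columns={"NES": "NES_710", "FDR": "FDR_710", "significant": "sig_710"}
    )
    merged = a.merge(b, on="set", how="outer")
    nes_a, nes_b = merged["NES_03"], merged["NES_710"]
    merged["reversible"] = (
        nes_a.notna() & nes_b.notna() & (np.sign(nes_a) * np.sign(nes_b) < 0)
    )
    return merged
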