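"""Preranked gene-set enrichment on the Z-ranked lists.

Implements the weighted Kolmogorov–Smirnov enrichment score: walking
the ranked list, member genes push the running sum up in proportion to
|Z|^p (p = 1 by default), non-members push it down by 1/(N - N_hit);
ES is the extremum of largest magnitude. Significance comes from a
gene-label permutation null (random same-size sets drawn from the
universe), the normalized enrichment score divides ES by the mean |ES|
of same-sign null draws (the size normalization), one-sided same-sign
p-values are Benjamini–Hochberg adjusted per tissue, and the
cross-tissue selection keeps every term significant (adj-p below a
threshold) in at least one tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._exceptions import DataError

__all__ = [
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "gsea_preranked",
    "bh_adjust",
    "select_terms",
]


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: ``term<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are removed (order-preserving) with a
    warning; malformed lines raise with their line number.
    """
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}: malformed GMT line {i} (need term, description, genes)")
        term, _desc, *genes = parts
        genes = [g for g in genes if g]
        dedup = list(dict.fromkeys(genes))
        if len(dedup) < len(genes):
            warnings.warn(f"term {term!r}: removed {len(genes) - len(dedup)} duplicate genes")
        collection[term] = dedup
    if not collection:
        warnings.warn(f"{path}: empty gene-set collection")
    return collection


def write_gmt(collection: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in collection.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")


def _running_sum(z_abs_p: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Running enrichment statistic along the ranked list."""
    n = len(hit)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise DataError("gene set must be a proper non-empty subset of the universe")
    hit_w = z_abs_p * hit
    total = hit_w.sum()
    if total <= 0:
        hit_w = hit.astype(float)  # all-zero weights: fall back to equal steps
        total = hit_w.sum()
    steps = np.where(hit, hit_w / total, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def enrichment_score(
    ranked_genes, z_values, members, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score, running sum and leading edge.

    ``ranked_genes`` must already be ordered by decreasing Z; the ES is
    the running-sum value of largest magnitude (earliest position on
    ties). The leading edge holds the member genes at or before the
    extremum for positive ES, and at or after it for negative ES.
    """
    genes = np.asarray(ranked_genes)
    z = np.asarray(z_values, dtype=float)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in genes), count=len(genes), dtype=bool)
    rs = _running_sum(np.abs(z) ** weight, hit)
    i_ext = int(np.argmax(np.abs(rs)))
    es = float(rs[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, rs, leading


def _es_batch(z_abs_p: np.ndarray, hit_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ES for many same-size index sets (rows of hit_matrix)."""
    n = hit_matrix.shape[1]
    n_hit = hit_matrix.sum(axis=1)
    hit_w = z_abs_p[None, :] * hit_matrix
    totals = hit_w.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0
    if bad.any():
        hit_w[bad] = hit_matrix[bad].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    miss = -1.0 / (n - n_hit)
    steps = np.where(hit_matrix, hit_w / totals, miss[:, None])
    rs = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(rs), axis=1)
    return rs[np.arange(rs.shape[0]), idx]


@dataclass
class GseaResult:
    """Per-tissue preranked GSEA output."""

    table: pd.DataFrame  # term, es, nes, size, p_value, adj_p, leading_edge
    n_perm: int
    excluded: pd.DataFrame  # term, size, reason

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["adj_p"] <= alpha]


def gsea_preranked(
    ranked: pd.DataFrame,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` is the output of :func:`glycofuse.genescore.rank_genes`
    (index = gene, column ``Z``, already ordered). For each term the
    null is ``n_perm`` random gene sets of the same size drawn from the
    universe; NES = ES / mean(|ES_null| with the same sign);
    p = (1 + #{same-sign |ES_null| >= |ES|}) / (1 + #same-sign);
    BH adjustment across all tested terms.
    """
    genes = np.asarray(ranked.index)
    if len(set(genes)) != len(genes):
        raise DataError("ranked list contains duplicate genes")
    z_abs_p = np.abs(ranked["Z"].to_numpy(dtype=float)) ** weight
    n = len(genes)
    rng = np.random.default_rng(seed)
    universe = set(genes)

    rows, excluded = [], []
    null_cache: dict[int, np.ndarray] = {}
    for term, members in collection.items():
        inset = [g for g in dict.fromkeys(members) if g in universe]
        size = len(inset)
        if size < min_size or size > max_size:
            excluded.append({"term": term, "size": size, "reason": "size"})
            continue
        if size == n:
            excluded.append({"term": term, "size": size, "reason": "equals universe"})
            continue
        es, _, leading = enrichment_score(genes, ranked["Z"].to_numpy(), inset, weight)
        if size not in null_cache:
            hit_matrix = np.zeros((n_perm, n), dtype=bool)
            for r in range(n_perm):
                hit_matrix[r, rng.choice(n, size=size, replace=False)] = True
            null_cache[size] = _es_batch(z_abs_p, hit_matrix)
        es_null = null_cache[size]
        same = es_null >= 0 if es >= 0 else es_null < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes = es / max(np.abs(es_null).mean(), 1e-300)
            p = 1.0
        else:
            mean_abs = np.abs(es_null[same]).mean()
            nes = es / mean_abs if mean_abs > 0 else 0.0
            p = (1.0 + np.sum(np.abs(es_null[same]) >= abs(es))) / (1.0 + n_same)
        rows.append(
            {
                "term": term,
                "es": es,
                "nes": nes,
                "size": size,
                "p_value": p,
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "es", "nes", "size", "p_value", "leading_edge"])
    if len(table):
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["adj_p"] = pd.Series(dtype=float)
    table = table[["term", "es", "nes", "size", "p_value", "adj_p", "leading_edge"]]
    return GseaResult(
        table=table.reset_index(drop=True),
        n_perm=n_perm,
        excluded=pd.DataFrame(excluded, columns=["term", "size", "reason"]),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier(p: float, adj: float) -> str:
    if adj < 0.001:
        return "***"
    if adj < 0.01:
        return "**"
    if adj < 0.05:
        return "*"
    if p < 0.001:
        return "ooo"
    if p < 0.01:
        return "oo"
    if p < 0.05:
        return "o"
    return ""


def select_terms(
    results: dict[str, GseaResult], alpha: float = 0.01
) -> pd.DataFrame:
    """Cross-tissue NES matrix of terms significant in >= 1 tissue.

    Rows are the union of terms with adj-p <= alpha in at least one
    tissue; columns carry each tissue's NES plus a significance-tier
    annotation (``***``/``**``/``*`` on adjusted p, ``ooo``/``oo``/``o``
    on raw p).
    """
    if not results:
        raise DataError("at least one tissue's results are required")
    keep: set[str] = set()
    for res in results.values():
        keep |= set(res.table.loc[res.table["adj_p"] <= alpha, "term"])
    terms = sorted(keep)
    out = pd.DataFrame(index=pd.Index(terms, name="term"))
    for tissue, res in results.items():
        t = res.table.set_index("term")
        out[f"nes_{tissue}"] = t["nes"].reindex(terms)
        out[f"sig_{tissue}"] = [
            _tier(t.loc[term, "p_value"], t.loc[term, "adj_p"]) if term in t.index else ""
            for term in terms
        ]
    return out
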