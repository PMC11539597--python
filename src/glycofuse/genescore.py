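"""Per-gene fusion scores and their permutation-calibrated Z-scores.

For tissue k the fusion score of gene i is V_ik = sum_j MM_ij * sVIP_jk:
module membership weighted by the signed importance of each module in
the consensus model. The same contraction applied to the signed-VIP
vectors of the permuted models yields a per-gene null (module
memberships are fixed; only the importances vary under permutation),
and Z_i = (V_i - mean(Vperm_i)) / SD(Vperm_i). Ranked lists are ordered
by decreasing Z with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._exceptions import DataError

__all__ = ["gene_v", "gene_null", "gene_zscore", "rank_genes", "score_tissue"]


def _check_alignment(MM: pd.DataFrame, modules) -> None:
    if list(MM.columns) != list(modules):
        raise DataError(
            f"module order mismatch: MM columns {list(MM.columns)} vs sVIP {list(modules)}"
        )


def gene_v(MM: pd.DataFrame, svip: pd.Series) -> pd.Series:
    """V = MM . sVIP (matrix-vector product over the tissue's modules)."""
    _check_alignment(MM, svip.index)
    v = MM.to_numpy(dtype=float) @ svip.to_numpy(dtype=float)
    return pd.Series(v, index=MM.index, name="V")


def gene_null(MM: pd.DataFrame, svip_perm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene null: Vperm_in = sum_j MM_ij * sVIPperm_jn.

    ``svip_perm`` is permutation x module. MM is NOT recomputed under
    permutation — only the signed importances vary.
    """
    if svip_perm.shape[0] == 0:
        raise DataError("empty permutation archive")
    _check_alignment(MM, svip_perm.columns)
    vperm = MM.to_numpy(dtype=float) @ svip_perm.to_numpy(dtype=float).T
    return pd.DataFrame(vperm, index=MM.index, columns=svip_perm.index)


def gene_zscore(V: pd.Series, Vperm: pd.DataFrame) -> pd.Series:
    """Z = (V - mean of the gene's null) / SD of the null (ddof=1).

    Genes with zero null SD get Z = 0 (kept in the list) with a warning.
    """
    if Vperm.shape[1] < 2:
        raise DataError("need >= 2 permutations for a Z-score")
    mu = Vperm.mean(axis=1)
    sd = Vperm.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with zero null SD; Z set to 0")
    z = (V - mu).where(~zero, 0.0) / sd.where(~zero, 1.0)
    return z.rename("Z")


def rank_genes(Z: pd.Series) -> pd.DataFrame:
    """Ranked list by decreasing Z; ties broken by gene id (lexicographic)."""
    df = pd.DataFrame({"gene": Z.index, "Z": Z.to_numpy(dtype=float)})
    df = df.sort_values(["Z", "gene"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("gene")


def score_tissue(
    MM: pd.DataFrame, svip: pd.Series, svip_perm: pd.DataFrame
) -> pd.DataFrame:
    """Full per-tissue table: V, Z and rank for every gene.

    The caller restricts ``svip``/``svip_perm`` to the tissue's own
    transcript modules (a tissue contributing both transcript and lipid
    blocks scores its genes against the transcript modules only).
    """
    V = gene_v(MM, svip)
    Vperm = gene_null(MM, svip_perm)
    Z = gene_zscore(V, Vperm)
    out = rank_genes(Z)
    out.insert(0, "V", V.reindex(out.index))
    out["n_permutations"] = svip_perm.shape[0]
    return out
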