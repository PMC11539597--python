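"""Signed weighted co-expression network analysis per omics block.

Builds a signed adjacency from pairwise Pearson correlations, converts
it to topological overlap, clusters features by average linkage on
1 - TOM, cuts the dendrogram into modules, and summarises each module
by its eigengene (first principal component of the standardized member
profiles). Eigengenes are averaged per design group downstream of the
fusion model.

Module detection uses a static branch cut at ``cut_height`` times the
maximum merge height with minimum-size pruning (plus optional
membership-based rescue of unassigned features). This keeps the two
parameters that matter — cut height and minimum module size — while
avoiding the full Dynamic Hybrid machinery; the divergence is
documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._exceptions import DataError

UNASSIGNED = "unassigned"

__all__ = [
    "NetworkParams",
    "ModuleModel",
    "signed_adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengene",
    "module_membership",
    "summarize_by_group",
    "detect_modules",
]


@dataclass(frozen=True)
class NetworkParams:
    """Network construction parameters.

    Defaults follow the transcriptome settings (soft power 6, minimum
    module size 20, cut height 0.995); lipid blocks use power 20
    (plasma/liver/muscle) or 12 (adipose) with minimum size 5.
    """

    power: int = 6
    min_module_size: int = 20
    cut_height: float = 0.995
    reassign_threshold: float | None = None  # MM rescue of unassigned, off by default
    min_coherence: float | None = 1.05  # correlation eigenvalues vs Marchenko-Pastur edge
    min_membership: float | None = None  # None = noise-calibrated min(3/sqrt(n), 0.5)

    def validate(self) -> None:
        if self.power < 1:
            raise DataError("soft power must be >= 1")
        if not (0.0 < self.cut_height <= 1.0):
            raise DataError("cut_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise DataError("min_module_size must be >= 2")
        if self.min_membership is not None and not (0.0 <= self.min_membership <= 1.0):
            raise DataError("min_membership must be in [0, 1]")


LIPID_PARAMS = {
    "plasma": NetworkParams(power=20, min_module_size=5),
    "liver": NetworkParams(power=20, min_module_size=5),
    "muscle": NetworkParams(power=20, min_module_size=5),
    "adipose": NetworkParams(power=12, min_module_size=5),
}


@dataclass
class ModuleModel:
    """Module detection result for one block."""

    assignment: pd.Series  # feature -> "M1".. / "unassigned"
    eigengenes: pd.DataFrame  # module x sample, unit-norm PC1 scores
    explained_variance: pd.Series  # module -> PC1 variance fraction
    membership: pd.DataFrame  # feature x module Pearson correlations
    linkage_matrix: np.ndarray | None = None
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigengenes.index)


def signed_adjacency(X: pd.DataFrame, power: int = 6) -> pd.DataFrame:
    """Signed soft-thresholded adjacency: ((1 + cor) / 2) ** power."""
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = X.index[sd == 0].tolist()
        raise DataError(f"zero-variance features: {bad}")
    cor = np.corrcoef(vals)
    A = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=X.index, columns=X.index)


def tom_similarity(A: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap of a signed adjacency.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with connectivity k_i = sum_{u != i} A_iu and unit diagonal.
    """
    is_df = isinstance(A, pd.DataFrame)
    a = A.to_numpy(dtype=float) if is_df else np.asarray(A, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise DataError("adjacency must be symmetric")
    diag = np.diag(a).copy()
    k = a.sum(axis=1) - diag
    # shared-neighbour term excludes u == i and u == j
    num = a @ a - diag[:, None] * a - a * diag[None, :] + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=A.index, columns=A.columns)
    return tom


def cluster_modules(
    tom: pd.DataFrame, params: NetworkParams | None = None, X: pd.DataFrame | None = None
) -> tuple[pd.Series, np.ndarray]:
    """Cut the average-linkage dendrogram of 1 - TOM into modules.

    Candidate branches are obtained by cutting at ``cut_height`` times
    the maximum merge height. When expression ``X`` is given and
    ``min_coherence`` is set, branch quality is then judged against a
    random-matrix null (the Marchenko-Pastur upper edge
    ``(1 + sqrt(m/n))**2``, the largest correlation eigenvalue expected
    from an equally sized block of independent features):

    * a branch whose *second* correlation eigenvalue exceeds the edge
      still contains more than one latent factor and is recursively
      split along its dendrogram children;
    * a branch whose *top* eigenvalue does not clear the edge is carved
      out of pure noise and is not promoted to a module;
    * members whose correlation with their module eigengene falls below
      a noise-calibrated threshold (``min_membership``, default
      ``min(3/sqrt(n_samples), 0.5)`` — about three null-correlation
      standard errors) are released to unassigned.

    Together these stand in for the branch-quality and assignment
    checks of the Dynamic Hybrid cut while keeping the two published
    parameters (cut height, minimum module size) in control. Branches
    smaller than ``min_module_size`` are labelled unassigned; module
    labels M1, M2, ... are ordered by decreasing size. When
    ``reassign_threshold`` is set, unassigned features with a module
    membership above the threshold are rescued into their
    best-correlated module.
    """
    params = params or NetworkParams()
    params.validate()
    features = list(tom.index)
    n = len(features)
    if n < params.min_module_size:
        warnings.warn("fewer features than min_module_size; all unassigned")
        assignment = pd.Series(UNASSIGNED, index=features, name="module")
        return assignment, np.empty((0, 4))
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    h = params.cut_height * Z[:, 2].max()
    raw = fcluster(Z, t=h, criterion="distance")
    labels = pd.Series(raw, index=features)
    branches = [np.flatnonzero(labels.to_numpy() == c) for c in labels.unique()]

    use_eigen = params.min_coherence is not None and X is not None
    if use_eigen:
        Xv = X.to_numpy(dtype=float)
        members, children = _subtree(Z, n)
        cut_roots = _cut_roots(Z, children, n, h)
        branches = []
        for root in cut_roots:
            branches.extend(_split_branch(root, members, children, Xv, params, n))
        branches = [b for b in branches if _is_coherent(Xv[b], X.shape[1], params)]
    branches = [b for b in branches if len(b) >= params.min_module_size]
    # stable ordering: decreasing size, ties by smallest member index
    branches.sort(key=lambda b: (-len(b), int(b[0]) if len(b) else 0))
    assignment = pd.Series(UNASSIGNED, index=features, name="module", dtype=object)
    for i, b in enumerate(branches):
        assignment.iloc[np.asarray(b)] = f"M{i + 1}"

    if use_eigen and branches:
        assignment = _prune_members(X, assignment, params)

    if params.reassign_threshold is not None and X is not None:
        present = [lab for lab in pd.unique(assignment) if lab != UNASSIGNED]
        if present:
            E, _ = module_eigengene(X, assignment)
            mm = module_membership(X, E)
            for feat in assignment.index[assignment == UNASSIGNED]:
                row = mm.loc[feat]
                if row.max() > params.reassign_threshold:
                    assignment.loc[feat] = row.idxmax()
    return assignment, Z


def _subtree(Z: np.ndarray, n: int) -> tuple[dict, dict]:
    """Leaf membership and child pointers for every dendrogram node."""
    members = {i: [i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _, _) in enumerate(Z):
        node = n + k
        children[node] = (int(a), int(b))
        members[node] = members[int(a)] + members[int(b)]
    return members, children


def _cut_roots(Z: np.ndarray, children: dict, n: int, cut: float) -> list[int]:
    """Maximal nodes whose merge height does not exceed the cut."""
    roots: list[int] = []
    stack = [2 * n - 2] if n > 1 else [0]
    while stack:
        node = stack.pop()
        if node < n or Z[node - n, 2] <= cut:
            roots.append(node)
        else:
            stack.extend(children[node])
    return roots


def _mp_edge(m: int, n_samples: int) -> float:
    return (1.0 + np.sqrt(m / n_samples)) ** 2


def _split_branch(
    node: int, members: dict, children: dict, Xv: np.ndarray, params: NetworkParams, n: int
) -> list[list[int]]:
    """Recursively split a branch while it holds more than one latent factor.

    A branch is split when the second eigenvalue of its member
    correlation matrix exceeds ``min_coherence`` times the
    Marchenko-Pastur edge (one shared factor explains one eigenvalue
    above the noise edge; a second one signals merged modules).
    """
    mem = members[node]
    if node < n or len(mem) < 2 * params.min_module_size:
        return [mem]
    sub = Xv[mem]
    lam = np.linalg.eigvalsh(np.corrcoef(sub))
    if lam[-2] <= params.min_coherence * _mp_edge(len(mem), sub.shape[1]):
        return [mem]
    left, right = children[node]
    if min(len(members[left]), len(members[right])) < params.min_module_size:
        big, small = (left, right) if len(members[left]) >= len(members[right]) else (right, left)
        return _split_branch(big, members, children, Xv, params, n) + [members[small]]
    return _split_branch(left, members, children, Xv, params, n) + _split_branch(
        right, members, children, Xv, params, n
    )


def _is_coherent(sub: np.ndarray, n_samples: int, params: NetworkParams) -> bool:
    """Top correlation eigenvalue above the noise (Marchenko-Pastur) edge?"""
    if len(sub) < 2:
        return False
    lam1 = float(np.linalg.eigvalsh(np.corrcoef(sub))[-1])
    return lam1 > params.min_coherence * _mp_edge(len(sub), n_samples)


def _prune_members(
    X: pd.DataFrame, assignment: pd.Series, params: NetworkParams
) -> pd.Series:
    """Release weakly attached members (low module membership) to unassigned.

    The default threshold min(3/sqrt(n), 0.5) is ~three standard errors
    of a null correlation over n samples: independent features attached
    to a branch by average linkage fall below it, true members (MM near
    the within-module correlation) stay far above.
    """
    thr = params.min_membership
    if thr is None:
        thr = min(3.0 / np.sqrt(X.shape[1]), 0.5)
    if thr <= 0:
        return assignment
    E, _ = module_eigengene(X, assignment)
    mm = module_membership(X, E)
    out = assignment.copy()
    for lab in E.index:
        in_module = assignment == lab
        weak = in_module & (mm[lab] < thr)
        if weak.any():
            out[weak] = UNASSIGNED
        if (out == lab).sum() < params.min_module_size:
            out[out == lab] = UNASSIGNED
    # re-label to keep M1.. ordered by decreasing size
    sizes = out.value_counts()
    kept = [lab for lab in sizes.index if lab != UNASSIGNED]
    kept.sort(key=lambda lab: (-sizes[lab], int(lab[1:])))
    rename = {lab: f"M{i + 1}" for i, lab in enumerate(kept)}
    return out.map(lambda lab: rename.get(lab, UNASSIGNED)).rename("module")


def _standardize(X: pd.DataFrame) -> np.ndarray:
    v = X.to_numpy(dtype=float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (v - mu) / sd


def module_eigengene(
    X: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-PC eigengene per module with deterministic orientation.

    Features are standardized across samples; the eigengene is the
    unit-norm first right singular vector of the module submatrix,
    sign-oriented so that its correlation with the mean member profile
    is non-negative. Returns (eigengenes module x sample,
    explained variance fraction per module).
    """
    labels = [lab for lab in pd.unique(assignment) if lab != UNASSIGNED]
    E = {}
    ev = {}
    for lab in labels:
        members = assignment.index[assignment == lab]
        sub = _standardize(X.loc[members])
        _, s, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        mean_profile = sub.mean(axis=0)
        orient = float(e @ mean_profile)
        if orient == 0.0:
            nz = np.nonzero(e)[0]
            orient = e[nz[0]] if nz.size else 1.0
        if orient < 0:
            e = -e
        E[lab] = e
        ev[lab] = float(s[0] ** 2 / np.sum(s**2)) if s.size else 0.0
    eig = pd.DataFrame(E, index=X.columns).T
    eig.index.name = "module"
    return eig, pd.Series(ev, name="explained_variance")


def module_membership(X: pd.DataFrame, E: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every feature with every module eigengene."""
    if not X.columns.equals(E.columns):
        raise DataError("sample order of expression and eigengenes must match")
    xv = X.to_numpy(dtype=float)
    sd = xv.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance features; their module membership is 0"
        )
    xs = _standardize(X)
    ev = E.to_numpy(dtype=float)
    es = (ev - ev.mean(axis=1, keepdims=True)) / ev.std(axis=1, keepdims=True)
    mm = xs @ es.T / X.shape[1]
    mm[zero, :] = 0.0
    mm = np.clip(mm, -1.0, 1.0)
    return pd.DataFrame(mm, index=X.index, columns=E.index)


def summarize_by_group(E: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean eigengene per design group (module x group).

    Group columns follow the design's group order of first appearance.
    """
    if not set(E.columns) <= set(design.index):
        raise DataError("eigengene samples missing from the design table")
    groups = design.loc[E.columns, "group"]
    order = pd.unique(design["group"])
    out = E.T.groupby(groups).mean().T.reindex(columns=order)
    if out.isna().any().any():
        empty = out.columns[out.isna().any()].tolist()
        raise DataError(f"design groups without samples: {empty}")
    out.index.name = "module"
    return out


def detect_modules(X: pd.DataFrame, params: NetworkParams | None = None) -> ModuleModel:
    """Full per-block pipeline: adjacency -> TOM -> cut -> eigengenes -> MM."""
    params = params or NetworkParams()
    A = signed_adjacency(X, power=params.power)
    tom = tom_similarity(A)
    assignment, Z = cluster_modules(tom, params, X=X)
    if (assignment == UNASSIGNED).all():
        E = pd.DataFrame(columns=X.columns)
        E.index.name = "module"
        ev = pd.Series(dtype=float)
        mm = pd.DataFrame(index=X.index, columns=E.index, dtype=float)
    else:
        E, ev = module_eigengene(X, assignment)
        mm = module_membership(X, E)
    return ModuleModel(
        assignment=assignment,
        eigengenes=E,
        explained_variance=ev,
        membership=mm,
        linkage_matrix=Z,
        params=params,
    )
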