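"""Multiblock fusion of group-level eigengene tables against glycemia.

Two fitted-model front ends in the statsmodels idiom:

* :class:`CCSWA` — common components and specific weights analysis
  (ComDim): unsupervised shared scores across blocks with per-block,
  per-dimension saliences.
* :class:`ConsensusOPLS` — consensus kernel-OPLS regression of a
  continuous outcome (mean basal glycemia per group) on a weighted sum
  of per-block linear kernels, with one predictive latent variable, up
  to three Y-orthogonal latent variables (count chosen by
  cross-validated Q2), k-fold cross-validation, a permutation test of
  model significance, and per-module (signed) variable importances.

Block weights are proportional to the positive part of the modified RV
coefficient between each block kernel and the outer product of the
centered outcome; they are recomputed inside every cross-validation
fold and every permutation so no information leaks from test groups or
from the unpermuted outcome.

The kernel-OPLS fit is algebraically equivalent, for a linear kernel
K = X Xᵀ, to a direct NIPALS orthogonal-projections-to-latent-structures
fit on X; the test suite holds it to that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConvergenceError, DataError

__all__ = [
    "build_kernels",
    "rv_modified",
    "consensus_weights",
    "kopls_fit",
    "cross_validate_q2",
    "vip_signed",
    "CCSWA",
    "CcswaResults",
    "ConsensusOPLS",
    "ConsensusOPLSResults",
    "PermutationResult",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# kernels and block weights
# ---------------------------------------------------------------------------

def _center_columns(X: np.ndarray, means: np.ndarray | None = None):
    if means is None:
        means = X.mean(axis=0)
    return X - means[None, :], means


def build_kernels(
    blocks: Mapping[str, pd.DataFrame], center: bool = True
) -> dict[str, np.ndarray]:
    """Frobenius-normalized linear kernel per block: K_b = X Xᵀ / ||X Xᵀ||_F."""
    kernels = {}
    for name, X in blocks.items():
        x = X.to_numpy(dtype=float)
        if center:
            x, _ = _center_columns(x)
        K = x @ x.T
        norm = np.linalg.norm(K, "fro")
        if norm < _EPS:
            raise DataError(f"block {name!r} is (numerically) all zero after centering")
        kernels[name] = K / norm
    return kernels


def rv_modified(K1: np.ndarray, K2: np.ndarray) -> float:
    """Modified RV coefficient between two sample-similarity matrices.

    Diagonals are removed before comparing; the result lies in [-1, 1].
    """
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    if K1.shape != K2.shape or K1.shape[0] != K1.shape[1]:
        raise DataError("kernels must be square and of identical shape")
    A = K1 - np.diag(np.diag(K1))
    B = K2 - np.diag(np.diag(K2))
    na = np.sqrt(np.sum(A * A))
    nb = np.sqrt(np.sum(B * B))
    if na < _EPS or nb < _EPS:
        raise DataError("kernel with zero off-diagonal part")
    return float(np.sum(A * B) / (na * nb))


def consensus_weights(
    kernels: Mapping[str, np.ndarray],
    y: np.ndarray | pd.Series,
    on_degenerate: str = "error",
) -> pd.Series:
    """Block weights proportional to max(RVmod(K_b, y yᵀ), 0), summing to 1.

    ``on_degenerate`` controls the all-nonpositive case: ``"error"``
    (no block predicts y) or ``"uniform"`` (equal weights; used inside
    cross-validation folds and permutation refits where aborting is not
    an option).
    """
    yv = np.asarray(y, dtype=float)
    yc = yv - yv.mean()
    Ky = np.outer(yc, yc)
    rv = np.array([rv_modified(K, Ky) for K in kernels.values()])
    w = np.clip(rv, 0.0, None)
    if w.sum() < _EPS:
        if on_degenerate == "uniform":
            w = np.ones(len(kernels))
        else:
            raise DataError("no block has positive RV with the outcome")
    w = w / w.sum()
    return pd.Series(w, index=list(kernels.keys()), name="weight")


# ---------------------------------------------------------------------------
# kernel OPLS
# ---------------------------------------------------------------------------

@dataclass
class _OrthoComponent:
    """One Y-orthogonal component; enough state to project test kernels."""

    c: np.ndarray  # generator: t_o = K_cur @ c / s
    s: float  # training norm of the raw orthogonal score
    t_o: np.ndarray  # unit-norm training score
    d: np.ndarray  # K_cur @ t_o (pre-deflation), for test-kernel deflation


@dataclass
class _KoplsFit:
    t_p: np.ndarray
    b: float
    components: list[_OrthoComponent]
    yhat: np.ndarray  # centered scale


def _kopls_core(K: np.ndarray, yc: np.ndarray, n_ortho: int) -> _KoplsFit:
    """K-OPLS on a centered kernel and centered outcome.

    Predictive score t_p = K_deflated @ yc; each orthogonal score is the
    part of the kernel image of t_p not collinear with t_p, followed by
    projection deflation K <- (I - t_o t_oᵀ) K (I - t_o t_oᵀ).
    """
    Kcur = np.array(K, dtype=float)
    comps: list[_OrthoComponent] = []
    for _ in range(n_ortho):
        t = Kcur @ yc
        tt = float(t @ t)
        yKy = float(yc @ t)
        if tt < _EPS or abs(yKy) < _EPS:
            break
        c = t / tt - yc / yKy
        to_raw = Kcur @ c
        s = float(np.linalg.norm(to_raw))
        if s < 1e-10:
            break  # no Y-orthogonal variation left
        t_o = to_raw / s
        d = Kcur @ t_o
        Kcur = Kcur - np.outer(t_o, d) - np.outer(d, t_o) + float(t_o @ d) * np.outer(t_o, t_o)
        comps.append(_OrthoComponent(c=c, s=s, t_o=t_o, d=d))
    t_p = Kcur @ yc
    tptp = float(t_p @ t_p)
    if tptp < _EPS:
        raise DataError("degenerate predictive score (K y is numerically zero)")
    b = float(t_p @ yc) / tptp
    return _KoplsFit(t_p=t_p, b=b, components=comps, yhat=b * t_p)


def _kopls_predict(K_te: np.ndarray, fit: _KoplsFit, yc_train: np.ndarray) -> np.ndarray:
    """Fitted-scale predictions for test rows of the (train-centered) kernel."""
    Kcur = np.array(K_te, dtype=float)
    for comp in fit.components:
        t_o_te = Kcur @ comp.c / comp.s
        Kcur = Kcur - np.outer(t_o_te, comp.d)
        Kcur = Kcur - np.outer(Kcur @ comp.t_o, comp.t_o)
    t_p_te = Kcur @ yc_train
    return fit.b * t_p_te


def _double_center(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    P = np.eye(n) - np.full((n, n), 1.0 / n)
    return P @ K @ P


def kopls_fit(K: np.ndarray, y: np.ndarray | pd.Series, n_ortho: int = 0) -> dict:
    """Public single-kernel K-OPLS fit.

    Double-centers the kernel (feature-space mean removal), centers y,
    and returns scores, fitted values, R2Y and the orthogonal score
    matrix. Raises on a non-PSD kernel (beyond -1e-8).
    """
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-10):
        raise DataError("kernel must be symmetric")
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin < -1e-8:
        raise DataError(f"kernel is not positive semidefinite (min eigenvalue {eigmin:.3g})")
    yv = np.asarray(y, dtype=float)
    ymean = yv.mean()
    yc = yv - ymean
    Kc = _double_center(K)
    fit = _kopls_core(Kc, yc, n_ortho)
    yhat = fit.yhat + ymean
    ss_res = float(np.sum((yv - yhat) ** 2))
    ss_tot = float(np.sum(yc**2))
    T_o = (
        np.column_stack([c.t_o for c in fit.components])
        if fit.components
        else np.empty((len(yv), 0))
    )
    return {
        "t_p": fit.t_p,
        "T_o": T_o,
        "b": fit.b,
        "fitted": yhat,
        "r2y": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "_fit": fit,
    }


# ---------------------------------------------------------------------------
# consensus machinery shared by fit / CV / permutations
# ---------------------------------------------------------------------------

def _as_arrays(blocks: Mapping[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    return {k: v.to_numpy(dtype=float) for k, v in blocks.items()}


def _consensus_train(
    Xs: Mapping[str, np.ndarray], y: np.ndarray, on_degenerate: str = "uniform"
):
    """Center blocks, build normalized kernels, weight them, return pieces."""
    centered, means, norms, kernels = {}, {}, {}, {}
    for name, X in Xs.items():
        xc, mu = _center_columns(X)
        K = xc @ xc.T
        norm = np.linalg.norm(K, "fro")
        if norm < _EPS:
            raise DataError(f"block {name!r} has no variance")
        centered[name] = xc
        means[name] = mu
        norms[name] = norm
        kernels[name] = K / norm
    w = consensus_weights(kernels, y, on_degenerate=on_degenerate)
    Kcons = sum(w[name] * kernels[name] for name in kernels)
    return centered, means, norms, kernels, w, Kcons


def _fold_assignment(n: int, folds: int, seed: int) -> list[np.ndarray]:
    if folds < 2 or folds > n:
        raise DataError(f"folds must be in [2, {n}], got {folds}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def _cv_q2_profile(
    Xs: Mapping[str, np.ndarray],
    y: np.ndarray,
    fold_idx: Sequence[np.ndarray],
    n_ortho_grid: Sequence[int],
) -> dict[int, float]:
    """Cross-validated Q2 for each candidate orthogonal-component count.

    Weights, centering and kernel norms are recomputed on the training
    groups of every fold.
    """
    n = len(y)
    press = {no: 0.0 for no in n_ortho_grid}
    tss = 0.0
    for te in fold_idx:
        tr = np.setdiff1d(np.arange(n), te)
        ytr, yte = y[tr], y[te]
        ymean = ytr.mean()
        ytr_c = ytr - ymean
        Ktr = None
        Kte = None
        centered, means, norms, kernels = {}, {}, {}, {}
        for name, X in Xs.items():
            xc, mu = _center_columns(X[tr])
            K = xc @ xc.T
            norm = np.linalg.norm(K, "fro")
            if norm < _EPS:
                raise DataError(f"block {name!r} has no variance in a training fold")
            kernels[name] = K / norm
            centered[name] = xc
            means[name] = mu
            norms[name] = norm
        w = consensus_weights(kernels, ytr, on_degenerate="uniform")
        for name, X in Xs.items():
            xte_c = X[te] - means[name][None, :]
            kte_b = xte_c @ centered[name].T / norms[name]
            Ktr = kernels[name] * w[name] if Ktr is None else Ktr + kernels[name] * w[name]
            Kte = kte_b * w[name] if Kte is None else Kte + kte_b * w[name]
        for no in n_ortho_grid:
            fit = _kopls_core(Ktr, ytr_c, no)
            yhat = _kopls_predict(Kte, fit, ytr_c) + ymean
            press[no] += float(np.sum((yte - yhat) ** 2))
        tss += float(np.sum((yte - ymean) ** 2))
    return {no: 1.0 - press[no] / tss for no in n_ortho_grid}


def cross_validate_q2(
    blocks: Mapping[str, pd.DataFrame],
    y: pd.Series | np.ndarray,
    folds: int = 14,
    n_ortho: int = 0,
    seed: int = 0,
) -> float:
    """k-fold cross-validated Q2 = 1 - PRESS / TSS for a fixed n_ortho."""
    Xs = _as_arrays(blocks)
    yv = np.asarray(y, dtype=float)
    fold_idx = _fold_assignment(len(yv), folds, seed)
    return _cv_q2_profile(Xs, yv, fold_idx, [n_ortho])[n_ortho]


def _fit_pipeline(
    Xs: Mapping[str, np.ndarray],
    y: np.ndarray,
    fold_idx: Sequence[np.ndarray],
    n_ortho: int | str,
    max_ortho: int,
):
    """Weights -> (CV model selection) -> final fit -> VIP. One pass."""
    if n_ortho == "auto":
        grid = list(range(max_ortho + 1))
        q2s = _cv_q2_profile(Xs, y, fold_idx, grid)
        best = grid[0]
        for no in grid[1:]:
            if q2s[no] > q2s[best] + 1e-12:  # ties resolve to fewer components
                best = no
        chosen, q2 = best, q2s[best]
    else:
        chosen = int(n_ortho)
        q2 = _cv_q2_profile(Xs, y, fold_idx, [chosen])[chosen]
    centered, means, norms, kernels, w, Kcons = _consensus_train(Xs, y, "uniform")
    ymean = y.mean()
    yc = y - ymean
    fit = _kopls_core(Kcons, yc, chosen)
    yhat = fit.yhat + ymean
    ss_tot = float(np.sum(yc**2))
    r2y = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return {
        "n_ortho": chosen,
        "q2": q2,
        "weights": w,
        "fit": fit,
        "yhat": yhat,
        "r2y": r2y,
        "centered": centered,
        "kernels": kernels,
        "Kcons": Kcons,
    }


def vip_signed(
    t_p: np.ndarray, blocks_centered: Mapping[str, np.ndarray], names: Mapping[str, list]
) -> pd.DataFrame:
    """Per-module back-projected loadings and (signed) VIP, block-wise.

    loading p_j = x_jᵀ t_p / (t_pᵀ t_p); VIP_j = sqrt(P_b p_j² / Σ p²)
    within each block (so Σ VIP² equals the block's module count);
    sVIP_j = VIP_j * sign(p_j).
    """
    tptp = float(t_p @ t_p)
    if tptp < _EPS:
        raise DataError("degenerate predictive score; VIP undefined")
    rows = []
    for bname, xc in blocks_centered.items():
        p = xc.T @ t_p / tptp
        ssq = float(np.sum(p**2))
        if ssq < _EPS:
            raise DataError(f"all-zero loadings in block {bname!r}")
        vip = np.sqrt(len(p) * p**2 / ssq)
        svip = vip * np.sign(p)
        for mod, pj, vj, sj in zip(names[bname], p, vip, svip):
            rows.append(
                {"block": bname, "module": mod, "loading": pj, "vip": vj, "svip": sj}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results classes
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Archive of permuted refits: Q2 null and the signed-VIP null."""

    q2_obs: float
    q2_perm: np.ndarray
    p_q2: float
    svip_perm: pd.DataFrame  # permutation x (block, module)
    n_perm: int


class ConsensusOPLS:
    """Consensus kernel-OPLS regression of an outcome on eigengene blocks.

    Parameters
    ----------
    blocks : mapping of block name -> group x module DataFrame
        All blocks must share an identical row (group) index.
    y : Series of the outcome per group (e.g. mean basal glycemia).
    n_ortho : "auto" (choose 0..max_ortho by CV Q2, ties toward fewer)
        or a fixed integer.
    folds : number of cross-validation folds over groups.
    """

    def __init__(
        self,
        blocks: Mapping[str, pd.DataFrame],
        y: pd.Series,
        n_ortho: int | str = "auto",
        max_ortho: int = 3,
        folds: int = 14,
    ):
        blocks = dict(blocks)
        if not blocks:
            raise DataError("at least one block is required")
        first = next(iter(blocks.values()))
        for name, X in blocks.items():
            if not X.index.equals(first.index):
                raise DataError(f"block {name!r} has a different group order")
        y = y.reindex(first.index)
        if y.isna().any():
            raise DataError("outcome missing for some groups")
        if not np.all(np.isfinite(y.to_numpy(dtype=float))):
            raise DataError("outcome contains non-finite values")
        if isinstance(n_ortho, int) and not (0 <= n_ortho <= max_ortho):
            raise DataError(f"n_ortho must be in [0, {max_ortho}]")
        self.blocks = blocks
        self.y = y.astype(float)
        self.n_ortho = n_ortho
        self.max_ortho = max_ortho
        self.folds = folds
        self.groups = list(first.index)
        self.module_names = {k: list(v.columns) for k, v in blocks.items()}

    def fit(self, seed: int = 0) -> "ConsensusOPLSResults":
        Xs = _as_arrays(self.blocks)
        yv = self.y.to_numpy()
        fold_idx = _fold_assignment(len(yv), self.folds, seed)
        state = _fit_pipeline(Xs, yv, fold_idx, self.n_ortho, self.max_ortho)
        vip = vip_signed(state["fit"].t_p, state["centered"], self.module_names)
        return ConsensusOPLSResults(model=self, seed=seed, _state=state, vip_table=vip)


@dataclass
class ConsensusOPLSResults:
    """Fitted consensus kernel-OPLS model."""

    model: ConsensusOPLS
    seed: int
    _state: dict
    vip_table: pd.DataFrame
    permutation: PermutationResult | None = field(default=None)

    # -- estimates -----------------------------------------------------------
    @property
    def q2(self) -> float:
        return self._state["q2"]

    @property
    def r2y(self) -> float:
        return self._state["r2y"]

    @property
    def n_ortho_(self) -> int:
        return self._state["n_ortho"]

    @property
    def weights(self) -> pd.Series:
        return self._state["weights"]

    @property
    def fittedvalues(self) -> pd.Series:
        return pd.Series(self._state["yhat"], index=self.model.groups, name="fitted")

    @property
    def predictive_scores(self) -> pd.Series:
        return pd.Series(self._state["fit"].t_p, index=self.model.groups, name="t_p")

    @property
    def orthogonal_scores(self) -> pd.DataFrame:
        comps = self._state["fit"].components
        if not comps:
            return pd.DataFrame(index=self.model.groups)
        return pd.DataFrame(
            {f"t_o{i + 1}": c.t_o for i, c in enumerate(comps)}, index=self.model.groups
        )

    def svip_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_frame(self.vip_table[["block", "module"]])
        return pd.Series(self.vip_table["svip"].to_numpy(), index=idx, name="svip")

    def svip_for_block(self, block: str) -> pd.Series:
        sub = self.vip_table[self.vip_table["block"] == block]
        return pd.Series(sub["svip"].to_numpy(), index=list(sub["module"]), name="svip")

    # -- inference -----------------------------------------------------------
    def permutation_test(self, n_perm: int = 999, seed: int = 1) -> PermutationResult:
        """Refit the whole pipeline under permuted outcomes.

        Each permutation shuffles y across groups and recomputes block
        weights, CV model selection, the final fit and the signed VIPs.
        p = (1 + #{Q2_perm >= Q2_obs}) / (N + 1). The signed-VIP archive
        feeds the per-gene Z-score null.
        """
        if n_perm < 1:
            raise DataError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        Xs = _as_arrays(self.model.blocks)
        yv = self.model.y.to_numpy()
        fold_idx = _fold_assignment(len(yv), self.model.folds, self.seed)
        cols = pd.MultiIndex.from_frame(self.vip_table[["block", "module"]])
        q2p = np.empty(n_perm)
        svip_rows = np.empty((n_perm, len(cols)))
        for i in range(n_perm):
            yp = rng.permutation(yv)
            state = _fit_pipeline(Xs, yp, fold_idx, self.model.n_ortho, self.model.max_ortho)
            vip = vip_signed(state["fit"].t_p, state["centered"], self.model.module_names)
            q2p[i] = state["q2"]
            svip_rows[i] = vip["svip"].to_numpy()
        p = (1.0 + np.sum(q2p >= self.q2)) / (n_perm + 1.0)
        result = PermutationResult(
            q2_obs=self.q2,
            q2_perm=q2p,
            p_q2=float(p),
            svip_perm=pd.DataFrame(svip_rows, columns=cols),
            n_perm=n_perm,
        )
        self.permutation = result
        return result

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Consensus kernel-OPLS regression",
            "=" * 48,
            f"groups:            {len(self.model.groups)}",
            f"blocks:            {len(self.model.blocks)}",
            f"orthogonal comps:  {self.n_ortho_}",
            f"CV folds:          {self.model.folds}",
            f"R2Y:               {self.r2y:.4f}",
            f"Q2 (CV):           {self.q2:.4f}",
        ]
        if self.permutation is not None:
            lines.append(
                f"permutation p(Q2): {self.permutation.p_q2:.4g} "
                f"(N={self.permutation.n_perm})"
            )
        lines.append("-" * 48)
        lines.append("block weights:")
        for name, w in self.weights.items():
            lines.append(f"  {name:<20s} {w:.4f}")
        lines.append("-" * 48)
        top = self.vip_table.reindex(
            self.vip_table["vip"].abs().sort_values(ascending=False).index
        ).head(8)
        lines.append("top modules by VIP (block, module, loading, VIP, sVIP):")
        for row in top.itertuples(index=False):
            lines.append(
                f"  {row.block:<14s} {row.module:<6s} "
                f"{row.loading:+.4f}  {row.vip:.3f}  {row.svip:+.3f}"
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Predictive vs first orthogonal score, colored by outcome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        tp = self.predictive_scores
        to = (
            self.orthogonal_scores.iloc[:, 0]
            if self.orthogonal_scores.shape[1]
            else pd.Series(0.0, index=tp.index)
        )
        sc = ax.scatter(tp, to, c=self.model.y, cmap="viridis")
        ax.set_xlabel("predictive score $t_p$")
        ax.set_ylabel("orthogonal score $t_{o1}$")
        ax.figure.colorbar(sc, ax=ax, label="outcome")
        return ax


# ---------------------------------------------------------------------------
# CCSWA / ComDim
# ---------------------------------------------------------------------------

class CCSWA:
    """Common components and specific weights analysis of kernel blocks.

    For each dimension, alternates salience updates lambda_b = qᵀ K_b q
    with extraction of the leading eigenvector of sum(lambda_b K_b)
    until the common score stabilises, then projection-deflates every
    block kernel.
    """

    def __init__(self, blocks: Mapping[str, pd.DataFrame]):
        if not blocks:
            raise DataError("at least one block is required")
        self.blocks = dict(blocks)
        first = next(iter(self.blocks.values()))
        for name, X in self.blocks.items():
            if not X.index.equals(first.index):
                raise DataError(f"block {name!r} has a different sample order")
        self.index = first.index

    def fit(self, n_dims: int = 2, tol: float = 1e-10, max_iter: int = 500) -> "CcswaResults":
        kernels = {k: v for k, v in build_kernels(self.blocks).items()}
        names = list(kernels.keys())
        Ks = [kernels[k].copy() for k in names]
        n = Ks[0].shape[0]
        total_inertia = sum(float(np.trace(K)) for K in Ks)
        scores = np.zeros((n, n_dims))
        saliences = np.zeros((len(Ks), n_dims))
        explained = np.zeros(n_dims)
        for d in range(n_dims):
            M = sum(Ks)
            q = _leading_eigvec(M)
            for it in range(max_iter):
                lam = np.array([float(q @ K @ q) for K in Ks])
                M = sum(l * K for l, K in zip(lam, Ks))
                q_new = _leading_eigvec(M)
                if q_new @ q < 0:
                    q_new = -q_new
                delta = float(np.linalg.norm(q_new - q))
                q = q_new
                if delta < tol:
                    break
            else:
                raise ConvergenceError(
                    f"CCSWA dimension {d + 1} did not converge in {max_iter} iterations",
                    n_iter=max_iter,
                    delta=delta,
                )
            lam = np.array([float(q @ K @ q) for K in Ks])
            scores[:, d] = q
            saliences[:, d] = lam
            explained[d] = lam.sum() / total_inertia if total_inertia > 0 else 0.0
            P = np.eye(n) - np.outer(q, q)
            Ks = [P @ K @ P for K in Ks]
        return CcswaResults(
            scores=pd.DataFrame(
                scores, index=self.index, columns=[f"dim{i + 1}" for i in range(n_dims)]
            ),
            saliences=pd.DataFrame(
                saliences, index=names, columns=[f"dim{i + 1}" for i in range(n_dims)]
            ),
            explained=pd.Series(
                explained, index=[f"dim{i + 1}" for i in range(n_dims)], name="explained"
            ),
        )


def _leading_eigvec(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    q = vecs[:, -1]
    # deterministic sign: largest-magnitude entry positive
    k = int(np.argmax(np.abs(q)))
    if q[k] < 0:
        q = -q
    return q


@dataclass
class CcswaResults:
    """CCSWA fit: orthonormal common scores and per-block saliences."""

    scores: pd.DataFrame  # samples x dims, unit-norm columns
    saliences: pd.DataFrame  # blocks x dims, non-negative
    explained: pd.Series

    def summary(self) -> str:
        lines = ["Common components and specific weights analysis", "=" * 48]
        for d in self.scores.columns:
            lines.append(f"{d}: explained inertia {self.explained[d]:.4f}")
            for b in self.saliences.index:
                lines.append(f"  salience {b:<20s} {self.saliences.loc[b, d]:.4f}")
        return "\n".join(lines)
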