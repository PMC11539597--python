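"""Count and lipid preprocessing, plus the insulin-tolerance AUC.

Counts: CPM filtering, TMM scaling factors (trimmed mean of M-values,
the edgeR-style weighted trimmed mean with inverse asymptotic-variance
weights), and log2-CPM transformation.

Lipids: missingness filtering (inclusive >= rule), round-robin
random-forest imputation (missForest-style: mean initialisation, each
variable's missing cells re-predicted from all others until the imputed
values stabilise, observed cells never touched), and total-signal
normalisation so every sample sums to 100. Lipid values are kept on the
raw intensity scale throughout (no log transform).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "cpm",
    "cpm_filter",
    "tmm_norm_factors",
    "log_cpm",
    "lipid_missing_filter",
    "impute_missing",
    "total_signal_normalize",
    "itt_auc",
]


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy()
    if (x < 0).any():
        raise DataError("count matrix contains negative entries")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise DataError(f"samples with zero library size: {bad}")
    return x


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    x = _check_counts(counts).astype(float)
    return pd.DataFrame(
        x / x.sum(axis=0, keepdims=True) * 1e6, index=counts.index, columns=counts.columns
    )


def cpm_filter(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    min_fraction_samples: float | None = None,
) -> pd.DataFrame:
    """Drop genes below ``cpm_threshold`` CPM in too few samples.

    A gene is retained when CPM >= threshold in at least
    ``ceil(min_fraction_samples * n_samples)`` samples. The default
    fraction ``1/n_samples`` keeps any gene that passes in a single
    sample — the least destructive reading of a bare "< 1 CPM" filter.
    Gene order is preserved. ``min_fraction_samples=0`` disables the
    filter entirely (every gene kept).
    """
    n = counts.shape[1]
    if min_fraction_samples is None:
        min_fraction_samples = 1.0 / n
    if not (0.0 <= min_fraction_samples <= 1.0):
        raise ConfigurationError("min_fraction_samples must be in [0, 1]")
    min_samples = int(np.ceil(min_fraction_samples * n))
    if min_samples == 0:
        return counts.copy()
    passing = (cpm(counts) >= cpm_threshold).sum(axis=1) >= min_samples
    out = counts.loc[passing]
    if out.empty:
        warnings.warn("cpm_filter removed every gene", stacklevel=2)
    return out


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float
) -> float:
    """Weighted trimmed mean of M-values for one sample against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("sample shares no expressed genes with the reference; factor set to 1")
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    logR = np.log2((o / n_obs) / (r / n_ref))
    absE = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2.0
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = len(logR)
    lo_l = np.floor(n * trim_M) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_A) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(logR)
    rank_s = rankdata(absE)
    sel = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not sel.any():
        return 1.0
    f = np.sum(logR[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_norm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.3,
    trim_A: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest
    to the mean upper-quartile (unless given explicitly). Trim fractions
    are applied to both tails of the M (log-ratio) and A (abundance)
    distributions.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    x = _check_counts(counts)
    c = cpm(counts).to_numpy()
    uq = np.quantile(c, 0.75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    ref = x[:, ref_idx]
    factors = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(x[:, j], ref, trim_M, trim_A)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2 CPM with a prior count, using effective library sizes.

    value = log2((count + prior) / (lib * factor + 2 * prior) * 1e6).
    """
    x = _check_counts(counts).astype(float)
    lib = x.sum(axis=0)
    f = np.ones(x.shape[1]) if factors is None else factors.reindex(counts.columns).to_numpy()
    if not np.all(np.isfinite(f)) or (f <= 0).any():
        raise DataError("normalization factors must be finite and positive")
    eff = lib * f + 2.0 * prior_count
    vals = np.log2((x + prior_count) / eff[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def lipid_missing_filter(lipids: pd.DataFrame, max_missing: float = 0.25) -> pd.DataFrame:
    """Drop lipids with a missing fraction >= ``max_missing`` (inclusive)."""
    frac = lipids.isna().mean(axis=1)
    return lipids.loc[frac < max_missing]


def impute_missing(
    lipids: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Round-robin random-forest imputation of missing lipid intensities.

    Missing cells start at the per-lipid observed mean, then each lipid
    with missing values is repeatedly re-predicted from all other lipids
    by a random forest until the imputations stabilise (relative change
    < tol) or ``max_iter`` rounds. Observed cells are never modified.
    """
    if not lipids.isna().any().any():
        return lipids.copy()
    if lipids.isna().all(axis=1).any():
        bad = lipids.index[lipids.isna().all(axis=1)].tolist()
        raise DataError(f"lipids with no observed values (filter first): {bad}")
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    est = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    imputer = IterativeImputer(
        estimator=est,
        max_iter=max_iter,
        tol=tol,
        initial_strategy="mean",
        sample_posterior=False,
        random_state=seed,
        skip_complete=True,
        keep_empty_features=False,
    )
    # samples are observations, lipids are the round-robin variables
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        filled = imputer.fit_transform(lipids.T.to_numpy())
    out = pd.DataFrame(filled.T, index=lipids.index, columns=lipids.columns)
    out = out.where(lipids.isna(), lipids)  # observed cells bit-identical
    return out


def total_signal_normalize(lipids: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its lipid intensities sum to 100."""
    if lipids.isna().any().any():
        raise DataError("total-signal normalization requires an imputed (complete) matrix")
    totals = lipids.sum(axis=0)
    if (totals <= 0).any():
        bad = lipids.columns[totals <= 0].tolist()
        raise DataError(f"samples with non-positive total signal: {bad}")
    return lipids / totals * 100.0


def itt_auc(
    times: np.ndarray | list[float],
    glycemia: np.ndarray | list[float],
    baseline_subtracted: bool = False,
) -> float:
    """Insulin-tolerance-test area under the glycemia curve (mg/dL * min).

    Trapezoidal integral over the measurement times; in
    ``baseline_subtracted`` mode the t=0 glycemia is subtracted first
    (area relative to baseline rather than absolute area).
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glycemia, dtype=float)
    if t.size != g.size or t.size < 2:
        raise DataError("need >= 2 matching time/glycemia points")
    if not np.all(np.diff(t) > 0):
        raise DataError("times must be strictly increasing")
    if not np.all(np.isfinite(g)):
        raise DataError("glycemia values must be finite")
    offset = g[0] if baseline_subtracted else 0.0
    return float(np.trapezoid(g - offset, t))
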