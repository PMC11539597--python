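"""Synthetic multi-tissue dataset generator.

Emulates the statistical backbone of a multi-organ mouse feeding study:
a factorial design (strains x diets x timepoints defining the sample
groups), per-tissue RNA-seq count blocks and lipidomic intensity blocks
whose features are organised in co-expression modules driven by latent
eigengenes, and a continuous phenotype (fasting glycemia, mg/dL) driven
linearly by a chosen subset of those module eigengenes.

Every generated object carries its ground truth (`TruthRecord`) so that
module recovery, variable-importance ranking and enrichment calls can be
scored against the planted structure.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError

UNASSIGNED = "none"  # truth label reserved for background features


def _block_rng(seed: int, name: str) -> np.random.Generator:
    """One independent stream per (seed, block name).

    Adding or reordering blocks must not perturb the draws of other
    blocks, so each block hashes its name into its own seed sequence.
    """
    h = int.from_bytes(hashlib.blake2s(name.encode()).digest()[:4], "little")
    return np.random.default_rng([int(seed), h])


@dataclass(frozen=True)
class DesignSpec:
    """Factorial sampling design: strains x diets x timepoints."""

    strains: Sequence[str] = ("B6", "DBA", "BALB")
    diets: Sequence[str] = ("RC", "HFD")
    timepoints: Sequence[int] = (2, 10, 30)
    mice_per_group: tuple[int, int] = (2, 4)
    seed: int = 0

    def validate(self) -> None:
        for attr in ("strains", "diets", "timepoints"):
            vals = list(getattr(self, attr))
            if not vals:
                raise ConfigurationError(f"DesignSpec.{attr} must be non-empty")
            if len(set(vals)) != len(vals):
                raise ConfigurationError(f"DesignSpec.{attr} contains duplicates: {vals}")
        lo, hi = self.mice_per_group
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"mice_per_group must satisfy 1 <= min <= max, got {self.mice_per_group}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.strains) * len(self.diets) * len(self.timepoints)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a DesignSpec into a sample table.

    Returns a DataFrame indexed by unique sample id with columns
    ``strain, diet, timepoint, group``; one group per factorial cell and
    an independently drawn number of mice per group.
    """
    spec.validate()
    rng = _block_rng(spec.seed, "design")
    lo, hi = spec.mice_per_group
    rows = []
    for strain, diet, tp in itertools.product(spec.strains, spec.diets, spec.timepoints):
        group = f"{strain}_{diet}_d{tp}"
        n = int(rng.integers(lo, hi + 1))
        for i in range(n):
            rows.append(
                {
                    "sample": f"{group}_m{i + 1}",
                    "strain": strain,
                    "diet": diet,
                    "timepoint": tp,
                    "group": group,
                }
            )
    design = pd.DataFrame(rows).set_index("sample")
    return design


@dataclass(frozen=True)
class ModulePlan:
    """Planted co-expression structure for one omics block.

    ``driver_effects`` maps module index -> beta (phenotype units per
    eigengene SD).  ``group_icc`` is the intraclass correlation of the
    latent eigengene within design groups: 0 keeps samples exchangeable
    (the right null for calibration work), values near 1 concentrate the
    eigengene at the group level so group-mean summaries retain signal.
    """

    n_modules: int
    module_sizes: Sequence[int]
    within_module_loading: float = 0.8
    n_background_genes: int = 100
    driver_effects: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 0.4
    group_icc: float = 0.0
    n_total_genes: int | None = None

    def validate(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                f"module_sizes has {len(self.module_sizes)} entries for {self.n_modules} modules"
            )
        if not (0.0 < self.within_module_loading <= 1.0):
            raise ConfigurationError("within_module_loading must be in (0, 1]")
        for m in self.driver_effects:
            if not (0 <= m < self.n_modules):
                raise ConfigurationError(f"driver module index {m} out of range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.group_icc < 1.0):
            raise ConfigurationError("group_icc must be in [0, 1)")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        if self.n_total_genes is not None and sum(self.module_sizes) > self.n_total_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_total_genes={self.n_total_genes}"
            )

    @property
    def n_background(self) -> int:
        if self.n_total_genes is not None:
            return self.n_total_genes - sum(self.module_sizes)
        return self.n_background_genes


@dataclass
class TruthRecord:
    """Ground truth of one generated block."""

    block: str
    assignment: pd.Series  # feature -> "M1".."Mk" or UNASSIGNED
    eigengenes: pd.DataFrame  # module x sample latent values
    driver_effects: dict[int, float]

    def module_members(self, index: int) -> list[str]:
        label = f"M{index + 1}"
        return list(self.assignment.index[self.assignment == label])


def _latent_eigengenes(
    design: pd.DataFrame, plan: ModulePlan, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent module eigengenes, unit variance, optional group structure."""
    n = len(design)
    groups = design["group"].to_numpy()
    uniq = pd.unique(groups)
    E = np.empty((plan.n_modules, n))
    rho = plan.group_icc
    for m in range(plan.n_modules):
        eps = rng.standard_normal(n)
        if rho > 0:
            u = rng.standard_normal(len(uniq))
            shift = pd.Series(u, index=uniq).loc[groups].to_numpy()
            E[m] = np.sqrt(rho) * shift + np.sqrt(1 - rho) * eps
        else:
            E[m] = eps
    labels = [f"M{m + 1}" for m in range(plan.n_modules)]
    return pd.DataFrame(E, index=labels, columns=design.index)


def _module_labels(plan: ModulePlan, feature_ids: list[str]) -> pd.Series:
    labels = []
    for m, size in enumerate(plan.module_sizes):
        labels.extend([f"M{m + 1}"] * size)
    labels.extend([UNASSIGNED] * plan.n_background)
    return pd.Series(labels, index=feature_ids, name="module")


def generate_expression_block(
    design: pd.DataFrame,
    plan: ModulePlan,
    library_size_range: tuple[float, float] = (5e5, 2e6),
    seed: int = 0,
    name: str = "rna",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Negative-binomial count block with planted modules.

    Gene log2 relative expression is ``baseline + loading * eigengene +
    noise``; counts are drawn NB with per-gene dispersion (log-uniform
    in [0.05, 0.5]) around the per-sample library-size-scaled mean.
    """
    plan.validate()
    lo, hi = library_size_range
    if lo <= 0 or hi < lo:
        raise ConfigurationError("library_size_range must be positive with min <= max")
    rng = _block_rng(seed, name)
    n_planted = sum(plan.module_sizes)
    n_genes = n_planted + plan.n_background
    n_samples = len(design)

    E = _latent_eigengenes(design, plan, rng)
    baseline = rng.uniform(3.0, 9.0, size=n_genes)  # log2 CPM scale
    log2rel = np.tile(baseline[:, None], (1, n_samples)).astype(float)
    row = 0
    for m, size in enumerate(plan.module_sizes):
        log2rel[row : row + size] += plan.within_module_loading * E.iloc[m].to_numpy()
        row += size
    log2rel += rng.normal(0.0, plan.noise_sd, size=(n_genes, n_samples))

    rel = np.exp2(log2rel)
    props = rel / rel.sum(axis=0, keepdims=True)
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    mu = props * lib
    dispersion = np.exp(rng.uniform(np.log(0.05), np.log(0.5), size=n_genes))
    size_param = 1.0 / dispersion
    p_nb = size_param[:, None] / (size_param[:, None] + mu)
    counts = rng.negative_binomial(size_param[:, None], p_nb)

    gene_ids = [f"{name}_g{i:04d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design.index)
    truth = TruthRecord(
        block=name,
        assignment=_module_labels(plan, gene_ids),
        eigengenes=E,
        driver_effects=dict(plan.driver_effects),
    )
    return counts_df, truth


def generate_lipid_block(
    design: pd.DataFrame,
    plan: ModulePlan,
    missing_rate: float = 0.2,
    seed: int = 0,
    name: str = "lipid",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Log-normal lipid intensities with MCAR missingness.

    Same latent-module construction as the expression block, on the
    natural-log intensity scale; entries are deleted completely at
    random at ``missing_rate`` and recorded as NaN.
    """
    plan.validate()
    if not (0.0 <= missing_rate <= 0.9):
        raise ConfigurationError(f"missing_rate must be in [0, 0.9], got {missing_rate}")
    rng = _block_rng(seed, name)
    n_planted = sum(plan.module_sizes)
    n_lipids = n_planted + plan.n_background
    n_samples = len(design)

    E = _latent_eigengenes(design, plan, rng)
    baseline = rng.uniform(8.0, 14.0, size=n_lipids)
    logint = np.tile(baseline[:, None], (1, n_samples)).astype(float)
    row = 0
    for m, size in enumerate(plan.module_sizes):
        logint[row : row + size] += plan.within_module_loading * E.iloc[m].to_numpy()
        row += size
    logint += rng.normal(0.0, max(plan.noise_sd, 1e-12), size=(n_lipids, n_samples))
    values = np.exp(logint)

    mask = rng.random((n_lipids, n_samples)) < missing_rate
    values = values.astype(float)
    values[mask] = np.nan

    lipid_ids = [f"{name}_l{i:04d}" for i in range(n_lipids)]
    df = pd.DataFrame(values, index=lipid_ids, columns=design.index)
    truth = TruthRecord(
        block=name,
        assignment=_module_labels(plan, lipid_ids),
        eigengenes=E,
        driver_effects=dict(plan.driver_effects),
    )
    return df, truth


def generate_phenotype(
    design: pd.DataFrame,
    truth: TruthRecord | Sequence[TruthRecord],
    baseline_by_strain_diet: float | Mapping[tuple[str, str], float] = 140.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fasting glycemia per sample: baseline + sum(beta * eigengene) + noise.

    Returns a DataFrame indexed by sample with columns ``glycemia`` and
    ``group``; per-group means are available via
    ``phenotype.groupby("group")["glycemia"].mean()`` or
    :func:`group_means`.
    """
    truths = [truth] if isinstance(truth, TruthRecord) else list(truth)
    rng = _block_rng(seed, "phenotype")
    if isinstance(baseline_by_strain_diet, Mapping):
        try:
            base = np.array(
                [
                    baseline_by_strain_diet[(r.strain, r.diet)]
                    for r in design.itertuples()
                ]
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing baseline for strain/diet {exc}") from exc
    else:
        base = np.full(len(design), float(baseline_by_strain_diet))

    y = base.astype(float).copy()
    deterministic = base.astype(float).copy()
    for t in truths:
        for m, beta in t.driver_effects.items():
            label = f"M{m + 1}"
            if label not in t.eigengenes.index:
                raise ConfigurationError(
                    f"driver module {label} absent from eigengene table of block {t.block}"
                )
            e = t.eigengenes.loc[label].reindex(design.index)
            if e.isna().any():
                raise ConfigurationError(
                    f"driver module {label} of block {t.block} lacks eigengene values "
                    "for some samples"
                )
            y += beta * e.to_numpy()
            deterministic += beta * e.to_numpy()
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=len(design))
    out = pd.DataFrame(
        {"glycemia": y, "deterministic": deterministic, "group": design["group"]},
        index=design.index,
    )
    return out


def group_means(phenotype: pd.DataFrame) -> pd.Series:
    """Mean glycemia per design group (group order of first appearance)."""
    order = pd.unique(phenotype["group"])
    return phenotype.groupby("group")["glycemia"].mean().reindex(order)


def truth_gene_sets(
    truth: TruthRecord,
    n_decoys: int = 0,
    decoy_size: int = 20,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene sets for enrichment testing: planted modules + random decoys."""
    sets: dict[str, list[str]] = {}
    for m in range(truth.eigengenes.shape[0]):
        members = truth.module_members(m)
        if members:
            sets[f"{truth.block}_set_M{m + 1}"] = members
    rng = _block_rng(seed, f"{truth.block}-decoys")
    universe = list(truth.assignment.index)
    for d in range(n_decoys):
        size = min(decoy_size, len(universe))
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        sets[f"{truth.block}_decoy{d + 1:02d}"] = members
    return sets
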